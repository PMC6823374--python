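"""L1 discretization of the Caputo fractional derivative.

For 0 < alpha <= 1 the Caputo derivative of x(t) weights the whole past of
x'(t) by a power-law kernel.  On a uniform grid t_k = k*dt the L1 scheme
approximates d^alpha x / dt^alpha at t_N by a weighted sum of the past
increments x(t_{k+1}) - x(t_k) with weights

    w_k(N) = (N - k)^(1 - alpha) - (N - 1 - k)^(1 - alpha),   k = 0 .. N-1.

Solving for x(t_N) splits the update into a history-free *Markov term*

    dt^alpha * Gamma(2 - alpha) * f(x(t_{N-1})) + x(t_{N-1})

and a *memory trace*, the weighted sum of all earlier increments
(k = 0 .. N-2), which is subtracted from the Markov term.  At alpha = 1 all
memory weights vanish and the scheme is exactly forward Euler, so the
fractional system degenerates to the classical one.

The scheme is explicit (the field is evaluated at the previous state) and
keeps the full history by default, costing O(N^2) over a run; an optional
truncation window exists for long runs and is an approximation beyond the
plain L1 scheme.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Callable, Sequence

import numpy as np
from scipy.special import gamma as _gamma

from .model import ParameterSet, vector_field

__all__ = [
    "DivergenceError",
    "SolverConfig",
    "Trajectory",
    "MemoryDecomposition",
    "l1_memory_weights",
    "integrate",
    "memory_decomposition",
    "memory_trace_series",
    "perturbed_initial_state",
    "simulate",
]

#: abort when any |state component| exceeds this (attractors live within |v| ~ 2.5)
DIVERGENCE_BOUND = 1e3


class DivergenceError(RuntimeError):
    """The integration produced a non-finite or runaway state."""

    def __init__(self, step: int, message: str | None = None):
        self.step = step
        super().__init__(message or f"trajectory diverged at step {step}")


@dataclass(frozen=True)
class SolverConfig:
    """Configuration for one L1 integration.

    ``initial_state`` of None means: perturb the model equilibrium by
    ``perturbation_scale`` times a U(0,1)^dim draw seeded with ``seed``.
    """

    alpha: float
    n_steps: int
    dt: float = 0.1
    initial_state: tuple[float, ...] | None = None
    seed: int = 0
    perturbation_scale: float = 1.0
    memory_window: int | None = None  # None = full history (exact L1)

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha <= 1.0:
            raise ValueError(f"alpha must lie in (0, 1], got {self.alpha}")
        if not self.dt > 0:
            raise ValueError("dt must be positive")
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")
        if self.perturbation_scale < 0:
            raise ValueError("perturbation_scale must be non-negative")
        if self.initial_state is not None:
            object.__setattr__(self, "initial_state", tuple(float(x) for x in self.initial_state))


@dataclass
class Trajectory:
    """Uniformly sampled states with the configuration that produced them."""

    times: np.ndarray
    states: np.ndarray  # shape (n_steps + 1, dim)
    config: SolverConfig
    field: Callable[[np.ndarray], np.ndarray] | None = dc_field(default=None, repr=False, compare=False)

    @property
    def v(self) -> np.ndarray:
        return self.states[:, 0]

    @property
    def w(self) -> np.ndarray:
        return self.states[:, 1]

    @property
    def y(self) -> np.ndarray:
        return self.states[:, 2]

    def __len__(self) -> int:
        return self.states.shape[0]


@dataclass(frozen=True)
class MemoryDecomposition:
    """Markov term and memory trace at one step; state = markov - memory."""

    markov_term: np.ndarray
    memory_trace: np.ndarray

    @property
    def state(self) -> np.ndarray:
        return self.markov_term - self.memory_trace


def l1_memory_weights(N: int, alpha: float) -> np.ndarray:
    """Memory weights w_k = (N-k)^(1-alpha) - (N-1-k)^(1-alpha), k = 0..N-2.

    These weight the *past* increments only (the k = N-1 weight of the full
    L1 sum is 1 and belongs to the Markov term).  For N < 2 there is no
    history yet and the sequence is empty.  At alpha = 1 every weight is 0.
    """
    if not 0.0 < alpha <= 1.0:
        raise ValueError(f"alpha must lie in (0, 1], got {alpha}")
    if N < 2:
        return np.empty(0)
    k = np.arange(N - 1, dtype=float)
    beta = 1.0 - alpha
    return (N - k) ** beta - (N - 1 - k) ** beta


def _increment_kernel(n_steps: int, alpha: float) -> np.ndarray:
    """D[j] = (j+1)^(1-alpha) - j^(1-alpha) for j = 0..n_steps.

    The memory trace at step N is sum_{j=1}^{N-1} D[j] * inc[N-1-j], i.e. the
    same weights as :func:`l1_memory_weights` indexed by age j = N-1-k.
    """
    j = np.arange(n_steps + 1, dtype=float)
    beta = 1.0 - alpha
    return (j + 1) ** beta - j**beta


def _memory_at(increments: np.ndarray, kernel: np.ndarray, N: int, window: int | None) -> np.ndarray:
    """Weighted history sum at step N given increments[i] = x_{i+1} - x_i."""
    if N < 2 or kernel.size == 0:
        return np.zeros(increments.shape[1])
    lo = 0 if window is None else max(0, N - 1 - window)
    # ages run from N-1 (oldest kept) down to 1
    return kernel[1 : N - lo] @ increments[N - 2 : lo - 1 if lo else None : -1]


def integrate(field: Callable[[np.ndarray], np.ndarray], cfg: SolverConfig,
              x0: Sequence[float] | None = None) -> Trajectory:
    """Integrate ``d^alpha x/dt^alpha = field(x)`` with the explicit L1 scheme.

    ``x0`` overrides ``cfg.initial_state``; one of the two must be given
    (model-aware callers should use :func:`simulate`, which fills in a seeded
    perturbation of the equilibrium).
    """
    if x0 is None:
        x0 = cfg.initial_state
    if x0 is None:
        raise ValueError("no initial state: pass x0 or set cfg.initial_state")
    x0 = np.asarray(x0, dtype=float)
    dim = x0.size

    n = cfg.n_steps
    # at alpha = 1 every memory weight is identically zero (forward Euler);
    # skip the O(N^2) history sum, which would only add exact zeros
    kernel = np.empty(0) if cfg.alpha == 1.0 else _increment_kernel(n, cfg.alpha)
    c_alpha = cfg.dt**cfg.alpha * _gamma(2.0 - cfg.alpha)

    states = np.empty((n + 1, dim))
    states[0] = x0
    increments = np.empty((n, dim))
    for N in range(1, n + 1):
        prev = states[N - 1]
        mem = _memory_at(increments, kernel, N, cfg.memory_window)
        nxt = c_alpha * np.asarray(field(prev), dtype=float) + prev - mem
        if not np.all(np.isfinite(nxt)) or np.max(np.abs(nxt)) > DIVERGENCE_BOUND:
            raise DivergenceError(N)
        states[N] = nxt
        increments[N - 1] = nxt - prev

    times = np.arange(n + 1) * cfg.dt
    return Trajectory(times=times, states=states, config=cfg, field=field)


def memory_decomposition(traj: Trajectory, at_step: int) -> MemoryDecomposition:
    """Markov term and memory trace of a stored trajectory at step ``at_step``.

    Their difference reproduces the stored state exactly (up to roundoff).
    """
    if traj.field is None:
        raise ValueError("trajectory carries no vector field; re-integrate to decompose")
    n = len(traj) - 1
    if not 1 <= at_step <= n:
        raise IndexError(f"at_step must lie in [1, {n}], got {at_step}")
    cfg = traj.config
    c_alpha = cfg.dt**cfg.alpha * _gamma(2.0 - cfg.alpha)
    prev = traj.states[at_step - 1]
    markov = c_alpha * np.asarray(traj.field(prev), dtype=float) + prev
    increments = np.diff(traj.states, axis=0)
    kernel = _increment_kernel(n, cfg.alpha)
    mem = _memory_at(increments, kernel, at_step, cfg.memory_window)
    return MemoryDecomposition(markov_term=markov, memory_trace=mem)


def memory_trace_series(traj: Trajectory, component: int = 0) -> np.ndarray:
    """Per-step memory trace of one component (default: voltage).

    Entry N is the memory trace entering the update of x(t_N); entries 0 and
    1 are zero (no history yet).  Identically zero at alpha = 1.
    """
    n = len(traj) - 1
    if n < 1:
        raise ValueError("trajectory too short")
    inc = np.diff(traj.states[:, component])
    kernel = _increment_kernel(n, traj.config.alpha)
    out = np.zeros(n + 1)
    win = traj.config.memory_window
    for N in range(2, n + 1):
        lo = 0 if win is None else max(0, N - 1 - win)
        out[N] = kernel[1 : N - lo] @ inc[N - 2 : lo - 1 if lo else None : -1]
    return out


def perturbed_initial_state(p: ParameterSet, seed: int, scale: float = 1.0) -> np.ndarray:
    """Equilibrium plus ``scale`` * U(0,1)^3, the canonical initial condition."""
    from .stability import equilibrium  # deferred: stability imports model only

    rng = np.random.default_rng(seed)
    return equilibrium(p).as_array() + scale * rng.uniform(0.0, 1.0, size=3)


def simulate(p: ParameterSet, cfg: SolverConfig) -> Trajectory:
    """Integrate the FH-R model under ``cfg``.

    If the config has no explicit initial state, the trajectory starts from a
    seeded random perturbation of the model equilibrium.
    """
    x0 = cfg.initial_state
    if x0 is None:
        x0 = perturbed_initial_state(p, cfg.seed, cfg.perturbation_scale)
    return integrate(lambda s: vector_field(s, p), cfg, x0=x0)
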