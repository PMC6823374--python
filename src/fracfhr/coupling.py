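"""Two electrically coupled FH-R neurons and complete-synchronization metrics.

The pair is coupled bidirectionally through the membrane voltage only,

    d^a v_i/dt^a = v_i - v_i^3/3 - w_i + y_i + I + g_e (v_j - v_i),

with identical parameters on both sides and coupling strength g_e >= 0.  The
stacked six-dimensional system is integrated with the same L1 scheme as a
single neuron, so the synchronization manifold v1 = v2, w1 = w2, y1 = y2 is
exactly invariant under the discrete update.

Complete synchronization (CS) is diagnosed with the similarity function

    S^2(gamma) = <(v1(t) - v2(t - gamma))^2> / sqrt(<v1^2> <v2^2>),

evaluated at lag gamma = 0 after discarding a transient; S(0) -> 0 means the
voltages coincide.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import ParameterSet, vector_field
from .solver import DivergenceError, SolverConfig, Trajectory, integrate, perturbed_initial_state

__all__ = [
    "CoupledConfig",
    "CoupledTrajectory",
    "SimilarityCurve",
    "coupled_field",
    "integrate_coupled",
    "similarity",
    "sync_sweep",
]

#: S(0) below this declares complete synchronization
CS_TOLERANCE = 0.01


@dataclass(frozen=True)
class CoupledConfig:
    """Configuration of one coupled run; both neurons share ``params``.

    Initial conditions are independent seeded perturbations of the (common)
    equilibrium, one seed per neuron.
    """

    params: ParameterSet
    g_e: float
    alpha: float
    n_steps: int
    dt: float = 0.1
    seeds: tuple[int, int] = (0, 1)
    perturbation_scale: float = 0.1
    transient_fraction: float = 0.5
    initial_states: tuple[tuple[float, ...], tuple[float, ...]] | None = None

    def __post_init__(self) -> None:
        if self.g_e < 0:
            raise ValueError("coupling strength g_e must be non-negative")
        if not 0.0 < self.transient_fraction < 1.0:
            raise ValueError("transient_fraction must lie in (0, 1)")


@dataclass
class CoupledTrajectory:
    times: np.ndarray
    states1: np.ndarray  # (n_steps + 1, 3)
    states2: np.ndarray
    config: CoupledConfig

    @property
    def v1(self) -> np.ndarray:
        return self.states1[:, 0]

    @property
    def v2(self) -> np.ndarray:
        return self.states2[:, 0]

    def post_transient(self) -> tuple[np.ndarray, np.ndarray]:
        """(v1, v2) after dropping the leading transient fraction."""
        start = int(self.config.transient_fraction * len(self.times))
        return self.states1[start:, 0], self.states2[start:, 0]


@dataclass
class SimilarityCurve:
    g_e_values: np.ndarray
    S0_values: np.ndarray  # NaN where a run diverged
    cs_tolerance: float = CS_TOLERANCE

    @property
    def cs_mask(self) -> np.ndarray:
        """Where complete synchronization is declared (S(0) < tolerance)."""
        with np.errstate(invalid="ignore"):
            return self.S0_values < self.cs_tolerance


def coupled_field(p: ParameterSet, g_e: float):
    """Vector field of the stacked (v1,w1,y1,v2,w2,y2) system."""

    def field(x: np.ndarray) -> np.ndarray:
        s1, s2 = x[:3], x[3:]
        f1 = vector_field(s1, p)
        f2 = vector_field(s2, p)
        f1[0] += g_e * (s2[0] - s1[0])
        f2[0] += g_e * (s1[0] - s2[0])
        return np.concatenate([f1, f2])

    return field


def integrate_coupled(cfg: CoupledConfig) -> CoupledTrajectory:
    if cfg.initial_states is not None:
        x0 = np.concatenate([np.asarray(s, dtype=float) for s in cfg.initial_states])
    else:
        x0 = np.concatenate(
            [perturbed_initial_state(cfg.params, s, cfg.perturbation_scale) for s in cfg.seeds]
        )
    scfg = SolverConfig(alpha=cfg.alpha, n_steps=cfg.n_steps, dt=cfg.dt, initial_state=tuple(x0))
    traj: Trajectory = integrate(coupled_field(cfg.params, cfg.g_e), scfg)
    return CoupledTrajectory(
        times=traj.times, states1=traj.states[:, :3], states2=traj.states[:, 3:], config=cfg
    )


def similarity(v1: np.ndarray, v2: np.ndarray, lag: int = 0) -> float:
    """Similarity function S(lag) between two voltage series.

    ``lag`` is in integer steps; v2 is shifted back by ``lag`` samples and
    averages are taken over the overlap.  Returns NaN when either series is
    identically zero (the normalization is undefined).
    """
    v1 = np.asarray(v1, dtype=float)
    v2 = np.asarray(v2, dtype=float)
    if v1.shape != v2.shape:
        raise ValueError("series must have equal length")
    if lag < 0 or lag >= v1.size:
        raise ValueError("lag must satisfy 0 <= lag < len(series)")
    a = v1[lag:]
    b = v2[: v2.size - lag] if lag else v2
    denom = np.sqrt(np.mean(a**2) * np.mean(b**2))
    if denom == 0.0:
        return float("nan")
    return float(np.sqrt(np.mean((a - b) ** 2) / denom))


def sync_similarity(traj: CoupledTrajectory, lag: int = 0) -> float:
    """S(lag) on the post-transient window of a coupled run."""
    v1, v2 = traj.post_transient()
    return similarity(v1, v2, lag=lag)


def sync_sweep(
    params: ParameterSet,
    alpha: float,
    g_e_grid,
    n_steps: int = 20000,
    dt: float = 0.1,
    base_seed: int = 0,
    perturbation_scale: float = 0.1,
    transient_fraction: float = 0.5,
) -> SimilarityCurve:
    """S(0) versus coupling strength, one independent seeded run per point.

    Seeds are derived from ``base_seed`` and the grid index so every grid
    point uses fresh initial conditions.  Diverged runs are recorded as NaN
    rather than aborting the sweep.
    """
    g_e_values = np.asarray(list(g_e_grid), dtype=float)
    S0 = np.empty(g_e_values.size)
    for i, ge in enumerate(g_e_values):
        cfg = CoupledConfig(
            params=params,
            g_e=float(ge),
            alpha=alpha,
            n_steps=n_steps,
            dt=dt,
            seeds=(base_seed + 2 * i, base_seed + 2 * i + 1),
            perturbation_scale=perturbation_scale,
            transient_fraction=transient_fraction,
        )
        try:
            S0[i] = sync_similarity(integrate_coupled(cfg))
        except DivergenceError:
            S0[i] = np.nan
    return SimilarityCurve(g_e_values=g_e_values, S0_values=S0)
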