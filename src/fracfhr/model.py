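"""FitzHugh-Rinzel (FH-R) vector field, Jacobian and parameter presets.

The FH-R neuron is a three-variable fast-slow excitable system: a FitzHugh-
Nagumo fast subsystem (membrane voltage ``v`` and recovery variable ``w``)
augmented with a slow modulation ``y`` of the injected current,

    dv/dt = v - v^3/3 - w + y + I
    dw/dt = delta * (a + v - b*w)
    dy/dt = mu * (c - v - d*y)

with constant stimulus current ``I``.  ``delta`` and especially ``mu`` are
small, producing the slow-fast structure responsible for elliptic bursting.
In the fractional-order generalization each left-hand side is a Caputo
derivative of order ``alpha`` (see :mod:`fracfhr.solver`); the vector field
itself is unchanged.

Voltages are on a mV-like scale and time on a ms-like scale, but the model
constants are treated as plain dimensionless reals throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

__all__ = [
    "ParameterSet",
    "PRESET_LABELS",
    "preset",
    "vector_field",
    "jacobian",
]


class AssumptionAWarning(UserWarning):
    """Raised (as a warning) when b*d >= b + d for user-supplied parameters."""


@dataclass(frozen=True)
class ParameterSet:
    """The seven FH-R model constants.

    ``assumption_a`` (b*d < b + d) guarantees a unique equilibrium and is
    required by the analysis routines in :mod:`fracfhr.stability`; plain
    simulation does not need it, so a violation only warns here.
    """

    a: float
    b: float
    c: float
    d: float
    delta: float
    mu: float
    I: float
    label: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        for name in ("b", "d", "delta", "mu"):
            if not getattr(self, name) > 0:
                raise ValueError(f"parameter {name} must be positive, got {getattr(self, name)}")
        if not all(np.isfinite([self.a, self.b, self.c, self.d, self.delta, self.mu, self.I])):
            raise ValueError("all model constants must be finite")
        if not self.assumption_a:
            warnings.warn(
                "b*d >= b + d: equilibrium may be non-unique and the stability "
                "analysis is inapplicable",
                AssumptionAWarning,
                stacklevel=2,
            )

    @property
    def assumption_a(self) -> bool:
        """Whether b*d < b + d (unique-equilibrium condition)."""
        return self.b * self.d < self.b + self.d

    def to_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in ("a", "b", "c", "d", "delta", "mu", "I")}

    @classmethod
    def from_dict(cls, data: Mapping[str, float], label: str | None = None) -> "ParameterSet":
        return cls(label=label, **{k: float(data[k]) for k in ("a", "b", "c", "d", "delta", "mu", "I")})

    def with_overrides(self, **overrides: float) -> "ParameterSet":
        """A copy with some constants replaced (label dropped)."""
        return replace(self, label=None, **overrides)


# Frozen in code deliberately: the five canonical studies hinge on these exact
# constants and tests pin them.
_BASE = dict(a=0.7, b=0.8, c=-0.775, d=1.0, delta=0.08, mu=0.0001, I=0.3125)
_OVERRIDES: dict[str, dict[str, float]] = {
    "I": {},
    "II": {"I": 0.4},
    "III": {"mu": 0.18, "I": 3.0},
    "IV": {"c": 1.3},
    "V": {"c": -0.908, "mu": 0.002},
}

PRESET_LABELS = tuple(_OVERRIDES)


def preset(label: str) -> ParameterSet:
    """Return one of the five canonical parameter sets ("I" .. "V").

    All presets share a=0.7, b=0.8, d=1, delta=0.08 and differ in c, mu, I:
    set I is the elliptic burster (I=0.3125), II tonic spiking (I=0.4),
    III a fast slow-variable regime (mu=0.18, I=3), IV a saddle regime
    (c=1.3), V sparse high-amplitude spiking (c=-0.908, mu=0.002).
    """
    if label not in _OVERRIDES:
        raise ValueError(f"unknown preset {label!r}; valid labels: {', '.join(PRESET_LABELS)}")
    return ParameterSet(label=label, **{**_BASE, **_OVERRIDES[label]})


def vector_field(state: np.ndarray, p: ParameterSet) -> np.ndarray:
    """Right-hand side (f1, f2, f3) of the FH-R equations at ``state=(v, w, y)``."""
    v, w, y = np.asarray(state, dtype=float)
    return np.array(
        [
            v - v**3 / 3.0 - w + y + p.I,
            p.delta * (p.a + v - p.b * w),
            p.mu * (p.c - v - p.d * y),
        ]
    )


def jacobian(v_star: float, p: ParameterSet) -> np.ndarray:
    """Jacobian of the vector field; it depends on the state only through v."""
    return np.array(
        [
            [1.0 - v_star**2, -1.0, 1.0],
            [p.delta, -p.delta * p.b, 0.0],
            [-p.mu, 0.0, -p.mu * p.d],
        ]
    )
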