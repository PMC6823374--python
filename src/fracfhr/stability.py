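"""Equilibrium, spectral and bifurcation analysis of the FH-R model.

Setting the vector field to zero gives w* = (v* + a)/b, y* = (c - v*)/d and a
cubic for the voltage,

    F(v*) = v*^3 - 3 p v* = q,   p = 1 - 1/b - 1/d,   q = 3I - 3a/b + 3c/d.

Under assumption A (b*d < b + d) we have p < 0, F is strictly increasing and
the equilibrium is unique for every q.  The Jacobian at the fixed point has a
negative determinant, so at least one eigenvalue is real and negative; the
other two are either both real or a complex-conjugate pair.

For a commensurate Caputo system of order alpha the equilibrium is
asymptotically stable iff every eigenvalue satisfies |arg(lambda)| >
alpha*pi/2.  Real negative eigenvalues have |arg| = pi and never violate
this, so stability is decided by the complex pair: the critical exponent is

    alpha* = (2/pi) * |arg(lambda_complex)|,

equivalently an arccos expression in the real eigenvalue lambda_1, the trace
and det(J).  Crossing alpha = alpha* is the fractional analogue of a Hopf
bifurcation; the same quantity, written as (2/pi) atan(|Im|/Re) when the
pair is unstable, is the necessary condition for chaos in a saddle-focus of
index 2 (one stable real direction, unstable spiral plane).

In the classical (alpha = 1) model the Hopf points in the stimulus current I
can be located two ways: the trace-zero approximation (invert F at the
voltages gamma_{1,2} = -+sqrt(1 - delta*b - mu*d) where trace(J) = 0) or by
root-finding the actual Re(lambda_complex)(I) = 0 crossing.  Both are
exposed; they differ in the fourth decimal because trace zero ignores the
real eigenvalue's contribution.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
from scipy.optimize import brentq

from .model import ParameterSet, jacobian

__all__ = [
    "CubicForm",
    "Equilibrium",
    "EigenSpectrum",
    "AlphaIndependentStability",
    "StabilityReport",
    "cubic_form",
    "equilibrium",
    "eigen_spectrum",
    "alpha_independent_stability",
    "critical_alpha",
    "chaos_alpha",
    "classical_hopf_currents",
    "hopf_curve",
    "n_index",
    "stability_report",
]

_REAL_TOL = 1e-9


class AssumptionAError(ValueError):
    """Analysis requested for parameters violating b*d < b + d."""


def _require_assumption_a(p: ParameterSet) -> None:
    if not p.assumption_a:
        raise AssumptionAError(
            "analysis requires b*d < b + d (unique equilibrium); "
            f"got b*d = {p.b * p.d}, b + d = {p.b + p.d}"
        )


@dataclass(frozen=True)
class CubicForm:
    """Invariants p, q of the equilibrium cubic F(v) = v^3 - 3 p v = q."""

    p: float
    q: float

    def F(self, v: float | np.ndarray) -> float | np.ndarray:
        return v**3 - 3.0 * self.p * v


@dataclass(frozen=True)
class Equilibrium:
    v_star: float
    w_star: float
    y_star: float

    def as_array(self) -> np.ndarray:
        return np.array([self.v_star, self.w_star, self.y_star])


@dataclass(frozen=True)
class EigenSpectrum:
    """Eigenvalues of the Jacobian at the equilibrium, plus derived scalars."""

    eigenvalues: tuple[complex, complex, complex]
    lambda1: float  # the (smallest) real eigenvalue
    complex_pair: complex | None  # member with positive imaginary part, if any
    det_J: float
    trace_J: float
    discriminant: float  # of the characteristic cubic; < 0 iff complex pair

    @property
    def has_complex_pair(self) -> bool:
        return self.complex_pair is not None

    @property
    def is_saddle_focus_index2(self) -> bool:
        """One negative real eigenvalue plus an unstable complex pair."""
        return self.complex_pair is not None and self.lambda1 < 0 and self.complex_pair.real > 0


def cubic_form(p: ParameterSet) -> CubicForm:
    _require_assumption_a(p)
    return CubicForm(
        p=1.0 - 1.0 / p.b - 1.0 / p.d,
        q=3.0 * p.I - 3.0 * p.a / p.b + 3.0 * p.c / p.d,
    )


def equilibrium(p: ParameterSet) -> Equilibrium:
    """The unique fixed point (v*, w*, y*).

    The cubic is solved via its companion matrix (numpy.roots), which is
    robust for p near 0, and the single real root selected; uniqueness is
    guaranteed because F is strictly increasing under assumption A.
    """
    cf = cubic_form(p)
    roots = np.roots([1.0, 0.0, -3.0 * cf.p, -cf.q])
    real = roots[np.abs(roots.imag) < 1e-7 * max(1.0, np.abs(roots).max())].real
    if real.size == 0:  # pragma: no cover - cannot happen for a real cubic
        raise RuntimeError("no real root found for the equilibrium cubic")
    v = float(real[np.argmin(np.abs(cf.F(real) - cf.q))])
    return Equilibrium(v_star=v, w_star=(v + p.a) / p.b, y_star=(p.c - v) / p.d)


def _char_poly_coeffs(v_star: float, p: ParameterSet) -> np.ndarray:
    """Monic characteristic polynomial coefficients of J(v*).

    Built from trace, sum of principal 2x2 minors and determinant of the
    analytic Jacobian, giving an eigenvalue route independent of numerical
    linear algebra.
    """
    b, d, delta, mu = p.b, p.d, p.delta, p.mu
    tr = 1.0 - v_star**2 - delta * b - mu * d
    minors = (
        delta * b * mu * d
        + (mu - mu * d + mu * d * v_star**2)
        + (delta - delta * b + delta * b * v_star**2)
    )
    det = mu * delta * ((b * d - b - d) - b * d * v_star**2)
    return np.array([1.0, -tr, minors, -det])


def eigen_spectrum(p: ParameterSet, cross_check_tol: float = 1e-8) -> EigenSpectrum:
    """Spectrum of the Jacobian at the equilibrium.

    Computed both as roots of the analytic characteristic polynomial and as
    numerical eigenvalues of the Jacobian; the two routes must agree to
    ``cross_check_tol`` (relative), otherwise something is numerically wrong
    and we refuse to report.
    """
    eq = equilibrium(p)
    J = jacobian(eq.v_star, p)
    ev = np.linalg.eigvals(J)
    coeffs = _char_poly_coeffs(eq.v_star, p)
    pr = np.roots(coeffs)
    scale = max(1.0, np.abs(ev).max())
    mismatch = np.abs(np.sort_complex(ev) - np.sort_complex(pr)).max() / scale
    if mismatch > cross_check_tol:
        raise RuntimeError(
            f"characteristic-polynomial roots and Jacobian eigenvalues disagree ({mismatch:.2e})"
        )

    tol = _REAL_TOL * scale
    real_mask = np.abs(ev.imag) < tol
    if not real_mask.any():
        # a real cubic always has a real root; near-degenerate spectra can
        # leave numerical imaginary dust on it
        real_mask[np.argmin(np.abs(ev.imag))] = True
    real_eigs = np.sort(ev[real_mask].real)
    complex_eigs = ev[~real_mask]
    pair = complex(complex_eigs[complex_eigs.imag > 0][0]) if complex_eigs.size else None
    lambda1 = float(real_eigs[0])

    # discriminant of the monic cubic l^3 + b2 l^2 + b1 l + b0
    _, b2, b1, b0 = coeffs
    disc = (
        18.0 * b2 * b1 * b0
        - 4.0 * b2**3 * b0
        + b2**2 * b1**2
        - 4.0 * b1**3
        - 27.0 * b0**2
    )
    key = np.lexsort((ev.imag, ev.real))
    return EigenSpectrum(
        eigenvalues=tuple(complex(z) for z in ev[key]),
        lambda1=lambda1,
        complex_pair=pair,
        det_J=float(np.linalg.det(J)),
        trace_J=float(np.trace(J)),
        discriminant=float(disc),
    )


@dataclass(frozen=True)
class AlphaIndependentStability:
    """Trace-zero voltages and the stimulus window they bound.

    ``outside_window`` applies the sufficient condition: for q <= F(gamma1)
    or q >= F(gamma2) all eigenvalues are real and negative, so the
    equilibrium is stable for every alpha.  The proof behind the window
    assumes mu < b*delta (with d = 1); ``stable_for_all_alpha`` is the
    direct eigenvalue (Hurwitz) check, valid unconditionally, and the two
    can disagree when mu > b*delta (parameter set III).
    """

    gamma1: float | None
    gamma2: float | None
    F_gamma1: float | None
    F_gamma2: float | None
    I_low: float | None
    I_high: float | None
    outside_window: bool | None
    stable_for_all_alpha: bool


def _q_to_I(q: float, p: ParameterSet) -> float:
    return q / 3.0 + p.a / p.b - p.c / p.d


def alpha_independent_stability(p: ParameterSet) -> AlphaIndependentStability:
    _require_assumption_a(p)
    spec = eigen_spectrum(p)
    hurwitz = bool(all(z.real < 0 for z in spec.eigenvalues))
    disc_trace = 1.0 - p.delta * p.b - p.mu * p.d
    if disc_trace <= 0:
        # no trace-zero voltages exist; only the eigenvalue route applies
        return AlphaIndependentStability(None, None, None, None, None, None, None, hurwitz)
    g2 = float(np.sqrt(disc_trace))
    cf = cubic_form(p)
    Fg1, Fg2 = float(cf.F(-g2)), float(cf.F(g2))
    I_low, I_high = _q_to_I(Fg1, p), _q_to_I(Fg2, p)
    outside = not (I_low < p.I < I_high)
    return AlphaIndependentStability(-g2, g2, Fg1, Fg2, I_low, I_high, outside, hurwitz)


def critical_alpha(p: ParameterSet, cross_check_tol: float = 1e-6) -> float | None:
    """Critical fractional exponent alpha* = (2/pi)|arg(lambda_complex)|.

    Returns None when the spectrum is all-real (stability is then decided by
    the signs of the eigenvalues, independent of alpha) or when the complex
    pair is stable so that the formal value exceeds 1 (stable for the whole
    admissible range alpha in (0, 1]).

    When the real eigenvalue is negative the arccos form in (lambda1,
    trace, det) must agree with the argument form to ``cross_check_tol``;
    disagreement indicates a numerical fault and raises.
    """
    spec = eigen_spectrum(p)
    if spec.complex_pair is None:
        return None
    alpha_star = (2.0 / np.pi) * abs(np.angle(spec.complex_pair))
    if spec.lambda1 < 0:
        lam1 = spec.lambda1
        ratio = (spec.trace_J - lam1) * np.sqrt(-lam1) / (2.0 * np.sqrt(-spec.det_J))
        alpha_arccos = (2.0 / np.pi) * np.arccos(min(1.0, max(0.0, ratio)))
        # the clipped arccos form saturates at 0/1; only compare inside
        if 0.0 < ratio < 1.0 and abs(alpha_arccos - alpha_star) > cross_check_tol:
            raise RuntimeError(
                f"arccos and arg forms of alpha* disagree: {alpha_arccos} vs {alpha_star}"
            )
    if alpha_star > 1.0:
        return None
    return float(alpha_star)


def chaos_alpha(p: ParameterSet) -> float | None:
    """Necessary-condition threshold for chaos, (2/pi) atan(|Im|/Re).

    Defined only for a saddle-focus of index 2 (stable real direction,
    unstable spiral); coincides with alpha* there.  This is a necessary
    condition only - it does not certify chaos above the threshold.
    """
    spec = eigen_spectrum(p)
    if not spec.is_saddle_focus_index2:
        return None
    lam = spec.complex_pair
    return float((2.0 / np.pi) * np.arctan(abs(lam.imag) / lam.real))


def _re_complex_pair(I: float, p: ParameterSet) -> float:
    spec = eigen_spectrum(p.with_overrides(I=I))
    if spec.complex_pair is None:
        return np.nan
    return spec.complex_pair.real


def classical_hopf_currents(
    p: ParameterSet, method: str = "continuation"
) -> tuple[float | None, float | None]:
    """Hopf stimulus currents (I_HB1, I_HB2) of the classical-order model.

    method="trace_zero": invert F at gamma1/gamma2 and map q to I; the
    textbook approximation.  method="continuation": bisect the actual
    Re(lambda_complex)(I) = 0 crossing, which sits slightly outside the
    trace-zero window because the real eigenvalue is small but nonzero.
    """
    _require_assumption_a(p)
    ais = alpha_independent_stability(p)
    if ais.gamma2 is None:
        return (None, None)
    if method == "trace_zero":
        return (ais.I_low, ais.I_high)
    if method != "continuation":
        raise ValueError(f"unknown method {method!r}; use 'trace_zero' or 'continuation'")

    def bracket_and_solve(I_from: float, I_to: float) -> float | None:
        grid = np.linspace(I_from, I_to, 200)
        vals = np.array([_re_complex_pair(I, p) for I in grid])
        ok = np.isfinite(vals)
        for i in range(len(grid) - 1):
            if ok[i] and ok[i + 1] and vals[i] * vals[i + 1] < 0:
                return float(
                    brentq(lambda I: _re_complex_pair(I, p), grid[i], grid[i + 1], xtol=1e-10)
                )
        return None

    # the true crossings sit just outside the trace-zero window, so start
    # the scans a little below/above its bounds
    hb1 = bracket_and_solve(ais.I_low - 0.05, min(0.7, ais.I_high))
    hb2 = bracket_and_solve(max(2.6, ais.I_low), ais.I_high + 0.05)
    return (hb1, hb2)


def n_index(p: ParameterSet, alpha: float) -> np.ndarray:
    """Instability indicators n_i = alpha*pi/2 - |arg(lambda_i)|.

    Plays the role the eigenvalue real part plays classically: the
    equilibrium is stable iff every n_i < 0.
    """
    spec = eigen_spectrum(p)
    return alpha * np.pi / 2.0 - np.abs(np.angle(np.array(spec.eigenvalues)))


def hopf_curve(p: ParameterSet, I_grid: Iterable[float]) -> np.ndarray:
    """alpha*(I) along a stimulus grid; NaN where the spectrum is all-real.

    Returns a structured array with fields I and alpha_star.  The all-real
    region (positive cubic discriminant, e.g. I in roughly [0.7, 2.6] at the
    base parameters) has no fractional Hopf point and is masked.
    """
    I_values = np.asarray(list(I_grid), dtype=float)
    out = np.empty(I_values.size, dtype=[("I", float), ("alpha_star", float)])
    out["I"] = I_values
    for i, I in enumerate(I_values):
        pi = p.with_overrides(I=float(I))
        spec = eigen_spectrum(pi)
        if spec.complex_pair is None:
            out["alpha_star"][i] = np.nan
        else:
            a = critical_alpha(pi)
            out["alpha_star"][i] = np.nan if a is None else a
    return out


@dataclass(frozen=True)
class StabilityReport:
    """One-stop analysis summary for a parameter set."""

    params: ParameterSet
    equilibrium: Equilibrium
    spectrum: EigenSpectrum
    alpha_independent: AlphaIndependentStability
    critical_alpha: float | None
    chaos_alpha: float | None
    hopf_trace_zero: tuple[float | None, float | None]
    hopf_continuation: tuple[float | None, float | None]

    def to_dict(self) -> dict:
        spec = self.spectrum
        return {
            "params": {**self.params.to_dict(), "label": self.params.label},
            "assumption_a": self.params.assumption_a,
            "equilibrium": {
                "v_star": self.equilibrium.v_star,
                "w_star": self.equilibrium.w_star,
                "y_star": self.equilibrium.y_star,
            },
            "eigenvalues": [[z.real, z.imag] for z in spec.eigenvalues],
            "lambda1": spec.lambda1,
            "det_J": spec.det_J,
            "trace_J": spec.trace_J,
            "is_saddle_focus_index2": spec.is_saddle_focus_index2,
            "gamma1": self.alpha_independent.gamma1,
            "gamma2": self.alpha_independent.gamma2,
            "F_gamma1": self.alpha_independent.F_gamma1,
            "F_gamma2": self.alpha_independent.F_gamma2,
            "I_window": [self.alpha_independent.I_low, self.alpha_independent.I_high],
            "stable_for_all_alpha": self.alpha_independent.stable_for_all_alpha,
            "critical_alpha": self.critical_alpha,
            "chaos_alpha": self.chaos_alpha,
            "hopf_trace_zero": list(self.hopf_trace_zero),
            "hopf_continuation": list(self.hopf_continuation),
        }


def stability_report(p: ParameterSet, hopf: bool = True) -> StabilityReport:
    """Assemble the full analysis (set ``hopf=False`` to skip the scans)."""
    return StabilityReport(
        params=p,
        equilibrium=equilibrium(p),
        spectrum=eigen_spectrum(p),
        alpha_independent=alpha_independent_stability(p),
        critical_alpha=critical_alpha(p),
        chaos_alpha=chaos_alpha(p),
        hopf_trace_zero=classical_hopf_currents(p, "trace_zero") if hopf else (None, None),
        hopf_continuation=classical_hopf_currents(p, "continuation") if hopf else (None, None),
    )
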