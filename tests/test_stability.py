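"""Equilibrium cubic, spectra, critical fractional exponent and Hopf structure."""

import numpy as np
import pytest

import fracfhr as f
from fracfhr.stability import AssumptionAError, _char_poly_coeffs

from conftest import random_assumption_a_params


class TestCubicForm:
    def test_invariants_preset_I(self):
        cf = f.cubic_form(f.preset("I"))
        assert cf.p == pytest.approx(-1.25, abs=1e-12)
        assert cf.q == pytest.approx(-4.0125, abs=1e-12)

    def test_cubic_satisfied_at_equilibrium(self):
        for label in f.PRESET_LABELS:
            p = f.preset(label)
            cf = f.cubic_form(p)
            eq = f.equilibrium(p)
            assert cf.F(eq.v_star) == pytest.approx(cf.q, abs=1e-9)

    def test_assumption_a_required(self):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            bad = f.ParameterSet(a=0.7, b=3.0, c=0.0, d=3.0, delta=0.08, mu=0.01, I=0.0)
        with pytest.raises(AssumptionAError):
            f.cubic_form(bad)
        with pytest.raises(AssumptionAError):
            f.equilibrium(bad)

    def test_F_strictly_increasing_under_assumption_a(self):
        rng = np.random.default_rng(0)
        v = np.linspace(-3, 3, 201)
        for _ in range(25):
            cf = f.cubic_form(random_assumption_a_params(rng))
            assert cf.p < 0
            assert np.all(np.diff(cf.F(v)) > 0)


class TestEquilibrium:
    @pytest.mark.parametrize(
        "label, expected, tol",
        [
            ("I", (-0.885098, -0.231373, 0.110098), 1e-5),
            ("II", (-0.841243, -0.176554, 0.066243), 1e-5),
            ("III", (0.891229, None, None), 1e-5),
            ("IV", (0.54648, 1.5581, 0.75352), 1e-4),
            ("V", (-0.948702, None, None), 1e-5),
        ],
    )
    def test_printed_fixed_points(self, label, expected, tol):
        eq = f.equilibrium(f.preset(label))
        got = (eq.v_star, eq.w_star, eq.y_star)
        for g, e in zip(got, expected):
            if e is not None:
                assert g == pytest.approx(e, abs=tol)

    def test_back_substitution_identities(self):
        rng = np.random.default_rng(3)
        for _ in range(25):
            p = random_assumption_a_params(rng)
            eq = f.equilibrium(p)
            assert eq.w_star == pytest.approx((eq.v_star + p.a) / p.b, rel=1e-12)
            assert eq.y_star == pytest.approx((p.c - eq.v_star) / p.d, rel=1e-12)


class TestEigenSpectrum:
    def test_preset_I_complex_pair(self):
        spec = f.eigen_spectrum(f.preset("I"))
        assert spec.lambda1 == pytest.approx(-0.000196427, abs=1e-5)
        assert spec.complex_pair.real == pytest.approx(0.076349, abs=1e-5)
        assert abs(spec.complex_pair.imag) == pytest.approx(0.245811, abs=1e-5)
        assert spec.is_saddle_focus_index2

    def test_preset_IV_all_real(self):
        spec = f.eigen_spectrum(f.preset("IV"))
        assert spec.complex_pair is None
        got = sorted(z.real for z in spec.eigenvalues)
        for g, e in zip(got, (-0.00028055, 0.0613089, 0.576231)):
            assert g == pytest.approx(e, abs=1e-5)
        assert not spec.is_saddle_focus_index2
        assert spec.discriminant > 0

    def test_char_poly_and_jacobian_agree_on_random_parameters(self):
        # mutual oracle: analytic characteristic polynomial vs numerical eigenvalues
        rng = np.random.default_rng(12)
        for _ in range(100):
            p = random_assumption_a_params(rng)
            spec = f.eigen_spectrum(p)  # raises internally above 1e-8 mismatch
            ev = np.array(spec.eigenvalues)
            assert ev.sum().real == pytest.approx(spec.trace_J, rel=1e-8, abs=1e-10)
            assert np.prod(ev).real == pytest.approx(spec.det_J, rel=1e-8, abs=1e-12)
            assert spec.lambda1 < 0  # det(J) < 0 forces a negative real root
            assert (spec.discriminant < 0) == spec.has_complex_pair

    def test_vieta_trace_identity_presets(self):
        for label in f.PRESET_LABELS:
            p = f.preset(label)
            eq = f.equilibrium(p)
            spec = f.eigen_spectrum(p)
            tr = 1 - eq.v_star**2 - p.delta * p.b - p.mu * p.d
            assert sum(z.real for z in spec.eigenvalues) == pytest.approx(tr, rel=1e-9)
            coeffs = _char_poly_coeffs(eq.v_star, p)
            assert coeffs[1] == pytest.approx(-tr, rel=1e-12)

    def test_real_root_localization_by_Q_at_minus_mu(self):
        # mu < b*delta (sets I, II): real root below -mu; mu > b*delta (III): in [-mu, 0)
        for label in ("I", "II"):
            p = f.preset(label)
            assert p.mu < p.b * p.delta
            assert f.eigen_spectrum(p).lambda1 < -p.mu
        p3 = f.preset("III")
        assert p3.mu > p3.b * p3.delta
        lam1 = f.eigen_spectrum(p3).lambda1
        assert -p3.mu <= lam1 < 0


class TestCriticalAlpha:
    @pytest.mark.parametrize(
        "label, expected",
        [("I", 0.80828), ("II", 0.6951), ("III", 0.95665), ("V", 0.956455)],
    )
    def test_printed_critical_exponents(self, label, expected):
        assert f.critical_alpha(f.preset(label)) == pytest.approx(expected, abs=1e-4)

    def test_all_real_spectrum_returns_none(self):
        assert f.critical_alpha(f.preset("IV")) is None

    def test_stable_complex_pair_returns_none(self):
        # far below the Hopf window the pair is stable: no critical exponent in (0, 1]
        p = f.preset("I").with_overrides(I=0.05)
        spec = f.eigen_spectrum(p)
        assert spec.complex_pair is not None and spec.complex_pair.real < 0
        assert f.critical_alpha(p) is None

    def test_matches_chaos_condition_where_saddle_focus(self):
        for label in ("I", "II", "III", "V"):
            p = f.preset(label)
            assert f.chaos_alpha(p) == pytest.approx(f.critical_alpha(p), abs=1e-9)

    def test_chaos_condition_requires_unstable_pair(self):
        assert f.chaos_alpha(f.preset("IV")) is None
        assert f.chaos_alpha(f.preset("I").with_overrides(I=0.05)) is None

    def test_n_index_sign_tracks_stability(self):
        p = f.preset("I")
        a_star = f.critical_alpha(p)
        assert np.all(f.n_index(p, a_star - 0.05) < 0)
        assert np.any(f.n_index(p, min(1.0, a_star + 0.05)) > 0)


class TestAlphaIndependentStability:
    def test_printed_window(self):
        ais = f.alpha_independent_stability(f.preset("I"))
        assert ais.gamma2 == pytest.approx(0.9674, abs=1e-4)
        assert ais.F_gamma2 == pytest.approx(4.5331, abs=2e-4)
        assert ais.I_low == pytest.approx(0.1390, abs=1e-3)
        assert ais.I_high == pytest.approx(3.1610, abs=1e-3)
        assert ais.outside_window is False  # I = 0.3125 sits inside

    def test_odd_symmetry_of_window(self):
        ais = f.alpha_independent_stability(f.preset("II"))
        assert ais.gamma1 == pytest.approx(-ais.gamma2, rel=1e-12)
        assert ais.F_gamma1 == pytest.approx(-ais.F_gamma2, rel=1e-12)

    def test_stability_outside_window_by_eigenvalue_oracle(self):
        # 50 stimuli outside (I_low, I_high): every eigenvalue strictly stable
        p = f.preset("I")
        ais = f.alpha_independent_stability(p)
        rng = np.random.default_rng(9)
        lows = rng.uniform(ais.I_low - 3.0, ais.I_low - 1e-6, size=25)
        highs = rng.uniform(ais.I_high + 1e-6, ais.I_high + 3.0, size=25)
        for I in np.concatenate([lows, highs]):
            spec = f.eigen_spectrum(p.with_overrides(I=float(I)))
            assert all(z.real < 0 for z in spec.eigenvalues)
            assert f.alpha_independent_stability(p.with_overrides(I=float(I))).stable_for_all_alpha

    def test_window_test_vs_hurwitz_disagree_for_fast_slow_variable(self):
        # mu > b*delta (set III): the window's sufficiency proof no longer applies
        ais = f.alpha_independent_stability(f.preset("III"))
        assert ais.outside_window is True
        assert ais.stable_for_all_alpha is False


class TestClassicalHopf:
    def test_trace_zero_currents(self):
        lo, hi = f.classical_hopf_currents(f.preset("I"), method="trace_zero")
        assert lo == pytest.approx(0.1390, abs=1e-3)
        assert hi == pytest.approx(3.1610, abs=1e-3)

    def test_continuation_currents(self):
        lo, hi = f.classical_hopf_currents(f.preset("I"), method="continuation")
        assert lo == pytest.approx(0.138716, abs=1e-4)
        assert hi == pytest.approx(3.161277, abs=1e-4)

    @pytest.mark.parametrize("method", ["trace_zero", "continuation"])
    def test_symmetry_sum_identity(self, method):
        p = f.preset("I")
        lo, hi = f.classical_hopf_currents(p, method=method)
        assert lo + hi == pytest.approx(2 * (p.a / p.b - p.c / p.d), abs=1e-3)

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError):
            f.classical_hopf_currents(f.preset("I"), method="magic")

    def test_continuation_zeroes_real_part(self):
        p = f.preset("I")
        lo, hi = f.classical_hopf_currents(p, method="continuation")
        for I in (lo, hi):
            spec = f.eigen_spectrum(p.with_overrides(I=I))
            assert abs(spec.complex_pair.real) < 1e-8


class TestHopfCurve:
    def test_critical_values_on_grid(self):
        curve = f.hopf_curve(f.preset("I"), [0.3125, 0.4])
        assert curve["alpha_star"][0] == pytest.approx(0.80828, abs=1e-4)
        assert curve["alpha_star"][1] == pytest.approx(0.6951, abs=1e-4)

    def test_all_real_region_masked(self):
        curve = f.hopf_curve(f.preset("I"), [1.0, 1.5, 2.0])
        assert np.all(np.isnan(curve["alpha_star"]))

    def test_curve_continuous_near_window_edges(self):
        curve = f.hopf_curve(f.preset("I"), np.linspace(0.15, 0.6, 10))
        assert np.all(np.isfinite(curve["alpha_star"]))
        # alpha* rises back toward 1 approaching the lower Hopf current
        assert curve["alpha_star"][0] > curve["alpha_star"][3]
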