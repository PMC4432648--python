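"""Mean-field kinetics, dispersion relations and the Turing bifurcation."""

import math

import numpy as np
import pytest

from digrow import (
    BifurcationPoint,
    MeanFieldState,
    ModelParams,
    NoTuringBifurcation,
    bifurcation_diagram,
    critical_h,
    critical_h_closed_form,
    growth_rate,
    homogeneous_steady_states,
    integrate_lattice_meanfield,
    jacobian_k,
    kinetics,
    max_growth,
    mixed_state,
)
from digrow.meanfield import CONTINUUM, LATTICE
from digrow.patterns import structure_factor


class TestKinetics:
    def test_all_x_stationary_without_death(self, stripe_params):
        state = MeanFieldState(1.0, 0.0, True, "ALL_X")
        assert kinetics(state, stripe_params) == (0.0, 0.0)

    def test_all_m_stationary_without_death_or_birth(self, stripe_params):
        state = MeanFieldState(0.0, 1.0, True, "ALL_M")
        assert kinetics(state, stripe_params) == (0.0, 0.0)

    def test_mixed_state_stationary(self, stripe_params):
        # closed form x* = b_X/l_X, m* = (l_X - b_X)/(s + l_X)
        dx, dm = kinetics(MeanFieldState(0.4, 3 / 7, True, "MIXED"), stripe_params)
        assert abs(dx) < 1e-14 and abs(dm) < 1e-14


class TestSteadyStates:
    def test_simplified_regime_has_exactly_three(self, stripe_params):
        states = homogeneous_steady_states(stripe_params)
        assert len(states) == 3
        assert [s.label for s in states] == ["ALL_X", "MIXED", "ALL_M"]
        mixed = states[1]
        assert mixed.x == pytest.approx(0.4)
        assert mixed.m == pytest.approx(3 / 7)

    @pytest.mark.parametrize("l_X,admissible", [
        (0.5, False), (0.99, False), (1.0, True), (1.01, True), (2.5, True),
    ])
    def test_mixed_admissible_iff_lx_at_least_bx(self, stripe_params, l_X, admissible):
        states = homogeneous_steady_states(stripe_params.replace(l_X=l_X))
        assert len(states) == 3
        mixed = next(s for s in states if s.label == "MIXED")
        assert mixed.admissible is admissible
        if not admissible:
            assert mixed.m < 0

    def test_all_returned_states_are_stationary(self, general_params):
        for s in homogeneous_steady_states(general_params):
            dx, dm = kinetics(s, general_params)
            assert abs(dx) < 1e-8 and abs(dm) < 1e-8


class TestJacobian:
    def test_k_zero_matches_homogeneous_jacobian(self, near_threshold_params):
        base = mixed_state(near_threshold_params)
        j_lat = jacobian_k(base, near_threshold_params, 0.0, LATTICE)
        j_con = jacobian_k(base, near_threshold_params, 0.0, CONTINUUM)
        assert np.allclose(j_lat, j_con)
        # finite-difference Jacobian of the homogeneous kinetics
        eps = 1e-7
        for col, (dx_var, dm_var) in enumerate([(eps, 0.0), (0.0, eps)]):
            d_hi = kinetics((base.x + dx_var, base.m + dm_var), near_threshold_params)
            d_lo = kinetics((base.x - dx_var, base.m - dm_var), near_threshold_params)
            fd = (np.array(d_hi) - np.array(d_lo)) / (2 * eps)
            assert np.allclose(j_lat[:, col], fd, atol=1e-6)

    def test_non_stationary_base_rejected(self, stripe_params):
        bad = MeanFieldState(0.5, 0.2, True, "OTHER")
        with pytest.raises(ValueError, match="not stationary"):
            jacobian_k(bad, stripe_params, 0.1)

    def test_mixed_state_stable_homogeneously_near_threshold(self, near_threshold_params):
        # leading eigenvalue of J(0): computed independently from trace and
        # determinant of the 2x2 (value -0.006346 at l_X = 1.0193)
        base = mixed_state(near_threshold_params)
        j = jacobian_k(base, near_threshold_params, 0.0)
        lead = max(np.linalg.eigvals(j).real)
        assert lead == pytest.approx(-0.006346, abs=2e-5)
        assert lead < 0

    @pytest.mark.parametrize("l_X", [1.1, 1.5, 2.5, 3.5])
    def test_uniform_state_stable_at_k0_when_admissible(self, stripe_params, l_X):
        p = stripe_params.replace(l_X=l_X)
        assert growth_rate(p, 0.0, LATTICE) < 0

    def test_lattice_omega_periodic_in_k(self, stripe_params):
        base = mixed_state(stripe_params)
        for k in (0.1, 0.5, 1.2):
            w1 = growth_rate(stripe_params, k, LATTICE, base)
            w2 = growth_rate(stripe_params, k + 2 * math.pi, LATTICE, base)
            assert w1 == pytest.approx(w2, rel=1e-9)

    def test_modes_agree_as_k_to_zero_faster_than_k2(self, stripe_params):
        # the continuum form is the O(a^2) truncation of the lattice form
        base = mixed_state(stripe_params)
        ks = np.array([0.1, 0.05, 0.025, 0.0125])
        gaps = np.array([
            abs(growth_rate(stripe_params, k, LATTICE, base)
                - growth_rate(stripe_params, k, CONTINUUM, base))
            for k in ks
        ])
        ratio = gaps / ks**2
        assert (np.diff(ratio) < 0).all()  # gap/k^2 still decaying: o(k^2)


class TestDispersionExtrema:
    def test_fastest_growing_wavelength_is_about_2h(self, stripe_params):
        mg = max_growth(stripe_params, LATTICE)
        wavelength = 2 * math.pi / mg.k_star
        assert wavelength / stripe_params.h == pytest.approx(2.0, rel=0.1)
        assert mg.omega_star > 0 and not mg.boundary

    def test_growth_sign_flips_across_bifurcation(self, near_threshold_params):
        base = mixed_state(near_threshold_params)
        below = max_growth(near_threshold_params, CONTINUUM, base, h=7.0)
        above = max_growth(near_threshold_params, CONTINUUM, base, h=9.0)
        assert below.omega_star < -1e-3
        assert above.omega_star > 1e-3


class TestCriticalH:
    def test_near_threshold_bifurcation_at_h8(self, near_threshold_params):
        res = critical_h(near_threshold_params, CONTINUUM)
        assert isinstance(res, BifurcationPoint)
        assert round(res.h_T) == 8

    def test_strong_activation_point(self, stripe_params):
        # independent closed form: double root of the determinant quadratic
        res = critical_h(stripe_params, CONTINUUM)
        assert res.h_T == pytest.approx(1.8115, rel=1e-3)
        assert res.lambda_T / res.h_T == pytest.approx(2.204, rel=1e-3)

    def test_closed_form_agrees_with_bisection(self, stripe_params):
        for l_X in (1.0193, 1.5, 2.5, 3.5):
            p = stripe_params.replace(l_X=l_X)
            cf = critical_h_closed_form(p)
            bi = critical_h(p, CONTINUUM)
            assert abs(cf.h_T - bi.h_T) / cf.h_T < 1e-4
            assert abs(cf.k_T - bi.k_T) / cf.k_T < 1e-4

    def test_h_T_decreases_with_activation_strength(self, stripe_params):
        # stronger long-range activation destabilises sooner
        h_ts = [critical_h_closed_form(stripe_params.replace(l_X=l)).h_T
                for l in (1.02, 1.5, 2.5, 3.5)]
        assert all(a > b for a, b in zip(h_ts, h_ts[1:]))

    def test_no_bifurcation_when_mixed_inadmissible(self, stripe_params):
        res = critical_h(stripe_params.replace(l_X=0.5), CONTINUUM)
        assert isinstance(res, NoTuringBifurcation)

    def test_omega_sign_check_around_h_T(self, stripe_params):
        res = critical_h_closed_form(stripe_params)
        base = mixed_state(stripe_params)
        assert max_growth(stripe_params, CONTINUUM, base, h=res.h_T - 0.1).omega_star < 0
        assert max_growth(stripe_params, CONTINUUM, base, h=res.h_T + 0.1).omega_star > 0


class TestBifurcationDiagram:
    def test_markers_and_values(self, stripe_params):
        df = bifurcation_diagram([0.5, 1.0193], stripe_params)
        row_low = df[df.l_X == 0.5].iloc[0]
        assert not row_low.bifurcation and math.isnan(row_low.h_T)
        row = df[df.l_X == 1.0193].iloc[0]
        assert row.h_T == pytest.approx(8.0, abs=0.01)
        assert row.half_lambda == pytest.approx(5.25, abs=0.01)


class TestLatticeMeanFieldIntegration:
    def test_mixed_fixed_point_stays_homogeneous(self, stripe_params):
        base = mixed_state(stripe_params)
        n = 64
        x, m = integrate_lattice_meanfield(
            np.full(n, base.x), np.full(n, base.m), stripe_params, t_end=20.0)
        assert np.allclose(x, base.x, atol=1e-6)
        assert np.allclose(m, base.m, atol=1e-6)

    def test_noisy_initial_field_selects_wavelength_2h(self, stripe_params):
        rng = np.random.default_rng(0)
        n, base = 200, mixed_state(stripe_params)
        x0 = np.full(n, base.x) + 0.01 * (rng.random(n) - 0.5)
        m0 = np.full(n, base.m) + 0.01 * (rng.random(n) - 0.5)
        x, m = integrate_lattice_meanfield(x0, m0, stripe_params, t_end=300.0)
        spec = structure_factor(m)
        predicted = 2 * math.pi / max_growth(stripe_params, LATTICE).k_star
        assert spec.peak_wavelength == pytest.approx(predicted, rel=0.15)
        # bounds hold to integration tolerance (no clipping applied)
        assert (x >= -1e-9).all() and (m >= -1e-9).all()
        assert (x + m <= 1 + 1e-9).all()

    def test_weak_activation_converges_to_all_x(self, stripe_params):
        p = stripe_params.replace(l_X=0.5)
        x, m = integrate_lattice_meanfield(
            np.full(50, 0.3), np.full(50, 0.3), p, t_end=200.0)
        assert np.allclose(x, 1.0, atol=1e-4)
        assert np.allclose(m, 0.0, atol=1e-4)

    def test_invalid_initial_fields_rejected(self, stripe_params):
        with pytest.raises(ValueError):
            integrate_lattice_meanfield(np.full(10, 0.7), np.full(10, 0.7),
                                        stripe_params, 1.0)
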