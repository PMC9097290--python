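"""Elastic-constant extraction and persistence-length estimators."""

import math

import numpy as np
import pytest

from duplexcg import elasticity as el, fixtures
from duplexcg.constants import CONSTANTS
from duplexcg.elasticity import FitError, InversionError


class TestLinearMC:
    def test_exact_line_zero_error(self):
        x = np.arange(8.0)
        fit = el.fit_linear_mc(x, 3 * x - 2)
        assert fit.slope == pytest.approx(3.0)
        assert fit.intercept == pytest.approx(-2.0)
        assert fit.slope_err == 0.0

    def test_error_scales_with_dy(self):
        x = np.arange(10.0)
        y = 2 * x + 1
        e1 = el.fit_linear_mc(x, y, 0.1, n_draws=4000, seed=0).slope_err
        e2 = el.fit_linear_mc(x, y, 0.4, n_draws=4000, seed=0).slope_err
        assert e2 == pytest.approx(4 * e1, rel=0.1)

    def test_matches_weighted_least_squares_sigma(self):
        x = np.arange(10.0)
        y = 2 * x + 1
        dy = 0.3
        fit = el.fit_linear_mc(x, y, dy, n_draws=10_000, seed=1)
        sxx = np.sum((x - x.mean()) ** 2)
        assert fit.slope_err == pytest.approx(dy / math.sqrt(sxx), rel=0.02)

    def test_too_few_points(self):
        with pytest.raises(FitError):
            el.fit_linear_mc([1.0, 2.0], [1.0, 2.0])


class TestStretchTorsionRoute:
    def test_closed_form_slope_inversion(self):
        m = el.extract_stretch_torsion_constants(0.013, 3.25e-3, 0.0333125, 13.0)
        assert m.S_eff == pytest.approx(1000.0, abs=1e-10)
        assert m.C == pytest.approx(400.0, abs=1e-9)
        assert m.g == pytest.approx(-100.0, abs=1e-9)

    def test_forward_inverse_round_trip_exact(self):
        for S_eff, C, g in [(1000, 400, -100), (800, 300, 50), (1500, 500, -200)]:
            tab0 = fixtures.generate_rod_response(
                S_eff, C, g, 13.0, 24.0, forces=np.arange(0, 41, 5.0), torques=[0.0])
            tabf = fixtures.generate_rod_response(
                S_eff, C, g, 13.0, 24.0, forces=[2.0], torques=np.arange(0, 31, 5.0))
            m = el.extract_stretch_torsion_from_data(
                tab0.f_pN, tab0.L_nm, tabf.tau_pN_nm, tabf.L_nm, tabf.theta_rad)
            assert m.S_eff == pytest.approx(S_eff, abs=1e-8)
            assert m.C == pytest.approx(C, abs=1e-8)
            assert m.g == pytest.approx(g, abs=1e-8)

    def test_decoupled_limit(self):
        m = el.extract_stretch_torsion_constants(0.013, 0.0, 0.0325, 13.0)
        assert m.g == 0.0
        assert m.C == pytest.approx(13.0 / 0.0325)

    def test_positive_A3_means_negative_g(self):
        # extension grows with torque <=> overwinding coupling (g < 0)
        m = el.extract_stretch_torsion_constants(0.013, 1e-3, 0.0325, 13.0)
        assert m.g < 0
        m2 = el.extract_stretch_torsion_constants(0.013, -1e-3, 0.0325, 13.0)
        assert m2.g > 0

    def test_inconsistent_slopes_raise(self):
        with pytest.raises(InversionError):
            el.extract_stretch_torsion_constants(0.013, 0.05, 0.01, 13.0)


class TestBenchmarkRoute:
    def test_round_trip_with_equipartition_variance(self):
        S_eff, C, g, L0, theta0 = 1000.0, 400.0, -100.0, 13.0, 24.0
        tab = fixtures.generate_rod_response(
            S_eff, C, g, L0, theta0, forces=np.arange(1, 21, 1.0), torques=[0.0])
        var = CONSTANTS.kB_pN_nm * 300.0 * L0 / C
        m = el.extract_benchmark_constants(tab.f_pN.values, tab.L_nm.values,
                                           tab.theta_rad.values, var)
        assert m.S_eff == pytest.approx(S_eff, abs=1e-8)
        assert m.C == pytest.approx(C, abs=1e-8)
        assert m.g == pytest.approx(g, abs=1e-8)
        assert m.L0 == pytest.approx(L0)
        assert m.theta0 == pytest.approx(theta0)

    def test_twist_variance_value(self):
        # var(dtheta) = kB T L0 / C with the package's constants
        var = CONSTANTS.kB_pN_nm * 300.0 * 13.0 / 400.0
        assert var == pytest.approx(0.1345, abs=5e-4)
        assert el.twist_variance_modulus(var, 13.0, 300.0) == pytest.approx(400.0)

    def test_zero_A2_gives_zero_g(self):
        tab = fixtures.generate_rod_response(
            1000.0, 400.0, 0.0, 13.0, 24.0, forces=np.arange(1, 21, 2.0), torques=[0.0])
        var = CONSTANTS.kB_pN_nm * 300.0 * 13.0 / 400.0
        m = el.extract_benchmark_constants(tab.f_pN.values, tab.L_nm.values,
                                           tab.theta_rad.values, var)
        assert m.g == pytest.approx(0.0, abs=1e-10)


class TestCrookednessStiffness:
    def test_round_trip(self):
        f = np.array([1.0, 5, 10, 15, 20])
        beta0, k_beta = 0.17, 1600.0
        cb = math.cos(beta0) * (1 + f / k_beta)
        k_est, b0_est, fit = el.crookedness_stiffness(f, cb)
        assert k_est == pytest.approx(k_beta, rel=1e-9)
        assert b0_est == pytest.approx(beta0, rel=1e-9)
        assert fit.intercept == pytest.approx(math.cos(beta0))

    def test_doubling_slope_halves_k(self):
        f = np.array([1.0, 5, 10, 15, 20])
        cb = 0.98 * (1 + f / 1000.0)
        cb2 = 0.98 * (1 + f / 500.0)
        k1, _, _ = el.crookedness_stiffness(f, cb)
        k2, _, _ = el.crookedness_stiffness(f, cb2)
        assert k1 == pytest.approx(2 * k2, rel=1e-9)

    def test_negative_slope_flagged(self):
        f = np.array([1.0, 5, 10, 15, 20])
        with pytest.raises(FitError, match="slope"):
            el.crookedness_stiffness(f, 0.98 * (1 - f / 1000.0))


class TestEffectiveTwistModulus:
    def test_plugin_value_and_degenerate(self):
        L0 = 45.0
        C_eff = 300.0
        var = CONSTANTS.kB_pN_nm * 300.0 * L0 / C_eff
        assert el.effective_twist_modulus(var, L0) == pytest.approx(C_eff)
        with pytest.raises(InversionError):
            el.effective_twist_modulus(0.0, L0)

    def test_monotone_with_suppressed_bending(self):
        # synthetic twist ensembles: tension reduces the twist variance
        rng = np.random.default_rng(0)
        L0 = 45.0
        theta_low_f = rng.normal(0, 0.30, 40_000)
        theta_high_f = rng.normal(0, 0.22, 40_000)
        c_low = el.effective_twist_modulus(theta_low_f.var(), L0)
        c_high = el.effective_twist_modulus(theta_high_f.var(), L0)
        assert c_high > c_low


class TestTangentsAndPersistence:
    def test_straight_chain_tangents(self):
        centers = np.outer(np.arange(30.0), [0, 0, 1.0])
        t, l = el.tangent_vectors(centers, half_window=5)
        assert np.allclose(t, [0, 0, 1])
        assert l == pytest.approx(1.0)
        assert np.allclose(np.linalg.norm(t, axis=1), 1.0)

    def test_helix_tangents_align_with_axis(self, helix21):
        from duplexcg import geometry

        _, xi, _, _, _ = geometry.frame_points(helix21)
        t, _ = el.tangent_vectors(xi, half_window=5)
        assert np.all(t[:, 2] > 0.99)

    def test_chain_too_short(self):
        with pytest.raises(FitError):
            el.tangent_vectors(np.zeros((10, 3)), half_window=5)

    def test_wlc_correlation_at_lp(self):
        pos, tan = fixtures.generate_wlc_ensemble(4000, 160, 0.5, 25.0, seed=2)
        c = el._mean_tangent_correlation(tan, 60)
        k = int(round(25.0 / 0.5))  # lag with s = l_p
        se = 1.0 / math.sqrt(4000)
        assert abs(c[k] - math.exp(-1)) < 3 * se

    def test_wlc_recovery_and_straight_ground_state(self):
        pos, _ = fixtures.generate_wlc_ensemble(10_000, 120, 0.34, 50.0, seed=4)
        res = el.persistence_decomposition(pos, None, half_window=5)
        assert res.l_p == pytest.approx(50.0, rel=0.03)
        assert math.isinf(res.l_s)
        assert res.l_d == pytest.approx(res.l_p)
        assert any("static" in f for f in res.flags)

    def test_harmonic_relation_with_curved_ground_state(self):
        pos, _ = fixtures.generate_wlc_ensemble(3000, 120, 0.34, 50.0, seed=4)
        ground, _ = fixtures.generate_wlc_ensemble(1, 120, 0.34, 300.0, seed=9)
        res = el.persistence_decomposition(pos, ground[0], half_window=5)
        assert 1.0 / res.l_p == pytest.approx(1.0 / res.l_s + 1.0 / res.l_d,
                                              rel=0.01)

    def test_frozen_trajectory_has_no_dynamic_contribution(self):
        ground, _ = fixtures.generate_wlc_ensemble(1, 120, 0.34, 80.0, seed=12)
        frames = np.repeat(ground, 50, axis=0)
        res = el.persistence_decomposition(frames, ground[0], half_window=5)
        assert np.allclose(res.c_p, res.c_s, atol=1e-12)
        assert math.isinf(res.l_d)
        assert res.l_p == pytest.approx(res.l_s)
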