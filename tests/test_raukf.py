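"""Unscented filter primitives and conductance estimation."""

import numpy as np
import pytest

from olmcell.raukf import (RAUKFConfig, adapt_noise, magnitude_init,
                           make_observation, percent_difference, poor_theta,
                           predict, psd_repair, run_raukf, sigma_points,
                           theta_from_model, unscented_transform, update)

CFG = RAUKFConfig()


class TestSigmaPoints:
    def test_scalar_points_symmetric(self):
        pts, wm, wc = sigma_points(np.array([2.0]), np.array([[1.0]]), CFG)
        assert pts[0, 0] == 2.0
        assert pts[1, 0] - 2.0 == pytest.approx(-(pts[2, 0] - 2.0))

    def test_weighted_reconstruction_of_mean_and_cov(self, rng):
        n = 5
        A = rng.normal(size=(n, n))
        P = A @ A.T + n * np.eye(n)
        mean = rng.normal(size=n)
        pts, wm, wc = sigma_points(mean, P, CFG)
        m2, P2 = unscented_transform(pts, wm, wc)
        np.testing.assert_allclose(m2, mean, atol=1e-8)
        np.testing.assert_allclose(P2, P, rtol=1e-6, atol=1e-8)

    def test_scaling_preserves_mean_reconstruction(self, rng):
        mean = rng.normal(size=3)
        P = np.eye(3)
        for alpha in (1e-3, 0.5, 1.0):
            pts, wm, wc = sigma_points(mean, P, RAUKFConfig(alpha=alpha))
            np.testing.assert_allclose(wm @ pts, mean, atol=1e-9)

    def test_indefinite_cov_repaired_or_rejected(self):
        P = np.array([[1.0, 0.0], [0.0, -1.0]])
        fixed = psd_repair(P)
        assert np.linalg.eigvalsh(fixed).min() >= 0


class TestPredictUpdate:
    def test_identity_dynamics_with_zero_Q(self, rng):
        x = rng.normal(size=4)
        P = np.diag([1.0, 2.0, 3.0, 4.0])
        xp, Pp = predict(x, P, np.zeros((4, 4)), lambda pts: pts, CFG)
        np.testing.assert_allclose(xp, x, atol=1e-9)
        np.testing.assert_allclose(Pp, P, rtol=1e-6, atol=1e-9)

    def test_linear_dynamics_closed_form(self, rng):
        A = np.array([[0.9, 0.1], [0.0, 0.8]])
        Q = 0.01 * np.eye(2)
        x = np.array([1.0, -1.0])
        P = np.array([[0.5, 0.1], [0.1, 0.3]])
        xp, Pp = predict(x, P, Q, lambda pts: pts @ A.T, CFG)
        np.testing.assert_allclose(xp, A @ x, atol=1e-8)
        np.testing.assert_allclose(Pp, A @ P @ A.T + Q, rtol=1e-6, atol=1e-8)

    def test_observed_update_reduces_variance(self):
        x = np.array([0.0, 1.0])
        P = np.eye(2)
        x2, P2, nu, S, K = update(x, P, y=0.5, R=0.5)
        assert nu == 0.5
        assert P2[0, 0] < P[0, 0]
        x3, P3, nu3, _, _ = update(x, P, y=0.0, R=0.5)
        np.testing.assert_allclose(x3, x)  # y equals prediction

    def test_ukf_equals_kalman_on_linear_gaussian_system(self, rng):
        """On linear dynamics the unscented pass IS the Kalman filter."""
        n = 3
        A = np.array([[0.9, 0.05, 0.0], [0.0, 0.85, 0.1], [0.0, 0.0, 0.95]])
        Q = 0.02 * np.eye(n)
        R = 0.1
        H = np.zeros(n)
        H[0] = 1.0
        x_true = rng.normal(size=n)
        xs_u = rng.normal(size=n)
        Ps_u = np.eye(n)
        xs_k, Ps_k = xs_u.copy(), Ps_u.copy()
        for _ in range(100):
            x_true = A @ x_true + rng.multivariate_normal(np.zeros(n), Q)
            y = x_true[0] + np.sqrt(R) * rng.normal()
            # unscented pass
            xp, Pp = predict(xs_u, Ps_u, Q, lambda pts: pts @ A.T, CFG)
            xs_u, Ps_u, _, _, _ = update(xp, Pp, y, R)
            # exact Kalman recursion
            xk = A @ xs_k
            Pk = A @ Ps_k @ A.T + Q
            S = Pk[0, 0] + R
            K = Pk[:, 0] / S
            xs_k = xk + K * (y - xk[0])
            Ps_k = Pk - np.outer(K, K) * S
        np.testing.assert_allclose(xs_u, xs_k, rtol=1e-8, atol=1e-10)
        np.testing.assert_allclose(Ps_u, Ps_k, rtol=1e-6, atol=1e-10)


class TestAdaptNoise:
    def test_no_fault_leaves_noise_unchanged(self):
        Q = np.eye(3)
        Qa, Ra, fault, phi = adapt_noise(nu=0.1, S=1.0, K=np.ones(3) / 3,
                                         Q=Q, R=1.0, cfg=CFG)
        assert not fault
        assert Ra == 1.0
        np.testing.assert_array_equal(Qa, Q)

    def test_saturated_fault_replaces_Q_estimate(self):
        """A huge fault drives the weight to 1: Q becomes K nu^2 K'."""
        Q = 1e-6 * np.eye(2)
        K = np.array([0.5, 0.1])
        nu = 100.0
        Qa, Ra, fault, _ = adapt_noise(nu=nu, S=1.0, K=K, Q=Q, R=1.0, cfg=CFG)
        assert fault
        np.testing.assert_allclose(Qa, np.outer(K, K) * nu ** 2, rtol=1e-9)

    def test_underestimated_R_is_pulled_toward_truth(self):
        """With innovations carrying ten times the assumed measurement
        variance, the fault-triggered updates close most of the gap."""
        rng = np.random.default_rng(4)
        true_var = 1.0
        R = 0.01
        Q = np.zeros((2, 2))
        bias0 = abs(R - true_var)
        nu2_avg = None
        for _ in range(2000):
            nu = np.sqrt(true_var) * rng.standard_normal()
            nu2_avg = (nu * nu if nu2_avg is None
                       else 0.95 * nu2_avg + 0.05 * nu * nu)
            Q, R, _, _ = adapt_noise(nu, R, np.zeros(2), Q, R, cfg=CFG,
                                     nu2_avg=nu2_avg)
        assert abs(R - true_var) < 0.5 * bias0


class TestPercentDifference:
    def test_exact_match_is_zero(self):
        assert percent_difference(1.0, 1.0) == 0.0

    def test_table_style_values(self):
        assert percent_difference(1.89e-5, 1.91e-5) == pytest.approx(1.047, abs=0.01)

    def test_scale_invariance_and_zero_reference(self):
        assert percent_difference(2.2, 2.0) == percent_difference(4.4, 4.0)
        assert np.isnan(percent_difference(1.0, 0.0))


class TestRunRaukf:
    def test_magnitude_initialization_rules(self):
        theta = np.array([1.91e-5, 4.33e-3, 7.31e-3, 4.85e-3])
        np.testing.assert_allclose(poor_theta(theta),
                                   [1e-5, 1e-3, 1e-3, 1e-3])
        P, Q = magnitude_init(theta)
        np.testing.assert_allclose(P, [1e-10, 1e-6, 1e-6, 1e-6])
        assert np.all(Q < P)

    def test_misaligned_inputs_rejected(self, model):
        with pytest.raises(ValueError):
            run_raukf(np.zeros(10), np.zeros(9), np.ones(4), model)

    def test_optimal_start_stays_near_truth_on_short_record(self, model):
        """Starting at the true conductances, a single protocol repeat
        leaves every estimate within a few percent."""
        from olmcell.stimuli import RAUKFTrain
        truth = theta_from_model(model)
        cfg1 = RAUKFTrain(repeats=1)
        obs, u, _ = make_observation(model, seed=5, train_cfg=cfg1)
        traj = run_raukf(obs, u, truth.copy(), model, reference=truth,
                         final_average_ms=686.0)
        assert np.nanmax(traj.percent_diff) < 5.0
        assert traj.theta.shape[1] == 4
        assert np.all(traj.final_stderr > 0)
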