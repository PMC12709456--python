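"""Linearised Hopf machinery: Jacobian, Lyapunov covariance, lagged model
covariances and their empirical counterparts."""

import numpy as np
import pytest

from trophicbrain.gec import compute_empirical_stats
from trophicbrain.hopf import (
    HopfParameters,
    build_jacobian,
    estimate_node_frequencies,
    lagged_model_covariance,
    model_statistics,
    normalize_shifted,
    solve_stationary_covariance,
)
from trophicbrain.synthetic import simulate_linear_sde
from .conftest import random_coupling


class TestJacobian:
    def test_single_node_closed_form(self):
        J = build_jacobian(np.zeros((1, 1)),
                           HopfParameters(a=-0.5, omega=1.0, sigma=0.1))
        assert np.allclose(J, [[-0.5, -1.0], [1.0, -0.5]])
        eig = sorted(np.linalg.eigvals(J), key=lambda z: z.imag)
        assert np.allclose(eig, [-0.5 - 1j, -0.5 + 1j])

    def test_uncoupled_block_is_diag_a(self):
        a = np.array([-0.3, -0.7])
        J = build_jacobian(np.zeros((2, 2)), HopfParameters(a=a, omega=1.0, sigma=0.1))
        assert np.allclose(J[:2, :2], np.diag(a))

    def test_omega_blocks_independent_of_coupling(self, rng):
        params = HopfParameters(a=-0.2, omega=np.array([0.3, 0.4, 0.5]), sigma=0.1)
        C = random_coupling(3, rng)
        J1 = build_jacobian(C, params)
        J2 = build_jacobian(2 * C, params)
        assert np.allclose(J1[:3, 3:], J2[:3, 3:])
        assert np.allclose(J1[3:, :3], np.diag([0.3, 0.4, 0.5]))

    def test_coupling_orientation_row_receives_column_sends(self):
        # C[m, n] = influence of m over n enters region n's equation
        C = np.zeros((2, 2))
        C[0, 1] = 0.1
        J = build_jacobian(C, HopfParameters(a=-0.5, omega=0.0, sigma=0.1))
        assert J[1, 0] == pytest.approx(0.1)  # input to node 1 from node 0
        assert J[0, 1] == pytest.approx(0.0)
        assert J[1, 1] == pytest.approx(-0.5 - 0.1)

    def test_positive_a_rejected(self):
        with pytest.raises(ValueError):
            build_jacobian(np.zeros((1, 1)), HopfParameters(a=0.1, omega=1.0, sigma=0.1))


class TestStationaryCovariance:
    def test_scalar_ou_closed_form(self, ou_params):
        J = build_jacobian(np.zeros((1, 1)), ou_params)
        K = solve_stationary_covariance(J, ou_params.sigma)
        assert np.allclose(np.diag(K), 0.1**2 / (2 * 0.5))

    def test_quadratic_noise_scaling(self, rng):
        params = HopfParameters(a=-0.3, omega=0.2, sigma=0.05)
        J = build_jacobian(random_coupling(4, rng), params)
        K1 = solve_stationary_covariance(J, 0.05)
        K3 = solve_stationary_covariance(J, 0.15)
        assert np.allclose(K3, 9 * K1)

    def test_psd_and_residual(self, rng):
        J = build_jacobian(random_coupling(5, rng),
                           HopfParameters(a=-0.2, omega=0.4, sigma=0.02))
        K = solve_stationary_covariance(J, 0.02)
        assert np.allclose(K, K.T)
        assert np.linalg.eigvalsh(K).min() > -1e-10

    def test_matches_brute_force_simulation(self):
        """Lyapunov solution vs long Euler-Maruyama simulation (oracle)."""
        rng = np.random.default_rng(5)
        C = random_coupling(4, rng, scale=0.1)
        params = HopfParameters(a=-0.2, omega=np.array([0.2, 0.3, 0.4, 0.5]),
                                sigma=0.05)
        J = build_jacobian(C, params)
        K = solve_stationary_covariance(J, params.sigma)
        n_rep, n_steps = 64, 16000
        traj = simulate_linear_sde(J, params.sigma, n_steps=n_steps, dt=0.05,
                                   n_replicas=n_rep, burn_in_steps=2000, seed=9)
        # replica-wise covariances give the Monte Carlo standard error
        covs = np.array([np.cov(traj[r], ddof=1) for r in range(n_rep)])
        mean_cov = covs.mean(axis=0)
        se = covs.std(axis=0, ddof=1) / np.sqrt(n_rep)
        assert np.all(np.abs(mean_cov - K) < 3.5 * se + 1e-4)


class TestLaggedCovariance:
    def test_zero_lag_recovers_stationary(self, rng):
        params = HopfParameters(a=-0.3, omega=0.3, sigma=0.05)
        J = build_jacobian(random_coupling(3, rng), params)
        K = solve_stationary_covariance(J, params.sigma)
        KSf, KSr = lagged_model_covariance(J, K, 0.0)
        assert np.allclose(KSf, K)
        assert np.allclose(KSr, K)

    def test_scalar_ou_exponential_decay(self, ou_params):
        J = build_jacobian(np.zeros((1, 1)), ou_params)
        K = solve_stationary_covariance(J, ou_params.sigma)
        KSf, _ = lagged_model_covariance(J, K, 2.0)
        assert KSf[0, 0] == pytest.approx(np.exp(-0.5 * 2.0) * K[0, 0], rel=1e-10)

    def test_detailed_balance_of_symmetric_system(self, rng):
        A = random_coupling(4, rng)
        C = 0.5 * (A + A.T)
        np.fill_diagonal(C, 0.0)
        params = HopfParameters(a=-0.2, omega=0.0, sigma=0.05)
        J = build_jacobian(C, params)
        K = solve_stationary_covariance(J, params.sigma)
        KSf, KSr = lagged_model_covariance(J, K, 3.0)
        assert np.allclose(KSf, KSr, atol=1e-12)


class TestNormalization:
    def test_self_normalisation_unit_diagonal(self, rng):
        params = HopfParameters(a=-0.3, omega=0.2, sigma=0.05)
        J = build_jacobian(random_coupling(3, rng), params)
        K = solve_stationary_covariance(J, params.sigma)
        FS = normalize_shifted(K, K, 3)
        assert np.allclose(np.diag(FS), 1.0)

    def test_hand_computed_example(self):
        K0 = np.diag([4.0, 9.0])
        KS = np.array([[4.0, 3.0], [3.0, 9.0]])
        FS = normalize_shifted(KS, K0, 2)
        assert np.allclose(FS, [[1.0, 0.5], [0.5, 1.0]])

    def test_joint_scale_invariance(self, rng):
        K0 = np.diag([1.0, 2.0, 3.0])
        KS = rng.standard_normal((3, 3))
        assert np.allclose(normalize_shifted(7 * KS, 7 * K0, 3),
                           normalize_shifted(KS, K0, 3))

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            normalize_shifted(np.eye(2), np.diag([1.0, 0.0]), 2)


class TestFrequencyEstimation:
    def test_recovers_sinusoid_frequency(self, rng):
        tr = 2.0
        t = np.arange(600) * tr
        ts = np.vstack([np.sin(2 * np.pi * 0.05 * t) + 0.05 * rng.standard_normal(600),
                        np.sin(2 * np.pi * 0.03 * t) + 0.05 * rng.standard_normal(600)])
        omega = estimate_node_frequencies(ts, tr)
        assert omega[0] == pytest.approx(2 * np.pi * 0.05, rel=0.1)
        assert omega[1] == pytest.approx(2 * np.pi * 0.03, rel=0.15)

    def test_identical_channels_identical_estimates(self, rng):
        x = rng.standard_normal(400)
        omega = estimate_node_frequencies(np.vstack([x, x]), 3.0)
        assert omega[0] == omega[1]

    def test_estimates_confined_to_band(self, rng):
        ts = rng.standard_normal((4, 400))
        with np.errstate(all="ignore"):
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                omega = estimate_node_frequencies(ts, 3.0, band_hz=(0.008, 0.08))
        assert np.all(omega >= 2 * np.pi * 0.008 - 1e-12)
        assert np.all(omega <= 2 * np.pi * 0.08 + 1e-12)

    def test_band_beyond_nyquist_rejected(self, rng):
        with pytest.raises(ValueError):
            estimate_node_frequencies(rng.standard_normal((2, 200)), 3.0,
                                      band_hz=(0.01, 0.4))


class TestAnalyticEmpiricalAgreement:
    def test_model_statistics_match_simulated_lagged_correlations(self):
        """Oracle equivalence: the analytic FC/FS of a small network agree
        elementwise with the empirical lagged correlations of a long
        simulated linear trajectory sampled at TR."""
        rng = np.random.default_rng(3)
        C = random_coupling(4, rng, scale=0.08)
        params = HopfParameters(a=-0.1, omega=2 * np.pi *
                                np.array([0.03, 0.04, 0.05, 0.06]), sigma=0.02,
                                tau=1.0)
        tr = 3.0
        fc_a, fsf_a, fsr_a = model_statistics(C, params, tr)

        from trophicbrain.hopf import build_jacobian

        J = build_jacobian(C, params)
        dt = 0.025
        stride = int(tr / dt)
        n_rep = 96
        traj = simulate_linear_sde(J, params.sigma, n_steps=60_000, dt=dt,
                                   n_replicas=n_rep, burn_in_steps=4000, seed=17)
        fcs, fsfs = [], []
        for r in range(n_rep):
            X = traj[r, :4, ::stride]
            st = compute_empirical_stats(X, 1)
            fcs.append(st.fc)
            fsfs.append(st.fs_forward)
        fc_e = np.mean(fcs, axis=0)
        fsf_e = np.mean(fsfs, axis=0)
        assert np.max(np.abs(fc_e - fc_a)) < 0.02
        assert np.max(np.abs(fsf_e - fsf_a)) < 0.02
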