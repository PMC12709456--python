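"""GEC estimation: empirical statistics and the pseudo-gradient fit."""

import numpy as np
import pytest
from scipy.stats import spearmanr

import trophicbrain as tb
from trophicbrain.gec import (
    EmpiricalStats,
    FitConfig,
    HopfGEC,
    average_stats,
    compute_empirical_stats,
    empirical_fc,
    empirical_shifted_correlation,
    fit_cohort,
    nonreversibility_reliability,
)
from trophicbrain.hopf import HopfParameters
from .conftest import random_coupling

TR = 3.0


def analytic_stats(C, params):
    fc, fsf, fsr = tb.model_statistics(C, params, TR)
    return EmpiricalStats(fc=fc, fs_forward=fsf, fs_reversal=fsr)


def jittered_hierarchy(n, seed):
    """Known coupling with untied planted levels (weight jitter)."""
    rng = np.random.default_rng(seed)
    net = tb.generate_hierarchical_coupling(n, 3, 0.04, 0.01, 0.9, seed=seed)
    C = np.clip(net.coupling * (1 + 0.3 * rng.standard_normal((n, n))), 0, None)
    np.fill_diagonal(C, 0.0)
    return C


class TestEmpiricalFC:
    def test_duplicated_channel_perfectly_correlated(self, rng):
        x = rng.standard_normal(200)
        fc = empirical_fc(np.vstack([x, x, rng.standard_normal(200)]))
        assert fc[0, 1] == pytest.approx(1.0)

    def test_sign_flip_anticorrelated(self, rng):
        x = rng.standard_normal(200)
        fc = empirical_fc(np.vstack([x, -x]))
        assert fc[0, 1] == pytest.approx(-1.0)

    def test_independent_channels_near_zero(self, rng):
        T = 20_000
        fc = empirical_fc(rng.standard_normal((2, T)))
        assert abs(fc[0, 1]) < 3 / np.sqrt(T)

    def test_constant_channel_rejected(self):
        with pytest.raises(ValueError):
            empirical_fc(np.vstack([np.ones(50), np.arange(50.0)]))


class TestShiftedCorrelation:
    def test_zero_lag_equals_fc(self, rng):
        ts = rng.standard_normal((4, 300))
        assert np.allclose(empirical_shifted_correlation(ts, 0), empirical_fc(ts),
                           atol=1e-12)

    def test_white_noise_lagged_near_zero(self, rng):
        T = 20_000
        fs = empirical_shifted_correlation(rng.standard_normal((3, T)), 1)
        off = ~np.eye(3, dtype=bool)
        assert np.max(np.abs(fs[off])) < 3 / np.sqrt(T)

    def test_reversal_equals_forward_transposed(self, rng):
        ts = rng.standard_normal((5, 400))
        fwd = empirical_shifted_correlation(ts, 2)
        rev = empirical_shifted_correlation(ts, 2, reversed=True)
        assert np.allclose(rev, fwd.T, atol=1e-10)

    def test_lag_orientation_row_leads(self, rng):
        # channel 1 is channel 0 delayed by one sample: x1(t+1) = x0(t),
        # so FS[0, 1] = corr(x0(t), x1(t+1)) must be ~1
        x = rng.standard_normal(5000)
        ts = np.vstack([x[1:], x[:-1]])
        fs = empirical_shifted_correlation(ts, 1)
        assert fs[0, 1] > 0.99
        assert fs[1, 0] < 0.1

    def test_exhausted_series_rejected(self, rng):
        with pytest.raises(ValueError):
            empirical_shifted_correlation(rng.standard_normal((2, 10)), 9)


class TestReliabilityShrinkage:
    def test_reliability_in_unit_interval(self, rng):
        ts = rng.standard_normal((6, 200))
        assert 0.0 <= nonreversibility_reliability(ts) <= 1.0

    def test_shrinkage_preserves_symmetric_part(self, rng):
        ts = rng.standard_normal((5, 300))
        raw = compute_empirical_stats(ts, 1, shrink=False)
        shr = compute_empirical_stats(ts, 1, shrink=True)
        assert np.allclose(0.5 * (raw.fs_forward + raw.fs_reversal),
                           0.5 * (shr.fs_forward + shr.fs_reversal), atol=1e-12)
        raw_anti = 0.5 * (raw.fs_forward - raw.fs_reversal)
        shr_anti = 0.5 * (shr.fs_forward - shr.fs_reversal)
        assert np.allclose(shr_anti, shr.reliability * raw_anti, atol=1e-12)

    def test_strong_signal_retains_high_reliability(self):
        rng = np.random.default_rng(5)
        net = tb.generate_hierarchical_coupling(8, 3, 0.12, 0.03, 0.9, seed=5)
        C = np.clip(net.coupling * (1 + 0.2 * rng.standard_normal((8, 8))), 0, None)
        np.fill_diagonal(C, 0.0)
        ts = tb.simulate_hopf_bold(C, a=-0.02, omega=2 * np.pi * 0.04,
                                   sigma=0.02, n_timepoints=8000,
                                   tr_seconds=3.0, seed=6, linear=True)
        assert nonreversibility_reliability(ts) > 0.8


class TestFitBasics:
    params = HopfParameters(a=-0.05, omega=2 * np.pi * 0.04, sigma=0.01, tau=1.0)

    def test_zero_rates_return_init(self, rng):
        C = random_coupling(5, rng)
        stats = analytic_stats(C, self.params)
        mask = np.ones((5, 5)) - np.eye(5)
        cfg = FitConfig(alpha=0.0, varsigma=0.0, max_iter=200, patience=20)
        init = random_coupling(5, rng, scale=0.02)
        res = HopfGEC(stats, mask, self.params, TR, config=cfg).fit(init=init)
        assert np.allclose(res.coupling, init * (mask > 0))
        assert res.converged

    def test_masking_enforced_exactly(self, rng):
        C = jittered_hierarchy(6, 2)
        stats = analytic_stats(C, self.params)
        mask = ((C + C.T) > 0).astype(float)
        mask[0, :] = 0.0  # forbid all outgoing edges of node 0
        cfg = FitConfig(max_iter=300, patience=50)
        res = HopfGEC(stats, mask, self.params, TR, config=cfg).fit()
        assert np.all(res.coupling[mask == 0] == 0)
        assert np.all(res.coupling >= 0)

    def test_best_error_non_increasing_on_trace(self, rng):
        C = jittered_hierarchy(6, 3)
        stats = analytic_stats(C, self.params)
        mask = ((C + C.T) > 0).astype(float)
        res = HopfGEC(stats, mask, self.params, TR,
                      config=FitConfig(max_iter=500, patience=100)).fit()
        best = np.minimum.accumulate(res.fit_trace[:, 0])
        assert np.all(np.diff(best) <= 1e-15)

    def test_fit_deterministic(self):
        C = jittered_hierarchy(6, 4)
        stats = analytic_stats(C, self.params)
        mask = ((C + C.T) > 0).astype(float)
        cfg = FitConfig(max_iter=300, patience=50)
        r1 = HopfGEC(stats, mask, self.params, TR, config=cfg).fit()
        r2 = HopfGEC(stats, mask, self.params, TR, config=cfg).fit()
        assert np.array_equal(r1.coupling, r2.coupling)

    def test_nan_stats_rejected(self):
        bad = np.full((3, 3), np.nan)
        with pytest.raises(ValueError):
            EmpiricalStats(fc=bad, fs_forward=bad, fs_reversal=bad)

    def test_summary_mentions_convergence(self, rng):
        C = jittered_hierarchy(6, 7)
        stats = analytic_stats(C, self.params)
        mask = ((C + C.T) > 0).astype(float)
        res = HopfGEC(stats, mask, self.params, TR,
                      config=FitConfig(max_iter=150, patience=30)).fit()
        assert "FC fit correlation" in res.summary()


class TestRecovery:
    @pytest.mark.parametrize("n_regions,seed", [(6, 1), (8, 2)])
    def test_noiseless_self_consistency(self, n_regions, seed):
        """Fitting analytic targets generated from a known coupling recovers
        it on the masked entries (r > 0.95) with matching hierarchy."""
        C_true = jittered_hierarchy(n_regions, seed)
        params = HopfParameters(a=-0.02, omega=2 * np.pi * 0.04, sigma=0.01,
                                tau=1.0)
        stats = analytic_stats(C_true, params)
        mask = ((C_true + C_true.T) > 0).astype(float)
        res = HopfGEC(stats, mask, params, TR).fit()
        m = (mask > 0) & ~np.eye(n_regions, dtype=bool)
        r = np.corrcoef(C_true[m], res.coupling[m])[0, 1]
        assert r > 0.95
        sp = spearmanr(tb.trophic_levels(C_true),
                       tb.trophic_levels(res.coupling)).statistic
        assert sp > 0.9

    def test_symmetric_target_yields_less_asymmetric_fit(self):
        C_true = jittered_hierarchy(6, 9)
        C_sym = 0.5 * (C_true + C_true.T)
        params = HopfParameters(a=-0.02, omega=2 * np.pi * 0.04, sigma=0.01,
                                tau=1.0)
        mask = ((C_true + C_true.T) > 0).astype(float)
        cfg = FitConfig(max_iter=1500, patience=200)
        res_asym = HopfGEC(analytic_stats(C_true, params), mask, params, TR,
                           config=cfg).fit()
        res_sym = HopfGEC(analytic_stats(C_sym, params), mask, params, TR,
                          config=cfg).fit()
        assert tb.asymmetry_index(res_sym.coupling) \
            < tb.asymmetry_index(res_asym.coupling)


class TestCohortFit:
    params = HopfParameters(a=-0.02, omega=2 * np.pi * 0.04, sigma=0.01, tau=1.0)

    def test_single_subject_equals_two_sequential_fits(self):
        C = jittered_hierarchy(6, 12)
        stats = analytic_stats(C, self.params)
        mask = ((C + C.T) > 0).astype(float)
        cfg = FitConfig(max_iter=200, patience=40)
        group_res, results = fit_cohort({"s1": stats}, mask, self.params, TR,
                                        config=cfg)
        manual_group = HopfGEC(stats, mask, self.params, TR, config=cfg).fit()
        manual_subj = HopfGEC(stats, mask, self.params, TR, config=cfg).fit(
            init=manual_group.coupling)
        assert np.array_equal(group_res.coupling, manual_group.coupling)
        assert np.array_equal(results["s1"].coupling, manual_subj.coupling)

    def test_identical_subjects_identical_results(self):
        C = jittered_hierarchy(6, 13)
        stats = analytic_stats(C, self.params)
        mask = ((C + C.T) > 0).astype(float)
        cfg = FitConfig(max_iter=200, patience=40)
        _, results = fit_cohort({"a": stats, "b": stats}, mask, self.params, TR,
                                config=cfg)
        assert np.array_equal(results["a"].coupling, results["b"].coupling)

    def test_average_stats_elementwise_mean(self, rng):
        s1 = analytic_stats(jittered_hierarchy(5, 1), self.params)
        s2 = analytic_stats(jittered_hierarchy(5, 2), self.params)
        avg = average_stats([s1, s2])
        assert np.allclose(avg.fc, 0.5 * (s1.fc + s2.fc))
        assert np.allclose(avg.fs_forward, 0.5 * (s1.fs_forward + s2.fs_forward))

    def test_per_subject_failure_does_not_abort(self, monkeypatch):
        C = jittered_hierarchy(5, 3)
        good = analytic_stats(C, self.params)
        bad = analytic_stats(C, self.params)
        bad.explode = True
        mask = ((C + C.T) > 0).astype(float)

        orig_fit = HopfGEC.fit

        def flaky_fit(self, init=None):
            if getattr(self.stats, "explode", False):
                raise RuntimeError("subject-level numerical failure")
            return orig_fit(self, init=init)

        monkeypatch.setattr(HopfGEC, "fit", flaky_fit)
        cfg = FitConfig(max_iter=100, patience=20)
        _, results = fit_cohort({"ok": good, "bad": bad}, mask, self.params, TR,
                                config=cfg)
        assert isinstance(results["bad"], RuntimeError)
        assert not isinstance(results["ok"], Exception)
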