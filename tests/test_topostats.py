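import itertools

import numpy as np
import pytest

from neurotopo import synthetic as syn
from neurotopo import topostats as ts
from neurotopo.containers import ErpSet
from neurotopo.erp import gfp


def brute_covariance_map(data_at_tf, covariate):
    """Loop-wise covariance map, independent of the vectorized engine."""
    v = np.asarray(data_at_tf, float)
    z = (covariate - covariate.mean()) / covariate.std(ddof=1)
    out = np.zeros(v.shape[1])
    for e in range(v.shape[1]):
        col = v[:, e]
        out[e] = np.sum(z * (col - col.mean())) / v.shape[0]
    return out


class TestCovarianceMap:
    def test_recovers_generative_topography(self):
        rng = np.random.default_rng(0)
        w = rng.normal(size=8)
        w -= w.mean()
        x = rng.normal(size=30)
        z = (x - x.mean()) / x.std(ddof=1)
        offset = rng.normal(size=8)
        maps = z[:, None] * w[None, :] + offset[None, :]
        c = ts.covariance_map(maps, x)
        assert np.allclose(c, w * (z @ z) / 30)

    def test_linearity_in_covariate_sign(self):
        rng = np.random.default_rng(1)
        maps = rng.normal(size=(10, 6))
        x = rng.normal(size=10)
        assert np.allclose(ts.covariance_map(maps, -x), -ts.covariance_map(maps, x))

    def test_matches_brute_force(self):
        rng = np.random.default_rng(2)
        maps = rng.normal(size=(9, 5))
        x = rng.normal(size=9)
        assert np.allclose(ts.covariance_map(maps, x), brute_covariance_map(maps, x))

    def test_constant_covariate_rejected(self):
        with pytest.raises(ValueError):
            ts.covariance_map(np.zeros((5, 4)), np.ones(5))


class TestTancovaExhaustiveOracle:
    def test_p_values_equal_full_enumeration(self):
        rng = np.random.default_rng(3)
        S, E, T = 5, 6, 10
        data = rng.standard_normal((S, E, T))
        x = rng.standard_normal(S)
        res = ts.tancova_timewise(data, x, exhaustive=True, duration=1, seed=0)
        assert res.n_permutations == 120
        z = (x - x.mean()) / x.std(ddof=1)
        oracle = np.empty((120, T))
        for i, perm in enumerate(itertools.permutations(range(S))):
            zz = z[list(perm)]
            for t in range(T):
                oracle[i, t] = gfp(brute_covariance_map_perm(data[:, :, t], zz))
        obs = np.array([gfp(brute_covariance_map_perm(data[:, :, t], z)) for t in range(T)])
        p_oracle = (oracle >= obs[None, :]).mean(axis=0)
        assert np.array_equal(p_oracle, res.p_series)


def brute_covariance_map_perm(data_at_tf, z):
    """Covariance map for an already-standardized (permuted) covariate."""
    v = np.asarray(data_at_tf, float)
    out = np.zeros(v.shape[1])
    for e in range(v.shape[1]):
        col = v[:, e]
        out[e] = np.sum(z * (col - col.mean())) / v.shape[0]
    return out


class TestTanovaSession:
    def test_identical_sessions_give_zero_statistic(self):
        rng = np.random.default_rng(4)
        data = rng.standard_normal((6, 5, 8))
        res = ts.tanova_session(data, data.copy(), n_permutations=200, duration=1, seed=0)
        assert np.allclose(res.statistic_series, 0.0)
        assert res.clusters == []

    def test_exhaustive_matches_sign_flip_enumeration(self):
        rng = np.random.default_rng(5)
        S, E, T = 6, 5, 7
        pre = rng.standard_normal((S, E, T))
        post = rng.standard_normal((S, E, T))
        res = ts.tanova_session(pre, post, exhaustive=True, duration=1)
        assert res.n_permutations == 64
        d = post - pre
        stats_all = np.empty((64, T))
        for i, signs in enumerate(itertools.product((1.0, -1.0), repeat=S)):
            m = (np.array(signs)[:, None, None] * d).mean(axis=0)
            stats_all[i] = [gfp(m[:, t]) for t in range(T)]
        obs = np.array([gfp(d.mean(axis=0)[:, t]) for t in range(T)])
        p_oracle = (stats_all >= obs[None, :]).mean(axis=0)
        assert np.array_equal(p_oracle, res.p_series)

    def test_recovers_injected_session_effect(self):
        cov = np.random.default_rng(6).normal(0, 1, 16)
        cfg = syn.ErpSimConfig(n_subjects=16, n_electrodes=20, n_timeframes=60,
                               effect_window=(25, 40), noise_sd=0.5, seed=8)
        pre, post, gt = syn.simulate_erp_set(cfg, cov, sessions=2,
                                             session_effect_strength=3.0)
        res = ts.tanova_session(pre, post, n_permutations=300, duration="fixed", seed=1)
        assert res.clusters, "expected a significant session cluster"
        a, b = res.clusters[0]
        lo, hi = gt["session_effect_window"]
        assert a < hi and b > lo  # overlap with the injected window


@pytest.fixture(scope="module")
def coupled():
    rng = np.random.default_rng(7)
    cov = rng.normal(0.1, 0.1, 18)
    cfg = syn.ErpSimConfig(n_subjects=18, n_electrodes=24, n_timeframes=80,
                           effect_window=(30, 50), coupling_strength=2.0,
                           noise_sd=0.8, seed=9)
    erps, gt = syn.simulate_erp_set(cfg, cov)
    return erps, cov, gt


class TestTancovaRecoveryAndInvariance:
    def test_cluster_overlaps_true_window(self, coupled):
        erps, cov, gt = coupled
        res = ts.tancova_timewise(erps, cov, n_permutations=500, duration="fixed", seed=2)
        assert res.clusters
        a, b = res.clusters[0]
        lo, hi = gt["effect_window"]
        assert a < hi and b > lo

    def test_constant_map_shift_leaves_statistics_unchanged(self, coupled):
        erps, cov, _ = coupled
        res1 = ts.tancova_timewise(erps.data, cov, n_permutations=200, duration=1, seed=3)
        shift = np.random.default_rng(10).normal(size=(1, erps.n_electrodes, 1))
        res2 = ts.tancova_timewise(erps.data + shift, cov, n_permutations=200,
                                   duration=1, seed=3)
        assert np.allclose(res1.statistic_series, res2.statistic_series)
        assert np.array_equal(res1.p_series, res2.p_series)

    def test_covariate_rescaling_leaves_p_unchanged(self, coupled):
        erps, cov, _ = coupled
        res1 = ts.tancova_timewise(erps.data, cov, n_permutations=200, duration=1, seed=4)
        res2 = ts.tancova_timewise(erps.data, 10.0 * cov + 3.0, n_permutations=200,
                                   duration=1, seed=4)
        assert np.allclose(res1.p_series, res2.p_series)

    def test_covariate_sign_flip_leaves_p_unchanged(self, coupled):
        erps, cov, _ = coupled
        res1 = ts.tancova_session_covariate(erps.data, 2 * erps.data, cov,
                                            n_permutations=150, duration=1, seed=5)
        res2 = ts.tancova_session_covariate(erps.data, 2 * erps.data, -cov,
                                            n_permutations=150, duration=1, seed=5)
        assert np.allclose(res1.statistic_series, res2.statistic_series)
        assert np.array_equal(res1.p_series, res2.p_series)

    def test_deterministic_under_seed(self, coupled):
        erps, cov, _ = coupled
        a = ts.tancova_timewise(erps, cov, n_permutations=150, seed=6)
        b = ts.tancova_timewise(erps, cov, n_permutations=150, seed=6)
        assert np.array_equal(a.p_series, b.p_series)
        assert a.clusters == b.clusters
        assert a.duration_threshold_tf == b.duration_threshold_tf

    def test_session_covariate_detects_interaction(self):
        rng = np.random.default_rng(11)
        S, E, T = 20, 16, 60
        cov = rng.normal(0, 1, S)
        z = (cov - cov.mean()) / cov.std(ddof=1)
        w = rng.normal(size=E)
        w -= w.mean()
        pre = rng.standard_normal((S, E, T))
        post = pre + rng.standard_normal((S, E, T)) * 0.3
        post[:, :, 20:35] += 2.0 * z[:, None, None] * w[None, :, None]
        res = ts.tancova_session_covariate(pre, post, cov, n_permutations=300,
                                           duration="fixed", seed=7)
        assert res.clusters
        a, b = res.clusters[0]
        assert a < 35 and b > 20


class TestNullCalibration:
    def test_timewise_rejection_rate_near_alpha(self):
        """Per-TF p < .05 occurs at ~5% across null simulations."""
        hits = total = 0
        for i in range(60):
            rng = np.random.default_rng(100 + i)
            cov = rng.normal(0, 1, 12)
            cfg = syn.ErpSimConfig(n_subjects=12, n_electrodes=12, n_timeframes=30,
                                   effect_window=(10, 20), coupling_strength=0.0,
                                   seed=200 + i)
            erps, _ = syn.simulate_erp_set(cfg, cov)
            res = ts.tancova_timewise(erps, cov, n_permutations=200, duration=1,
                                      seed=300 + i)
            hits += (res.p_series < 0.05).sum()
            total += res.p_series.size
        rate = hits / total
        assert 0.025 < rate < 0.075

    def test_p_values_valid_under_null(self):
        """P(p <= u) <= u + 1/(n_perm+1), checked at several u."""
        ps = []
        for i in range(80):
            rng = np.random.default_rng(500 + i)
            data = rng.standard_normal((10, 8, 5))
            cov = rng.normal(0, 1, 10)
            res = ts.tancova_timewise(data, cov, n_permutations=199, duration=1,
                                      seed=600 + i)
            ps.extend(res.p_series)
        ps = np.array(ps)
        for u in (0.01, 0.05, 0.10, 0.25):
            emp = (ps <= u).mean()
            margin = 3 * np.sqrt(u * (1 - u) / ps.size)
            assert emp <= u + 1.0 / 200.0 + margin


class TestDurationThreshold:
    def test_iid_null_threshold_small(self):
        """Independent TFs: run-length theory keeps the threshold tiny."""
        rng = np.random.default_rng(12)
        perm_stats = rng.standard_normal((400, 800))
        thr = ts.duration_threshold(perm_stats)
        assert 1 <= thr <= 5

    def test_degenerate_autocorrelated_null(self):
        """Every permutation constant over TFs: runs are all-or-nothing, so no
        finite length can push the exceedance below a global alpha smaller
        than the per-TF rejection mass, and the threshold caps at the series
        length."""
        rng = np.random.default_rng(13)
        levels = rng.standard_normal(100)
        perm_stats = np.tile(levels[:, None], (1, 50))
        # top 4/100 permutations are significant at every TF (mass 0.04)
        thr = ts.duration_threshold(perm_stats, alpha=0.05, global_alpha=0.03)
        assert thr == 50

    def test_degenerate_null_discrete_mass_below_alpha_controls_at_one(self):
        """When the discrete per-TF rejection mass already sits below the
        global level, even length-1 runs control the family-wise error."""
        rng = np.random.default_rng(16)
        perm_stats = np.tile(rng.standard_normal(100)[:, None], (1, 50))
        assert ts.duration_threshold(perm_stats, alpha=0.05, global_alpha=0.05) == 1

    def test_fixed_fallback_is_twelve(self):
        assert ts.FALLBACK_DURATION_TF == 12
        rng = np.random.default_rng(14)
        data = rng.standard_normal((8, 6, 20))
        cov = rng.normal(0, 1, 8)
        res = ts.tancova_timewise(data, cov, n_permutations=120, duration="fixed", seed=0)
        assert res.duration_threshold_tf == 12

    def test_too_few_permutations_rejected(self):
        with pytest.raises(ValueError):
            ts.duration_threshold(np.zeros((50, 10)))


class TestFindClusters:
    def test_exact_twelve_run_detected(self):
        p = np.array([0.2] + [0.01] * 12 + [0.2])
        assert ts.find_clusters(p, 0.05, 12) == [(1, 13)]

    def test_eleven_run_too_short(self):
        p = np.array([0.01] * 11 + [0.2] * 5)
        assert ts.find_clusters(p, 0.05, 12) == []

    def test_alpha_boundary_not_significant(self):
        p = np.array([0.05] * 20)
        assert ts.find_clusters(p, 0.05, 1) == []

    def test_multiple_clusters_and_edges(self):
        p = np.array([0.01] * 3 + [0.9] + [0.04] * 2)
        assert ts.find_clusters(p, 0.05, 2) == [(0, 3), (4, 6)]

    def test_ms_conversion_uses_onset(self):
        rng = np.random.default_rng(15)
        cov = rng.normal(0, 1, 10)
        data = rng.standard_normal((10, 8, 30))
        data[:, :, 10:25] += 5.0 * ((cov - cov.mean()) / cov.std(ddof=1))[:, None, None] \
            * np.linspace(-1, 1, 8)[None, :, None]
        erps = ErpSet(data, sampling_rate=1000.0, onset_index=10)
        res = ts.tancova_timewise(erps, cov, n_permutations=300, duration=5, seed=1)
        assert res.clusters
        (a, b), (ms_a, ms_b) = res.clusters[0], res.clusters_ms[0]
        assert ms_a == pytest.approx((a - 10) * 1.0)
        assert ms_b == pytest.approx((b - 10) * 1.0)
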