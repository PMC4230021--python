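import math

import numpy as np
import pytest
from scipy import stats

from betameth.combine import (
    CorrelationProfile,
    adjust_all,
    bh_fdr,
    combine_site,
    estimate_correlation,
    make_zseries,
    z_transform,
)

NAN = float("nan")


def flat_profile(max_dist=200, rho=0.0):
    return CorrelationProfile(max_dist=max_dist,
                              rho=np.full(max_dist + 1, rho))


class TestZTransform:
    def test_median_p_maps_to_zero(self):
        assert z_transform([0.5])[0] == pytest.approx(0.0, abs=1e-12)

    def test_upper_tail_quantile(self):
        # oracle: standard normal quantile at 0.95
        assert z_transform([0.05])[0] == pytest.approx(
            stats.norm.ppf(0.95), abs=1e-9
        )

    def test_na_propagates(self):
        z = z_transform([0.5, NAN, 0.1])
        assert math.isnan(z[1]) and not math.isnan(z[2])

    def test_extreme_p_clipped_finite(self):
        z = z_transform([0.0, 1.0])
        assert np.isfinite(z).all()

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            z_transform([1.5])
        with pytest.raises(ValueError):
            z_transform([0.5], clip_eps=0.7)


class TestEstimateCorrelation:
    def test_iid_z_scores_have_no_correlation(self):
        rng = np.random.default_rng(11)
        n = 100_000
        pos = np.arange(1, n + 1)
        zs = make_zseries(np.repeat("chr1", n), pos,
                          stats.norm.sf(rng.standard_normal(n)))
        prof = estimate_correlation(zs, max_dist=50)
        assert np.abs(prof.rho[1:]).max() < 0.02

    def test_duplicated_series_at_distance_two(self):
        # z at pos p equals z at pos p+2 -> rho[2] ~ 1
        rng = np.random.default_rng(3)
        m = 300
        z_half = rng.standard_normal(m)
        pos = np.concatenate([10 * np.arange(1, m + 1),
                              10 * np.arange(1, m + 1) + 2])
        p = stats.norm.sf(np.concatenate([z_half, z_half]))
        order = np.argsort(pos)
        zs = make_zseries(np.repeat("chr1", 2 * m), pos[order], p[order])
        prof = estimate_correlation(zs, max_dist=5)
        assert prof.rho[2] > 0.99

    def test_ar1_lag_correlation_recovered(self):
        rng = np.random.default_rng(7)
        n = 100_000
        z = np.empty(n)
        z[0] = rng.standard_normal()
        eps = rng.standard_normal(n)
        for i in range(1, n):
            z[i] = 0.5 * z[i - 1] + math.sqrt(1 - 0.25) * eps[i]
        zs = make_zseries(np.repeat("chr1", n), np.arange(1, n + 1),
                          stats.norm.sf(z))
        prof = estimate_correlation(zs, max_dist=3)
        assert prof.rho[1] == pytest.approx(0.5, abs=0.05)
        assert prof.rho[2] == pytest.approx(0.25, abs=0.05)

    def test_sparse_bins_inherit_nearest(self):
        rng = np.random.default_rng(1)
        n = 2000
        pos = 10 * np.arange(1, n + 1)  # only distance 10 is populated
        zs = make_zseries(np.repeat("chr1", n), pos,
                          stats.norm.sf(rng.standard_normal(n)))
        prof = estimate_correlation(zs, max_dist=15)
        assert np.all(prof.rho == prof.rho[10])

    def test_too_few_sites_rejected(self):
        zs = make_zseries(["chr1"], [100], [0.5])
        with pytest.raises(ValueError, match="at least 2"):
            estimate_correlation(zs)


class TestCombineSite:
    def test_singleton_window_returns_raw_p(self):
        zs = make_zseries(["chr1", "chr1"], [100, 10_000], [0.03, 0.5])
        p = combine_site(zs, flat_profile(), center=0, window_bp=200)
        assert p == pytest.approx(0.03, rel=1e-9)

    def test_two_null_sites_stay_null(self):
        zs = make_zseries(["chr1", "chr1"], [100, 150], [0.5, 0.5])
        p = combine_site(zs, flat_profile(), center=0)
        assert p == pytest.approx(0.5, abs=1e-9)

    def test_two_equal_signals_reinforce(self):
        # z1 = z2 = 1.6449, rho = 0: p = 1 - Phi(2 * 1.6449 / sqrt(2))
        zs = make_zseries(["chr1", "chr1"], [100, 150], [0.05, 0.05])
        p = combine_site(zs, flat_profile(), center=0)
        z = stats.norm.ppf(0.95)
        assert p == pytest.approx(float(stats.norm.sf(2 * z / math.sqrt(2))),
                                  rel=1e-6)
        assert p == pytest.approx(0.0100, abs=2e-4)

    def test_untestable_center_is_na(self):
        zs = make_zseries(["chr1", "chr1"], [100, 150], [NAN, 0.05])
        assert math.isnan(combine_site(zs, flat_profile(), center=0))

    def test_variance_floor_under_negative_correlation(self):
        zs = make_zseries(["chr1"] * 3, [100, 101, 102], [0.01] * 3)
        p = combine_site(zs, flat_profile(rho=-0.99), center=1)
        assert 0.0 < p < 1.0

    def test_zero_correlation_equals_classic_stouffer(self):
        rng = np.random.default_rng(21)
        for _ in range(200):
            n = rng.integers(1, 8)
            pos = np.sort(rng.choice(np.arange(100, 200), size=n,
                                     replace=False))
            pvals = rng.uniform(0.001, 0.999, size=n)
            zs = make_zseries(np.repeat("chr1", n), pos, pvals)
            got = combine_site(zs, flat_profile(), center=0, window_bp=10_000)
            z = stats.norm.isf(pvals)
            expected = float(stats.norm.sf(z.sum() / math.sqrt(n)))
            assert got == pytest.approx(expected, rel=1e-9)

    def test_invariant_under_site_order_reversal(self):
        rng = np.random.default_rng(33)
        prof = CorrelationProfile(
            max_dist=200, rho=np.linspace(0.5, 0.0, 201))
        pos = np.array([100, 130, 160, 190])
        pvals = rng.uniform(size=4)
        zs_fwd = make_zseries(np.repeat("chr1", 4), pos, pvals)
        zs_rev = make_zseries(np.repeat("chr1", 4), (300 - pos)[::-1],
                              pvals[::-1])
        p_fwd = combine_site(zs_fwd, prof, center=1)
        p_rev = combine_site(zs_rev, prof, center=2)
        assert p_fwd == pytest.approx(p_rev, rel=1e-12)


class TestAdjustAll:
    def test_all_null_input_stays_null(self):
        pos = np.arange(1, 301) * 50
        p = adjust_all(np.repeat("chr1", 300), pos, np.full(300, 0.5))
        assert np.allclose(p, 0.5, atol=1e-9)

    def test_run_of_signal_is_boosted(self):
        rng = np.random.default_rng(8)
        n = 3000
        pos = np.arange(1, n + 1) * 50
        p_raw = rng.uniform(0.2, 0.8, size=n)
        p_raw[1500:1510] = 0.05
        out = adjust_all(np.repeat("chr1", n), pos, p_raw)
        assert np.all(out[1501:1509] < 0.05)

    def test_isolated_signal_is_diluted(self):
        rng = np.random.default_rng(9)
        n = 2001
        pos = np.arange(1, n + 1) * 50
        p_raw = rng.uniform(0.4, 0.6, size=n)
        p_raw[1000] = 1e-6
        out = adjust_all(np.repeat("chr1", n), pos, p_raw)
        assert out[1000] > 1e-6

    def test_chromosome_boundary_respected(self):
        # same positions on different chromosomes never share a window
        chroms = np.array(["chr1", "chr1", "chr2", "chr2"])
        pos = np.array([100, 150, 100, 150])
        p = np.array([0.01, 0.01, 0.5, 0.5])
        out = adjust_all(chroms, pos, p, min_pairs=1)
        assert out[2] == pytest.approx(0.5, abs=0.05)

    def test_na_sites_ignored_but_propagated(self):
        pos = np.arange(1, 101) * 50
        p = np.full(100, 0.5)
        p[10] = NAN
        out = adjust_all(np.repeat("chr1", 100), pos, p)
        assert math.isnan(out[10])
        assert np.isfinite(np.delete(out, 10)).all()


def textbook_bh(p):
    """Independent step-up oracle."""
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj


class TestBhFdr:
    def test_textbook_example(self):
        assert bh_fdr([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_all_ones(self):
        assert bh_fdr([1.0, 1.0, 1.0]) == pytest.approx([1.0, 1.0, 1.0])

    def test_single_p_unchanged(self):
        assert bh_fdr([0.2])[0] == pytest.approx(0.2)

    def test_matches_independent_step_up_oracle(self):
        rng = np.random.default_rng(17)
        p = rng.uniform(size=500)
        assert bh_fdr(p) == pytest.approx(textbook_bh(p))

    def test_monotone_dominates_raw_and_stable_under_reapplication(self):
        rng = np.random.default_rng(18)
        p = rng.uniform(size=200)
        adj = bh_fdr(p)
        assert np.all(adj >= p - 1e-12)
        assert np.all(adj <= 1.0)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-12)
        # re-adjusting never shrinks a value and keeps the ranking
        re_adj = bh_fdr(adj)
        assert np.all(re_adj >= adj - 1e-12)
        assert np.all(np.diff(re_adj[order]) >= -1e-12)

    def test_na_excluded_from_ranking(self):
        p = [0.01, NAN, 0.02]
        adj = bh_fdr(p)
        assert math.isnan(adj[1])
        assert adj[0] == pytest.approx(0.02)  # m=2, not 3


class TestNullCalibration:
    def test_combined_p_not_anticonservative_under_global_null(self):
        rng = np.random.default_rng(101)
        n = 100_000
        gaps = rng.integers(2, 201, size=n)
        pos = np.cumsum(gaps)
        p_raw = rng.uniform(size=n)
        out = adjust_all(np.repeat("chr1", n), pos, p_raw)
        for alpha in (0.01, 0.05):
            se = math.sqrt(alpha * (1 - alpha) / n)
            assert np.mean(out < alpha) <= alpha + 3 * se
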