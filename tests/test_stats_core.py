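"""Statistical primitives against brute-force and scipy oracles."""

import numpy as np
import pytest
import scipy.stats
from hypothesis import given, settings
from hypothesis import strategies as hst

from ecstrata.errors import ValidationError
from ecstrata.stats_core import (
    bh_adjust,
    hypergeom_test,
    ks_two_sample,
    rank_sum_matrix,
    t_test_unpaired,
    wilcoxon_rank_sum,
)


def wilcoxon_enumeration_oracle(x, y):
    """Two-sided exact rank-sum p by enumerating group-label assignments."""
    from itertools import combinations

    pooled = np.concatenate([x, y])
    ranks = scipy.stats.rankdata(pooled)
    n1, n = len(x), len(pooled)
    mu = n1 * (n + 1) / 2
    w_obs = ranks[:n1].sum()
    hits = total = 0
    for subset in combinations(range(n), n1):
        total += 1
        if abs(ranks[list(subset)].sum() - mu) >= abs(w_obs - mu) - 1e-9:
            hits += 1
    return hits / total


class TestWilcoxon:
    def test_hand_example_disjoint_samples(self):
        res = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6])
        assert res.p_value == pytest.approx(0.1)
        assert res.statistic == 6.0

    def test_identical_multisets_give_p_one(self):
        res = wilcoxon_rank_sum([1, 2, 3], [1, 2, 3])
        assert res.p_value == pytest.approx(1.0)

    def test_all_values_tied(self):
        res = wilcoxon_rank_sum([5.0] * 4, [5.0] * 3)
        assert res.p_value == pytest.approx(1.0)
        assert res.statistic == pytest.approx(4 * 8 / 2)

    def test_all_tied_large_samples(self):
        res = wilcoxon_rank_sum([1.0] * 20, [1.0] * 20)
        assert res.p_value == pytest.approx(1.0)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        hst.lists(hst.integers(0, 4), min_size=1, max_size=5),
        hst.lists(hst.integers(0, 4), min_size=1, max_size=5),
    )
    def test_exact_path_matches_enumeration_oracle(self, x, y):
        res = wilcoxon_rank_sum(x, y, exact_threshold=12)
        assert res.p_value == pytest.approx(wilcoxon_enumeration_oracle(x, y))

    def test_exact_path_matches_scipy_without_ties(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            x = rng.permutation(12)[:5].astype(float)
            y = rng.permutation(np.arange(20, 32))[:5].astype(float)
            ours = wilcoxon_rank_sum(x, y).p_value
            ref = scipy.stats.mannwhitneyu(x, y, method="exact").pvalue
            assert ours == pytest.approx(ref)

    def test_normal_path_matches_scipy(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            x = rng.integers(0, 8, size=25).astype(float)
            y = rng.integers(0, 8, size=30).astype(float)
            ours = wilcoxon_rank_sum(x, y, exact_threshold=0).p_value
            ref = scipy.stats.mannwhitneyu(
                x, y, method="asymptotic", use_continuity=True
            ).pvalue
            assert ours == pytest.approx(ref, rel=1e-9)

    def test_matrix_version_agrees_with_scalar(self):
        rng = np.random.default_rng(2)
        xa = rng.integers(0, 5, size=(10, 20)).astype(float)
        xb = rng.integers(0, 5, size=(10, 25)).astype(float)
        p_mat = rank_sum_matrix(xa, xb)
        for i in range(10):
            assert p_mat[i] == pytest.approx(
                wilcoxon_rank_sum(xa[i], xb[i], exact_threshold=0).p_value
            )

    def test_empty_sample_rejected(self):
        with pytest.raises(ValidationError):
            wilcoxon_rank_sum([], [1.0])

    def test_null_rejection_rate_calibrated(self):
        rng = np.random.default_rng(42)
        rej = sum(
            wilcoxon_rank_sum(rng.normal(size=30), rng.normal(size=30)).p_value
            <= 0.05
            for _ in range(2000)
        )
        ci = 2.576 * np.sqrt(0.05 * 0.95 / 2000)
        assert 0.05 - ci <= rej / 2000 <= 0.05 + ci


class TestBhAdjust:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.03]) == pytest.approx([0.03])

    def test_hand_stepup_example(self):
        assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_all_ones(self):
        assert bh_adjust([1.0, 1.0]) == pytest.approx([1.0, 1.0])

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(3)
        p = rng.uniform(size=50)
        assert bh_adjust(p) == pytest.approx(
            multipletests(p, method="fdr_bh")[1]
        )

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(hst.lists(hst.floats(0, 1), min_size=1, max_size=12))
    def test_permutation_equivariance(self, p):
        p = np.asarray(p)
        perm = np.random.default_rng(0).permutation(len(p))
        assert bh_adjust(p)[perm] == pytest.approx(bh_adjust(p[perm]))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            bh_adjust([0.5, 1.5])


class TestKs:
    def test_identical_samples_d_zero(self):
        assert ks_two_sample([1, 2, 3], [1, 2, 3]).statistic == 0.0

    def test_disjoint_supports_d_one(self):
        res = ks_two_sample([1, 2], [10, 11, 12])
        assert res.statistic == 1.0

    def test_hand_ecdf_example(self):
        assert ks_two_sample([1, 2], [1.5, 2.5]).statistic == pytest.approx(0.5)

    def test_statistic_matches_scipy_p_matches_kolmogorov_series(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            x = rng.normal(size=40)
            y = rng.normal(0.3, size=55)
            ours = ks_two_sample(x, y)
            ref = scipy.stats.ks_2samp(x, y, method="asymp")
            assert ours.statistic == pytest.approx(ref.statistic)
            # limiting Kolmogorov survival function, independent series sum
            lam = np.sqrt(40 * 55 / 95) * ours.statistic
            series = 2 * sum(
                (-1) ** (k - 1) * np.exp(-2 * k**2 * lam**2)
                for k in range(1, 101)
            )
            assert ours.p_value == pytest.approx(min(series, 1.0), abs=1e-10)

    def test_d_matches_brute_force_with_ties(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            x = rng.integers(0, 5, size=12).astype(float)
            y = rng.integers(0, 5, size=9).astype(float)
            grid = np.concatenate([x, y])
            d = max(
                abs((x <= v).mean() - (y <= v).mean()) for v in grid
            )
            assert ks_two_sample(x, y).statistic == pytest.approx(d)

    def test_null_rejection_rate_calibrated(self):
        rng = np.random.default_rng(42)
        rej = sum(
            ks_two_sample(rng.normal(size=200), rng.normal(size=200)).p_value
            <= 0.05
            for _ in range(2000)
        )
        ci = 2.576 * np.sqrt(0.05 * 0.95 / 2000)
        assert 0.05 - ci <= rej / 2000 <= 0.05 + ci


class TestHypergeom:
    def test_zero_hits_give_p_one(self):
        assert hypergeom_test(0, 5, 5, 20).p_value == pytest.approx(1.0)

    def test_hand_urn_example(self):
        assert hypergeom_test(5, 5, 5, 10).p_value == pytest.approx(1 / 252)

    def test_degenerate_urn_all_marked(self):
        assert hypergeom_test(5, 10, 5, 10).p_value == pytest.approx(1.0)

    def test_matches_brute_force_small_urns(self):
        from math import comb

        for big_n in range(2, 13):
            for big_k in range(big_n + 1):
                for n in range(1, big_n + 1):
                    for k in range(max(0, n + big_k - big_n), min(big_k, n) + 1):
                        brute = sum(
                            comb(big_k, i) * comb(big_n - big_k, n - i)
                            for i in range(k, min(big_k, n) + 1)
                        ) / comb(big_n, n)
                        assert hypergeom_test(k, big_k, n, big_n).p_value == pytest.approx(
                            brute, abs=1e-12
                        )

    def test_matches_scipy_sf(self):
        ours = hypergeom_test(40, 500, 200, 2000).p_value
        ref = scipy.stats.hypergeom.sf(39, 2000, 500, 200)
        assert ours == pytest.approx(ref, rel=1e-10)

    def test_pmf_sums_to_one(self):
        from ecstrata.stats_core import _log_hypergeom_pmf

        for big_n, big_k, n in [(10, 5, 5), (30, 12, 7), (100, 40, 25)]:
            lo = max(0, n + big_k - big_n)
            hi = min(big_k, n)
            support = np.arange(lo, hi + 1)
            total = np.exp(_log_hypergeom_pmf(support, big_n, big_k, n)).sum()
            assert total == pytest.approx(1.0, abs=1e-12)

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValidationError):
            hypergeom_test(6, 5, 5, 10)

    def test_null_rejection_rate_calibrated(self):
        rng = np.random.default_rng(42)
        ks = rng.hypergeometric(500, 1500, 200, size=2000)
        rej = sum(
            hypergeom_test(int(k), 500, 200, 2000).p_value <= 0.05 for k in ks
        )
        ci = 2.576 * np.sqrt(0.05 * 0.95 / 2000)
        assert 0.05 - ci <= rej / 2000 <= 0.05 + ci


class TestTTest:
    def test_identical_samples(self):
        res = t_test_unpaired([1, 2, 3], [1, 2, 3])
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_hand_pooled_example(self):
        res = t_test_unpaired([1, 2, 3], [2, 3, 4])
        assert res.statistic == pytest.approx(-1.2247, abs=1e-4)

    def test_vanishing_jitter_drives_p_to_zero(self):
        p_prev = 1.0
        for eps in (1e-1, 1e-3, 1e-6):
            x = np.array([0, 0, 0, 0]) + np.array([eps, -eps, eps, -eps])
            y = np.array([1.0, 1.0, 1.0, 1.0])
            p = t_test_unpaired(x, y).p_value
            assert p <= p_prev
            p_prev = p
        assert p_prev < 1e-10

    def test_degenerate_zero_variance_convention(self):
        assert t_test_unpaired([2.0, 2.0], [2.0, 2.0]).p_value == 1.0
        assert t_test_unpaired([2.0, 2.0], [3.0, 3.0]).p_value == 0.0

    def test_matches_scipy(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=15)
        y = rng.normal(0.5, size=20)
        ref = scipy.stats.ttest_ind(x, y)
        res = t_test_unpaired(x, y)
        assert res.statistic == pytest.approx(ref.statistic)
        assert res.p_value == pytest.approx(ref.pvalue)
        ref_w = scipy.stats.ttest_ind(x, y, equal_var=False)
        res_w = t_test_unpaired(x, y, welch=True)
        assert res_w.p_value == pytest.approx(ref_w.pvalue)

    def test_null_rejection_rate_calibrated(self):
        rng = np.random.default_rng(42)
        rej = sum(
            t_test_unpaired(rng.normal(size=20), rng.normal(size=20)).p_value
            <= 0.05
            for _ in range(2000)
        )
        ci = 2.576 * np.sqrt(0.05 * 0.95 / 2000)
        assert 0.05 - ci <= rej / 2000 <= 0.05 + ci
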