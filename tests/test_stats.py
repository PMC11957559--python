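"""Ratio statistics, Wilcoxon tests vs permutation oracles, BH, smoothing."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata

from xdose.stats import (
    bh_adjust,
    estimate_germline_fraction,
    log2_sex_ratio,
    msci_test,
    rank_sum_test,
    signed_rank_test,
    smooth_expression_along_x,
    within_sex_xa_test,
    xa_ratio_test,
)


# ---------------------------------------------------------------------------
# Independent brute-force oracles (enumeration over all assignments)


def oracle_rank_sum(x, y, alternative="two-sided"):
    """Enumerate all C(n+m, n) group assignments of the pooled midranks."""
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    n1 = len(x)
    obs = ranks[:n1].sum()
    sums = [sum(c) for c in itertools.combinations(ranks, n1)]
    total = len(sums)
    eps = 1e-9
    p_le = sum(s <= obs + eps for s in sums) / total
    p_ge = sum(s >= obs - eps for s in sums) / total
    if alternative == "two-sided":
        return min(1.0, 2.0 * min(p_le, p_ge))
    return p_le if alternative == "less" else p_ge


def oracle_signed_rank(d, alternative="less"):
    """Enumerate all 2^n sign assignments of the nonzero |d| midranks."""
    d = np.asarray(d, float)
    d = d[d != 0]
    ranks = rankdata(np.abs(d))
    obs = ranks[d > 0].sum()
    eps = 1e-9
    sums = [
        sum(r for r, s in zip(ranks, signs) if s)
        for signs in itertools.product([0, 1], repeat=len(d))
    ]
    total = len(sums)
    p_le = sum(s <= obs + eps for s in sums) / total
    p_ge = sum(s >= obs - eps for s in sums) / total
    if alternative == "two-sided":
        return min(1.0, 2.0 * min(p_le, p_ge))
    return p_le if alternative == "less" else p_ge


class TestRankSumExact:
    def test_three_vs_three_matches_full_enumeration(self):
        x, y = [1.0, 2.5, 4.0], [0.5, 3.0, 5.0]
        res = rank_sum_test(x, y)
        assert res.method == "exact"
        assert res.p_value == pytest.approx(oracle_rank_sum(x, y))

    @pytest.mark.parametrize("seed", range(20))
    def test_random_small_samples_match_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n1, n2 = rng.integers(2, 5, 2)
        # integer values to exercise ties
        x = rng.integers(0, 5, n1).astype(float)
        y = rng.integers(0, 5, n2).astype(float)
        for alt in ("two-sided", "less", "greater"):
            assert rank_sum_test(x, y, alt).p_value == pytest.approx(
                oracle_rank_sum(x, y, alt)
            ), (x, y, alt)

    def test_agrees_with_scipy_exact_when_tie_free(self):
        from scipy.stats import mannwhitneyu

        rng = np.random.default_rng(5)
        x, y = rng.normal(size=6), rng.normal(size=7)
        res = rank_sum_test(x, y)
        ref = mannwhitneyu(x, y, method="exact")
        assert res.statistic == ref.statistic
        assert res.p_value == pytest.approx(ref.pvalue)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            rank_sum_test([], [1.0])


class TestSignedRankExact:
    @pytest.mark.parametrize("seed", range(20))
    def test_random_small_samples_match_oracle(self, seed):
        rng = np.random.default_rng(100 + seed)
        n = int(rng.integers(3, 9))
        d = rng.integers(-4, 5, n).astype(float)
        if not (d != 0).any():
            d[0] = 1.0
        for alt in ("two-sided", "less", "greater"):
            v, p, _ = signed_rank_test(d, alt)
            assert p == pytest.approx(oracle_signed_rank(d, alt)), (d, alt)

    def test_statistic_is_positive_rank_sum(self):
        v, _, _ = signed_rank_test([3.0, -1.0, 2.0])
        # |d| ranks: 3->3, 1->1, 2->2; positives 3 and 2
        assert v == 5.0

    def test_asymptotic_branch_matches_scipy(self):
        from scipy.stats import wilcoxon

        rng = np.random.default_rng(2)
        d = rng.normal(-0.3, 1.0, 60)
        v, p, _ = signed_rank_test(d, "less")
        ref = wilcoxon(d, alternative="less", method="approx", correction=True)
        assert v == ref.statistic
        assert p == pytest.approx(ref.pvalue, rel=1e-6)


class TestLog2SexRatio:
    def test_values_and_exclusions(self):
        means = pd.DataFrame({"M": [10.0, 5.0, 0.0, 3.0], "F": [10.0, 10.0, 4.0, 0.0]},
                             index=list("abcd"))
        ratio, excluded = log2_sex_ratio(means)
        assert ratio["a"] == 0.0
        assert ratio["b"] == -1.0  # half expression: the two-fold line
        assert np.isnan(ratio["c"]) and np.isnan(ratio["d"])
        assert excluded.tolist() == [False, False, True, True]


class TestXaRatioTest:
    def test_shifted_x_detected(self):
        rng = np.random.default_rng(0)
        ratios = pd.Series(
            np.concatenate([rng.normal(-1, 0.3, 200), rng.normal(0, 0.3, 2000)]),
            index=[f"g{i}" for i in range(2200)],
        )
        is_x = pd.Series([True] * 200 + [False] * 2000, index=ratios.index)
        res = xa_ratio_test(ratios, is_x)
        assert res["p"] < 1e-6
        assert res["median_x"] == pytest.approx(-1, abs=0.1)

    def test_small_class_rejected(self):
        ratios = pd.Series([0.1, 0.2, 0.3], index=list("abc"))
        is_x = pd.Series([True, False, False], index=ratios.index)
        with pytest.raises(ValueError, match="at least 2 genes"):
            xa_ratio_test(ratios, is_x)


class TestWithinSex:
    def test_halved_x_is_significant(self):
        rng = np.random.default_rng(1)
        means = pd.DataFrame(
            {
                "M": np.concatenate([rng.lognormal(3, 1, 150) / 2,
                                     rng.lognormal(3, 1, 1500)]),
                "F": np.ones(1650),
            },
            index=[f"g{i}" for i in range(1650)],
        )
        is_x = pd.Series([True] * 150 + [False] * 1500, index=means.index)
        res = within_sex_xa_test(means, is_x, "M")
        assert res["p"] < 0.01

    def test_single_gene_class_rejected(self):
        means = pd.DataFrame({"M": [1.0, 2.0, 3.0], "F": [1.0] * 3}, index=list("abc"))
        is_x = pd.Series([True, False, False], index=means.index)
        with pytest.raises(ValueError):
            within_sex_xa_test(means, is_x, "M")


class TestMsci:
    def test_all_ratios_at_reference_degenerate(self):
        res = msci_test([-1.0] * 10)
        assert res.degenerate and res.p_value == 1.0

    def test_symmetric_around_reference_not_significant(self):
        rng = np.random.default_rng(3)
        ps = [msci_test(rng.normal(-1, 0.4, 50)).p_value for _ in range(200)]
        assert np.mean(ps) == pytest.approx(0.5, abs=0.1)

    def test_below_reference_detected(self):
        rng = np.random.default_rng(4)
        res = msci_test(rng.normal(-1.8, 0.4, 200))
        assert res.p_value < 1e-10
        assert res.statistic >= 0

    def test_too_few_ratios_rejected(self):
        with pytest.raises(ValueError, match="at least 6"):
            msci_test([-2.0] * 5)


class TestBh:
    def test_step_up_hand_example(self):
        # step-up: min over j>=i of p_(j)*m/j -> all collapse to 0.04
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_and_equal_p_unchanged(self):
        assert bh_adjust([0.2])[0] == pytest.approx(0.2)
        np.testing.assert_allclose(bh_adjust([0.3, 0.3, 0.3]), [0.3, 0.3, 0.3])

    def test_monotone_capped_and_dominates_raw(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=50)
        adj = bh_adjust(p)
        assert (adj >= p - 1e-12).all() and (adj <= 1.0).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestGermlineFraction:
    @pytest.mark.parametrize(
        "r,eps,expected",
        [(1.0, 0.0, 0.0), (0.1, 0.1, 1.0), (0.55, 0.1, 0.5), (0.5, 0.0, 0.5)],
    )
    def test_mixture_inversion(self, r, eps, expected):
        g, clamped = estimate_germline_fraction(r, eps)
        assert g == pytest.approx(expected)
        assert not clamped

    def test_clamping_flagged(self):
        g, clamped = estimate_germline_fraction(1.2, 0.0)
        assert g == 0.0 and clamped

    def test_invalid_residual_rejected(self):
        with pytest.raises(ValueError):
            estimate_germline_fraction(0.5, 1.0)


class TestLoess:
    def test_constant_reproduced(self):
        x = np.linspace(0, 1, 30)
        fit = smooth_expression_along_x(x, np.full(30, 2.5))
        np.testing.assert_allclose(fit, 2.5)

    def test_linear_reproduced(self):
        x = np.linspace(0, 1, 30)
        y = 3 * x + 1
        fit = smooth_expression_along_x(x, y)
        np.testing.assert_allclose(fit, y, atol=1e-8)

    def test_fit_within_data_range(self):
        rng = np.random.default_rng(6)
        x = np.sort(rng.uniform(size=100))
        y = rng.normal(size=100)
        fit = smooth_expression_along_x(x, y)
        assert fit.min() >= y.min() - 1e-9 and fit.max() <= y.max() + 1e-9

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            smooth_expression_along_x([1, 2, 3], [1, 2, 3])
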