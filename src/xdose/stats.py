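"""Dosage-compensation statistics.

Per-gene log2 male:female expression ratios, X-vs-autosome rank tests, the
one-sample signed-rank test against the two-fold (log2 = -1) expectation
used to detect meiotic sex chromosome inactivation, sex-biased gene
classification with a negative-binomial exact test, the germ/soma mixture
estimator, and loess smoothing of expression along a chromosome.

Wilcoxon conventions follow the R defaults the field's tooling uses:
average ranks for ties, zero differences dropped (signed-rank), continuity
correction with the normal approximation, and an exact null distribution for
small samples.  Exact p-values are computed from the permutation
distribution of the observed midranks (dynamic programming), so tied data
are handled exactly; the two-sided exact p is ``min(1, 2*min(P<=, P>=))``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import nbinom, norm, rankdata
from statsmodels.nonparametric.smoothers_lowess import lowess
from statsmodels.stats.multitest import multipletests

from .io import CountMatrix, GeneAnnotation, SampleSheet
from .norm import filter_low_expression, tmm_factors

__all__ = [
    "RankTestResult",
    "MsciTestResult",
    "rank_sum_test",
    "signed_rank_test",
    "log2_sex_ratio",
    "xa_ratio_test",
    "within_sex_xa_test",
    "msci_test",
    "bh_adjust",
    "sex_biased_genes",
    "relative_x_expression",
    "estimate_germline_fraction",
    "smooth_expression_along_x",
]

EXACT_MAX_N = 25  # exact null distribution up to this total sample size

TWOFOLD_REFERENCE = -1.0  # log2 M:F expected without dosage compensation


# ---------------------------------------------------------------------------
# Wilcoxon machinery


def _subset_sum_distribution(values: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Counts of rank-sums over all size-k subsets of ``values`` (small ints)."""
    total = int(values.sum())
    # ways[j, s]: number of size-j subsets with sum s
    ways = np.zeros((k + 1, total + 1), dtype=float)
    ways[0, 0] = 1.0
    for v in values:
        v = int(v)
        for j in range(min(k, len(values)), 0, -1):
            ways[j, v:] += ways[j - 1, : total + 1 - v]
    sums = np.arange(total + 1)
    return sums, ways[k]


def _signflip_sum_distribution(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Counts of positive-part sums over all 2^n sign assignments."""
    total = int(values.sum())
    ways = np.zeros(total + 1, dtype=float)
    ways[0] = 1.0
    for v in values:
        v = int(v)
        new = ways.copy()
        new[v:] += ways[: total + 1 - v]
        ways = new
    return np.arange(total + 1), ways


@dataclass
class RankTestResult:
    """Mann-Whitney/Wilcoxon result: U (first group), p, and group sizes."""

    statistic: float
    p_value: float
    n1: int
    n2: int
    method: str


def rank_sum_test(
    x: Sequence[float], y: Sequence[float], alternative: str = "two-sided"
) -> RankTestResult:
    """Two-sample Wilcoxon rank-sum (Mann-Whitney U) test.

    Exact permutation null over the observed midranks for total n <=
    ``EXACT_MAX_N``; otherwise normal approximation with tie and continuity
    corrections.  The reported statistic is U for ``x``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 < 1 or n2 < 1:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2.0
    n = n1 + n2
    if n <= EXACT_MAX_N:
        doubled = np.round(2 * ranks).astype(int)
        sums, ways = _subset_sum_distribution(doubled, n1)
        total_ways = ways.sum()
        obs = int(round(2 * r1))
        p_le = ways[sums <= obs].sum() / total_ways
        p_ge = ways[sums >= obs].sum() / total_ways
        method = "exact"
    else:
        mean = n1 * n2 / 2.0
        _, tie_counts = np.unique(ranks, return_counts=True)
        tie_term = (tie_counts**3 - tie_counts).sum()
        sd = np.sqrt(n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1.0))))
        if sd == 0:
            p_le = p_ge = 1.0
        else:
            p_le = norm.cdf((u1 - mean + 0.5) / sd)
            p_ge = norm.sf((u1 - mean - 0.5) / sd)
        method = "asymptotic"
    if alternative == "two-sided":
        p = min(1.0, 2.0 * min(p_le, p_ge))
    elif alternative == "less":
        p = p_le
    elif alternative == "greater":
        p = p_ge
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return RankTestResult(float(u1), float(min(p, 1.0)), n1, n2, method)


def signed_rank_test(
    diffs: Sequence[float], alternative: str = "less"
) -> tuple[float, float, bool]:
    """One-sample Wilcoxon signed-rank test on a vector of differences.

    Zeros are dropped; ties get average ranks.  Returns ``(V, p, degenerate)``
    where V is the positive-rank sum and ``degenerate`` flags an input with
    no non-zero differences (p reported as 1).  Exact sign-flip null for
    n <= ``EXACT_MAX_N`` non-zero values, else normal approximation with
    continuity and tie corrections.
    """
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return 0.0, 1.0, True
    ranks = rankdata(np.abs(d))
    v = ranks[d > 0].sum()
    if n <= EXACT_MAX_N:
        doubled = np.round(2 * ranks).astype(int)
        sums, ways = _signflip_sum_distribution(doubled)
        total_ways = ways.sum()
        obs = int(round(2 * v))
        p_le = ways[sums <= obs].sum() / total_ways
        p_ge = ways[sums >= obs].sum() / total_ways
    else:
        mean = n * (n + 1) / 4.0
        _, tie_counts = np.unique(ranks, return_counts=True)
        sd = np.sqrt(
            n * (n + 1) * (2 * n + 1) / 24.0 - (tie_counts**3 - tie_counts).sum() / 48.0
        )
        if sd == 0:
            p_le = p_ge = 1.0
        else:
            p_le = norm.cdf((v - mean + 0.5) / sd)
            p_ge = norm.sf((v - mean - 0.5) / sd)
    if alternative == "two-sided":
        p = min(1.0, 2.0 * min(p_le, p_ge))
    elif alternative == "less":
        p = p_le
    elif alternative == "greater":
        p = p_ge
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return float(v), float(min(p, 1.0)), False


# ---------------------------------------------------------------------------
# Ratio statistics


def log2_sex_ratio(means: pd.DataFrame) -> tuple[pd.Series, pd.Series]:
    """Per-gene log2(male mean / female mean).

    ``means`` has columns 'M' and 'F' (sex-mean expression).  Genes with a
    zero mean in either sex are flagged excluded and carry no ratio (NaN);
    no pseudo-count is applied.
    """
    positive = (means["M"] > 0) & (means["F"] > 0)
    ratio = pd.Series(np.nan, index=means.index, name="log2_mf")
    ratio[positive] = np.log2(means.loc[positive, "M"] / means.loc[positive, "F"])
    excluded = ~positive
    excluded.name = "excluded"
    return ratio, excluded


def xa_ratio_test(log2_mf: pd.Series, is_x: pd.Series) -> dict:
    """Two-sided rank-sum comparison of X-linked vs autosomal log2 M:F ratios."""
    values = log2_mf.dropna()
    x_vals = values[is_x.reindex(values.index).fillna(False)]
    a_vals = values[~is_x.reindex(values.index).fillna(False)]
    if len(x_vals) < 2 or len(a_vals) < 2:
        raise ValueError("need at least 2 genes in each of the X and autosome classes")
    res = rank_sum_test(x_vals, a_vals, alternative="two-sided")
    return {
        "n_x": res.n1,
        "n_autosome": res.n2,
        "median_x": float(x_vals.median()),
        "median_autosome": float(a_vals.median()),
        "U": res.statistic,
        "p": res.p_value,
        "method": res.method,
    }


def within_sex_xa_test(
    means: pd.DataFrame, is_x: pd.Series, sex: str
) -> dict:
    """Two-sided rank-sum of X vs autosomal mean expression within one sex."""
    if sex not in means.columns:
        raise ValueError(f"no mean expression for sex {sex!r}")
    values = means[sex].dropna()
    x_vals = values[is_x.reindex(values.index).fillna(False)]
    a_vals = values[~is_x.reindex(values.index).fillna(False)]
    if len(x_vals) < 2 or len(a_vals) < 2:
        raise ValueError("need at least 2 genes in each of the X and autosome classes")
    res = rank_sum_test(x_vals, a_vals, alternative="two-sided")
    return {
        "sex": sex,
        "n_x": res.n1,
        "n_autosome": res.n2,
        "median_x": float(x_vals.median()),
        "median_autosome": float(a_vals.median()),
        "U": res.statistic,
        "p": res.p_value,
        "method": res.method,
    }


@dataclass
class MsciTestResult:
    """Signed-rank test of X-linked log2 M:F ratios against the two-fold line.

    A significantly one-sided-low result means male X expression falls below
    even the halving expected from hemizygosity alone — the transcriptional
    signature of meiotic sex chromosome inactivation in a bulk gonad sample.
    """

    n: int
    statistic: float  # positive-rank sum V
    p_value: float
    reference: float
    degenerate: bool

    def __post_init__(self) -> None:
        if self.statistic < 0 or not 0 <= self.p_value <= 1:
            raise ValueError("invalid signed-rank result")


def msci_test(log2_mf_x: Sequence[float], reference: float = TWOFOLD_REFERENCE) -> MsciTestResult:
    """One-sided signed-rank test: are X ratios below the two-fold reference?

    Tests ``median(log2_mf) < reference`` on the non-NaN X-linked ratios.
    All-equal-to-reference input is degenerate: flagged, p = 1.
    """
    values = np.asarray(pd.Series(log2_mf_x).dropna(), dtype=float)
    if len(values) < 6:
        raise ValueError("need at least 6 X-linked ratios")
    v, p, degenerate = signed_rank_test(values - reference, alternative="less")
    return MsciTestResult(len(values), v, p, reference, degenerate)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# Sex-biased gene classification (NB exact test, common dispersion)


def _nb_loglik(y: np.ndarray, mu: np.ndarray, phi: float) -> np.ndarray:
    """NB log-likelihood, continuous in y (gamma-function form)."""
    mu = np.maximum(mu, 1e-12)
    if phi <= 1e-10:
        return y * np.log(mu) - mu - gammaln(y + 1)
    r = 1.0 / phi
    return (
        gammaln(y + r)
        - gammaln(r)
        - gammaln(y + 1)
        + r * np.log(r / (r + mu))
        + y * np.log(mu / (r + mu))
    )


def _common_dispersion(pseudo: np.ndarray, g1: np.ndarray, g2: np.ndarray) -> float:
    """Common NB dispersion by Cox-Reid adjusted profile likelihood.

    ``pseudo`` are library-size-equalized counts; group means are the MLEs
    under equal library sizes.  The adjustment subtracts half the log
    determinant of the observed information of the two group-mean
    parameters.
    """
    from scipy.optimize import minimize_scalar

    mu1 = pseudo[:, g1].mean(axis=1, keepdims=True)
    mu2 = pseudo[:, g2].mean(axis=1, keepdims=True)

    def neg_apl(log_phi: float) -> float:
        phi = float(np.exp(log_phi))
        ll = _nb_loglik(pseudo[:, g1], mu1, phi).sum() + _nb_loglik(
            pseudo[:, g2], mu2, phi
        ).sum()
        w1 = (mu1[:, 0] / (1 + phi * mu1[:, 0])) * len(g1)
        w2 = (mu2[:, 0] / (1 + phi * mu2[:, 0])) * len(g2)
        adj = 0.5 * (np.log(np.maximum(w1, 1e-12)).sum() + np.log(np.maximum(w2, 1e-12)).sum())
        return -(ll - adj)

    res = minimize_scalar(neg_apl, bounds=(np.log(1e-4), np.log(4.0)), method="bounded")
    return float(np.exp(res.x))


def _nb_exact_p(s1: float, s2: float, n1: int, n2: int, phi: float) -> float:
    """Two-sided exact NB test on group sums at equal library sizes.

    Conditional on the total, sums the probabilities of all outcomes at most
    as likely as the observed split (the classic small-sample exact test for
    two NB groups with common dispersion).
    """
    s1, s2 = int(round(s1)), int(round(s2))
    total = s1 + s2
    if total == 0:
        return 1.0
    mu = total / (n1 + n2)
    k = np.arange(total + 1)
    if phi <= 1e-10:
        from scipy.stats import binom

        logf = binom.logpmf(k, total, n1 / (n1 + n2))
    else:
        r1, r2 = n1 / phi, n2 / phi
        p1 = r1 / (r1 + n1 * mu)
        p2 = r2 / (r2 + n2 * mu)
        logf = nbinom.logpmf(k, r1, p1) + nbinom.logpmf(total - k, r2, p2)
    logf = logf - np.max(logf)
    f = np.exp(logf)
    f /= f.sum()
    return float(min(1.0, f[f <= f[s1] * (1 + 1e-9)].sum()))


def sex_biased_genes(
    cm: CountMatrix,
    sheet: SampleSheet,
    tissue: str,
    stage: str,
    alpha: float = 0.05,
    min_cpm: float = 0.5,
    min_libraries: int = 2,
) -> tuple[pd.DataFrame, dict]:
    """Classify genes of one group as male-biased, female-biased or unbiased.

    Filters and TMM-normalizes the group's samples, equalizes library sizes
    by rescaling counts to the geometric-mean effective library, estimates a
    common NB dispersion (Cox-Reid adjusted profile likelihood) and applies
    a per-gene two-group NB exact test; BH-adjusted p < ``alpha`` declares
    bias, with direction from the fold-change sign.  Returns the per-gene
    table and an MB/FB/SB/T summary with percentages.
    """
    group = sheet.group(tissue, stage)
    males = group.index[group["sex"] == "M"]
    females = group.index[group["sex"] == "F"]
    if len(males) < 2 or len(females) < 2:
        raise ValueError("need at least 2 replicates per sex")
    samples = list(males) + list(females)
    kept = filter_low_expression(cm, samples, min_cpm=min_cpm, min_libraries=min_libraries)
    sub = cm.subset(genes=kept, samples=samples)
    factors = tmm_factors(sub)
    eff = (sub.library_sizes * factors).to_numpy(dtype=float)
    n0 = float(np.exp(np.mean(np.log(eff))))
    pseudo = sub.counts.to_numpy(dtype=float) / eff * n0
    g1 = np.arange(len(males))
    g2 = np.arange(len(males), len(samples))
    phi = _common_dispersion(pseudo, g1, g2)
    s1 = pseudo[:, g1].sum(axis=1)
    s2 = pseudo[:, g2].sum(axis=1)
    pvals = np.array(
        [_nb_exact_p(a, b, len(g1), len(g2), phi) for a, b in zip(s1, s2)]
    )
    padj = bh_adjust(pvals)
    m_mean = pseudo[:, g1].mean(axis=1)
    f_mean = pseudo[:, g2].mean(axis=1)
    with np.errstate(divide="ignore"):
        lfc = np.log2(np.maximum(m_mean, 1e-9) / np.maximum(f_mean, 1e-9))
    label = np.where(padj < alpha, np.where(lfc > 0, "MB", "FB"), "unbiased")
    table = pd.DataFrame(
        {
            "mean_M": m_mean,
            "mean_F": f_mean,
            "log2_fc": lfc,
            "p": pvals,
            "p_adj": padj,
            "label": label,
        },
        index=kept,
    )
    n_mb = int((label == "MB").sum())
    n_fb = int((label == "FB").sum())
    total = len(kept)
    summary = {
        "tissue": tissue,
        "stage": stage,
        "MB": n_mb,
        "FB": n_fb,
        "SB": n_mb + n_fb,
        "T": total,
        "MB_pct": 100.0 * n_mb / total,
        "FB_pct": 100.0 * n_fb / total,
        "SB_pct": 100.0 * (n_mb + n_fb) / total,
        "dispersion": phi,
        "test": "NB exact test, common Cox-Reid dispersion (not edgeR QL F-test)",
    }
    return table, summary


# ---------------------------------------------------------------------------
# Germ/soma mixture estimator


def relative_x_expression(
    means: pd.DataFrame, is_x: pd.Series, method: str = "median"
) -> float:
    """Autosome-normalized male:female X expression ratio r (linear scale).

    Under a germ/soma mixture with germ fraction g and residual meiotic X
    activity eps, the expectation is r = 1 - g*(1 - eps).

    ``method='median'`` (default) de-logs the difference of the median
    per-gene log2 M:F ratios (X minus autosomes): robust to strongly
    sex-biased genes and to chromosome-scale normalization shifts, which
    cancel in the difference.  ``method='mean'`` uses the ratio of summed
    sex-mean expression instead.
    """
    is_x = is_x.reindex(means.index).fillna(False)
    x = means.loc[is_x]
    a = means.loc[~is_x]
    if method == "mean":
        r_x = x["M"].sum() / x["F"].sum()
        r_a = a["M"].sum() / a["F"].sum()
        return float(r_x / r_a)
    if method != "median":
        raise ValueError("method must be 'median' or 'mean'")
    ratios, _ = log2_sex_ratio(means)
    diff = ratios[is_x].median() - ratios[~is_x].median()
    return float(2.0**diff)


def estimate_germline_fraction(r: float, residual: float = 0.0) -> tuple[float, bool]:
    """Invert the germ/soma mixture: g = (1 - r) / (1 - residual).

    ``r`` is the autosome-normalized male:female X expression ratio (linear
    scale).  The estimate is clamped to [0, 1]; the flag reports clamping.
    """
    if not 0 <= residual < 1:
        raise ValueError("residual activity must be in [0, 1)")
    g = (1.0 - r) / (1.0 - residual)
    clamped = g < 0 or g > 1
    return float(min(1.0, max(0.0, g))), clamped


# ---------------------------------------------------------------------------
# Smoothing


def smooth_expression_along_x(
    positions: Sequence[float], values: Sequence[float], span: float = 0.5
) -> np.ndarray:
    """Loess (tricube-weighted local linear) smooth of expression vs position.

    Returns fitted values at the input positions (original order).
    """
    positions = np.asarray(positions, dtype=float)
    values = np.asarray(values, dtype=float)
    if len(positions) < 10:
        raise ValueError("need at least 10 genes to smooth")
    return lowess(values, positions, frac=span, it=0, return_sorted=False)
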