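"""Expression filtering and normalization (CPM / TMM / RPKM).

The analysis chain mirrors standard bulk RNA-seq practice for between-sex
expression comparisons: within each tissue x stage group, genes are first
filtered on raw-library-size CPM, TMM normalization factors are computed on
the filtered matrix, and CPM/RPKM values use the effective library sizes
(library size x factor).  RPKM divides by the exon-union length of each gene
in kb.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence
import warnings

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .io import CountMatrix, GeneAnnotation, SampleSheet

__all__ = [
    "ExpressionMatrix",
    "filter_low_expression",
    "tmm_factors",
    "cpm",
    "rpkm",
    "mean_by_sex",
    "normalize_group",
]


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values in CPM or RPKM units."""

    values: pd.DataFrame
    kind: str  # 'cpm' or 'rpkm'
    group: tuple[str, str] | None = None  # (tissue, stage) when group-scoped

    def __post_init__(self) -> None:
        if self.kind not in ("cpm", "rpkm"):
            raise ValueError("kind must be 'cpm' or 'rpkm'")
        if (self.values.values < 0).any():
            raise ValueError("expression values must be >= 0")

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index


def filter_low_expression(
    cm: CountMatrix,
    samples: Sequence[str] | None = None,
    min_cpm: float = 0.5,
    min_libraries: int = 2,
) -> pd.Index:
    """Genes expressed at >= ``min_cpm`` CPM in >= ``min_libraries`` samples.

    CPM here always uses raw library sizes (filtering precedes
    normalization).  ``samples`` restricts the check to one analysis group;
    a group smaller than ``min_libraries`` is an error.
    """
    sub = cm.counts if samples is None else cm.counts[list(samples)]
    if sub.shape[1] < min_libraries:
        raise ValueError(
            f"group has {sub.shape[1]} samples; at least {min_libraries} required"
        )
    lib = sub.sum(axis=0)
    cpm_values = sub * 1e6 / lib
    keep = (cpm_values >= min_cpm).sum(axis=1) >= min_libraries
    return cm.gene_ids[keep]


def _tmm_pair(
    obs: np.ndarray,
    ref: np.ndarray,
    lib_obs: float,
    lib_ref: float,
    trim_m: float,
    trim_a: float,
) -> float:
    """Trimmed mean of M-values factor of one sample against the reference.

    Doubly trims the per-gene log-ratios (M) and average log-abundances (A),
    then takes the inverse-asymptotic-variance weighted mean of the retained
    M values; returns 2**that mean.
    """
    with np.errstate(divide="ignore", invalid="ignore"):
        p_obs = obs / lib_obs
        p_ref = ref / lib_ref
        log_ratio = np.log2(p_obs / p_ref)
        abs_expr = (np.log2(p_obs) + np.log2(p_ref)) / 2.0
        variance = (lib_obs - obs) / (lib_obs * obs) + (lib_ref - ref) / (lib_ref * ref)
    finite = np.isfinite(log_ratio) & np.isfinite(abs_expr)
    log_ratio, abs_expr, variance = log_ratio[finite], abs_expr[finite], variance[finite]
    if log_ratio.size == 0:
        warnings.warn("no genes shared with the reference sample; factor set to 1")
        return 1.0
    if np.max(np.abs(log_ratio)) < 1e-6:
        return 1.0
    n = log_ratio.size
    lo_m = np.floor(n * trim_m) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * trim_a) + 1
    hi_a = n + 1 - lo_a
    rank_m = rankdata(log_ratio)
    rank_a = rankdata(abs_expr)
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep.any():
        return 1.0
    f = np.sum(log_ratio[keep] / variance[keep]) / np.sum(1.0 / variance[keep])
    return float(2.0**f)


def tmm_factors(
    cm: CountMatrix,
    genes: Iterable[str] | None = None,
    trim_m: float = 0.3,
    trim_a: float = 0.05,
) -> pd.Series:
    """Trimmed-mean-of-M-values normalization factors.

    The reference sample is the one whose 75th-percentile count fraction is
    closest to the across-sample mean; factors are rescaled so their
    geometric mean is 1.
    """
    counts = cm.counts if genes is None else cm.counts.loc[list(genes)]
    if counts.shape[1] < 2:
        raise ValueError("TMM requires at least 2 samples")
    lib = cm.library_sizes.to_numpy(dtype=float)  # raw library sizes (full matrix)
    x = counts.to_numpy(dtype=float)
    q75 = np.percentile(x, 75, axis=0) / lib
    ref_idx = int(np.argmin(np.abs(q75 - q75.mean())))
    factors = np.array(
        [
            _tmm_pair(x[:, j], x[:, ref_idx], lib[j], lib[ref_idx], trim_m, trim_a)
            for j in range(x.shape[1])
        ]
    )
    factors /= np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="norm_factor")


def cpm(cm: CountMatrix, norm_factors: pd.Series | None = None) -> ExpressionMatrix:
    """Counts per million of the effective library (library size x factor)."""
    factors = cm.norm_factors if norm_factors is None else norm_factors
    eff = cm.library_sizes * factors
    if (eff <= 0).any():
        raise ValueError("effective library sizes must be > 0")
    return ExpressionMatrix(cm.counts * 1e6 / eff, kind="cpm")


def rpkm(
    cm: CountMatrix,
    annotation: GeneAnnotation,
    norm_factors: pd.Series | None = None,
) -> ExpressionMatrix:
    """Reads per kilobase of exon-union length per million effective reads."""
    missing = [g for g in cm.gene_ids if g not in annotation.gene_ids]
    if missing:
        raise ValueError(f"genes without annotated length: {missing[:10]}")
    lengths = annotation.genes.loc[cm.gene_ids, "exon_union_length"]
    values = cpm(cm, norm_factors).values.mul(1e3 / lengths, axis=0)
    return ExpressionMatrix(values, kind="rpkm")


def mean_by_sex(expr: ExpressionMatrix, sheet: SampleSheet) -> pd.DataFrame:
    """Per-gene arithmetic mean expression across replicates within each sex."""
    out = {}
    for sex in ("M", "F"):
        cols = [s for s in expr.sample_ids if sheet.samples.at[s, "sex"] == sex]
        if not cols:
            raise ValueError(f"no samples of sex {sex!r} in the expression matrix")
        out[sex] = expr.values[cols].mean(axis=1)
    return pd.DataFrame(out)


def normalize_group(
    cm: CountMatrix,
    sheet: SampleSheet,
    tissue: str,
    stage: str,
    annotation: GeneAnnotation | None = None,
    min_cpm: float = 0.5,
    min_libraries: int = 2,
) -> tuple[ExpressionMatrix, pd.Index, pd.Series]:
    """Filter, TMM-normalize and express one tissue x stage group.

    Returns the RPKM (or CPM when no annotation is given) matrix restricted
    to the group's samples and kept genes, the kept-gene index and the TMM
    factors.
    """
    samples = sheet.group(tissue, stage).index
    if samples.empty:
        raise ValueError(f"no samples for tissue={tissue!r} stage={stage!r}")
    kept = filter_low_expression(cm, samples, min_cpm=min_cpm, min_libraries=min_libraries)
    sub = cm.subset(genes=kept, samples=samples)
    factors = tmm_factors(sub)
    sub = CountMatrix(sub.counts, factors)
    expr = rpkm(sub, annotation) if annotation is not None else cpm(sub)
    expr.group = (tissue, stage)
    return expr, kept, factors
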