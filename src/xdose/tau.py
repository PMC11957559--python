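"""Tissue-specificity index tau and chromosome-level comparisons.

Tau ranges from 0 (a gene expressed equally in all surveyed tissues) to 1
(expression confined to a single tissue):

    tau = sum_i (1 - x_i / max_j x_j) / (N - 1)

computed per sex on per-tissue median expression (RPKM).  X-linked genes are
compared against autosomal genes with rank-sum tests, BH-adjusted within
each sex.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd

from .io import GeneAnnotation, SampleSheet
from .norm import ExpressionMatrix
from .stats import bh_adjust, rank_sum_test

__all__ = ["tau", "tissue_medians", "tau_by_sex", "tau_chromosome_tests"]


def tau(values: pd.DataFrame | np.ndarray, log_transform: bool = False) -> pd.Series:
    """Tau per gene from a genes x tissues table of expression summaries.

    All-zero genes are undefined (NaN).  ``log_transform`` applies
    log2(x + 1) before the index, off by default.
    """
    x = pd.DataFrame(values).astype(float)
    if x.shape[1] < 2:
        raise ValueError("tau requires at least 2 tissues")
    if (x.values < 0).any():
        raise ValueError("expression summaries must be >= 0")
    if log_transform:
        x = np.log2(x + 1.0)
    xmax = x.max(axis=1)
    n = x.shape[1]
    with np.errstate(invalid="ignore", divide="ignore"):
        t = (1.0 - x.div(xmax, axis=0)).sum(axis=1) / (n - 1)
    t[xmax <= 0] = np.nan
    t.name = "tau"
    return t


def tissue_medians(
    expr_by_group: dict[tuple[str, str], ExpressionMatrix],
    sheet: SampleSheet,
    sex: str,
    tissues: Sequence[str],
    stages: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-gene median expression per tissue for one sex.

    Medians are taken jointly over developmental stages and replicates of
    the requested tissue (restricted to ``stages`` when given).  Only genes
    present in every contributing group (i.e. that survived each group's
    expression filter) are retained.
    """
    per_tissue: dict[str, pd.Series] = {}
    for tissue in tissues:
        cols: list[pd.DataFrame] = []
        for (t, stage), expr in expr_by_group.items():
            if t != tissue or (stages is not None and stage not in stages):
                continue
            sel = [s for s in expr.sample_ids if sheet.samples.at[s, "sex"] == sex]
            if sel:
                cols.append(expr.values[sel])
        if not cols:
            raise ValueError(f"no {sex} samples for tissue {tissue!r}")
        joined = pd.concat(cols, axis=1, join="inner")
        per_tissue[tissue] = joined.median(axis=1)
    return pd.DataFrame(per_tissue).dropna()


def tau_by_sex(
    expr_by_group: dict[tuple[str, str], ExpressionMatrix],
    sheet: SampleSheet,
    tissues: Sequence[str],
    stages: Sequence[str] | None = None,
    log_transform: bool = False,
) -> pd.DataFrame:
    """Tau per gene for each sex (columns 'M', 'F')."""
    out = {}
    for sex in ("M", "F"):
        med = tissue_medians(expr_by_group, sheet, sex, tissues, stages)
        out[sex] = tau(med, log_transform=log_transform)
    return pd.DataFrame(out)


def tau_chromosome_tests(
    tau_values: pd.Series,
    annotation: GeneAnnotation,
    sex: str,
    against: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Rank-sum comparisons of X tau vs pooled autosomes and each autosome.

    ``against`` restricts the per-scaffold comparisons; requesting an
    X-classified scaffold there is rejected as an invalid comparison.
    Returns one row per comparison with BH-adjusted p-values (adjusted
    within this sex's set of comparisons).  Scaffolds with fewer than 2
    genes are skipped with a warning.
    """
    values = tau_values.dropna()
    scaffold = annotation.genes["scaffold"].reindex(values.index)
    is_x = annotation.is_x.reindex(values.index).fillna(False)
    x_vals = values[is_x]
    if len(x_vals) < 2:
        raise ValueError("need at least 2 X-linked genes with tau values")
    rows = []
    a_vals = values[~is_x]
    res = rank_sum_test(x_vals, a_vals, alternative="two-sided")
    rows.append(
        ("X", "autosomes", sex, len(x_vals), len(a_vals),
         float(x_vals.median()), float(a_vals.median()), res.statistic, res.p_value)
    )
    if against is None:
        autosomes = [
            s for s in annotation.scaffold_lengths if s not in annotation.x_scaffolds
        ]
    else:
        invalid = set(against) & set(annotation.x_scaffolds)
        if invalid:
            raise ValueError(f"X-vs-X comparison requested for {sorted(invalid)}")
        autosomes = list(against)
    for scaf in autosomes:
        vals = values[scaffold == scaf]
        if len(vals) < 2:
            warnings.warn(f"scaffold {scaf!r} has fewer than 2 genes; skipped")
            continue
        res = rank_sum_test(x_vals, vals, alternative="two-sided")
        rows.append(
            ("X", scaf, sex, len(x_vals), len(vals),
             float(x_vals.median()), float(vals.median()), res.statistic, res.p_value)
        )
    table = pd.DataFrame(
        rows,
        columns=["group1", "group2", "sex", "n1", "n2", "median1", "median2", "U", "p"],
    )
    table["p_adj"] = bh_adjust(table["p"].to_numpy())
    return table
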