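"""Windowed ChIP/input enrichment profiling.

Detects chromosome-scale enrichment of a silencing histone mark (e.g.
H3K9me3) on the X: both libraries are scaled to depth per million mapped
reads, the per-window log2 ChIP/input ratio is computed over a shared
tiling (default 30 kb windows), a penalized cubic smoothing spline is drawn
per scaffold, and the X is compared to the autosomes by the difference of
median window enrichments with a rank-sum test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .io import CoverageTrack
from .sexlink import normalize_track
from .stats import rank_sum_test

__all__ = ["EnrichmentProfile", "enrichment_profile", "smooth_profile", "x_enrichment_test"]


@dataclass
class EnrichmentProfile:
    """Per-window log2 ChIP/input enrichment over a shared genome tiling."""

    windows: pd.DataFrame  # scaffold, start, end, log2_chip_input [, smoothed]
    n_excluded: int
    pseudo: float
    min_input: float

    def scaffold_medians(self) -> pd.Series:
        return self.windows.groupby("scaffold", sort=False)["log2_chip_input"].median()


def enrichment_profile(
    chip: CoverageTrack,
    input_: CoverageTrack,
    pseudo: float = 0.5,
    min_input: float = 1.0,
) -> EnrichmentProfile:
    """log2((chip + pseudo) / (input + pseudo)) per window, on normalized depths.

    Raw tracks are normalized to per-million units first (already-normalized
    tracks are used as-is); windows whose normalized input depth falls below
    ``min_input`` are excluded and counted.  Mismatched tilings are an error.
    """
    if not chip.same_windows(input_):
        raise ValueError("chip and input tracks must share an identical window tiling")
    if not chip.normalized:
        chip = normalize_track(chip)
    if not input_.normalized:
        input_ = normalize_track(input_)
    c = chip.windows["mean_depth"].to_numpy()
    i = input_.windows["mean_depth"].to_numpy()
    keep = i >= min_input
    out = chip.windows[["scaffold", "start", "end"]].copy()
    out["log2_chip_input"] = np.log2(c + pseudo) - np.log2(i + pseudo)
    return EnrichmentProfile(
        windows=out.loc[keep].reset_index(drop=True),
        n_excluded=int((~keep).sum()),
        pseudo=pseudo,
        min_input=min_input,
    )


def smooth_profile(
    profile: EnrichmentProfile, min_windows: int = 10
) -> EnrichmentProfile:
    """Add a per-scaffold smoothed enrichment curve (column ``smoothed``).

    Uses a penalized cubic smoothing spline with the penalty chosen by
    generalized cross-validation, evaluated at window midpoints.  Scaffolds
    with fewer than ``min_windows`` windows keep their raw values and are
    flagged in the ``smooth_flag`` column.
    """
    from scipy.interpolate import make_smoothing_spline

    out = profile.windows.copy()
    smoothed = np.empty(len(out))
    flag = np.empty(len(out), dtype=object)
    for scaf, grp in out.groupby("scaffold", sort=False):
        idx = grp.index.to_numpy()
        y = grp["log2_chip_input"].to_numpy()
        if len(grp) < min_windows:
            smoothed[idx] = y
            flag[idx] = "too_few_windows"
            continue
        mid = ((grp["start"] + grp["end"]) / 2.0).to_numpy(dtype=float)
        if np.allclose(y, y[0]):
            smoothed[idx] = y[0]  # GCV is ill-posed on exactly constant input
        else:
            spline = make_smoothing_spline(mid, y)
            smoothed[idx] = spline(mid)
        flag[idx] = "spline_gcv"
    out["smoothed"] = smoothed
    out["smooth_flag"] = flag
    return EnrichmentProfile(out, profile.n_excluded, profile.pseudo, profile.min_input)


def x_enrichment_test(
    profile: EnrichmentProfile, x_scaffolds: Iterable[str], min_windows: int = 5
) -> dict:
    """X-vs-autosome summary of window enrichments.

    Reports the difference of medians (X minus autosomes), the de-logged
    fold estimate and a two-sided rank-sum p-value.  This chromosome-scale
    test is an addition to the visual windowed profile and is labeled as
    such in the output metadata.
    """
    x_set = set(x_scaffolds)
    on_x = profile.windows["scaffold"].isin(x_set)
    x_vals = profile.windows.loc[on_x, "log2_chip_input"]
    a_vals = profile.windows.loc[~on_x, "log2_chip_input"]
    if len(x_vals) < min_windows or len(a_vals) < min_windows:
        raise ValueError(
            f"need at least {min_windows} windows on the X and the autosomes"
        )
    res = rank_sum_test(x_vals, a_vals, alternative="two-sided")
    diff = float(x_vals.median() - a_vals.median())
    return {
        "n_x_windows": len(x_vals),
        "n_autosome_windows": len(a_vals),
        "median_x": float(x_vals.median()),
        "median_autosome": float(a_vals.median()),
        "difference": diff,
        "fold_estimate": float(2.0**diff),
        "U": res.statistic,
        "p": res.p_value,
        "note": "rank-sum window test added on top of the visual profile",
    }
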