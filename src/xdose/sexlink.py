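"""X-chromosome identification from male vs female DNA-seq coverage.

In an X0/XX system males carry a single X, so male read depth on X-linked
scaffolds is expected to be half the female depth (log2 M:F close to -1)
while autosomes sit near 0.  Scaffolds are classified from the median
per-window log2 ratio of library-size-normalized coverage.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .io import CoverageTrack

__all__ = [
    "AlreadyNormalizedError",
    "ScaffoldCoverageReport",
    "normalize_track",
    "coverage_log2_ratio",
    "classify_scaffolds",
    "identify_x",
]

# Midpoints between the expected log2 ratios of -1 (X) and 0 (autosome).
X_THRESHOLD = -0.5
AUTOSOME_THRESHOLD = -0.25


class AlreadyNormalizedError(ValueError):
    """Normalizing a track twice would silently change its units."""


@dataclass
class ScaffoldCoverageReport:
    """Per-scaffold coverage classification (X-linked / autosomal / ambiguous)."""

    table: pd.DataFrame  # index scaffold: n_windows, median_log2_mf, classification, reason

    @property
    def x_scaffolds(self) -> list[str]:
        return list(self.table.index[self.table["classification"] == "X-linked"])


def normalize_track(track: CoverageTrack) -> CoverageTrack:
    """Scale depths to depth per million mapped reads.

    Raises on a zero mapped-read count and on tracks already normalized.
    """
    if track.normalized:
        raise AlreadyNormalizedError("track is already normalized")
    if track.library_mapped_reads <= 0:
        raise ValueError("library_mapped_reads must be > 0")
    windows = track.windows.copy()
    windows["mean_depth"] = windows["mean_depth"] * 1e6 / track.library_mapped_reads
    return replace(track, windows=windows, normalized=True)


def coverage_log2_ratio(
    male: CoverageTrack,
    female: CoverageTrack,
    pseudo: float = 0.5,
    min_depth: float = 0.0,
) -> tuple[pd.DataFrame, int]:
    """Per-window ``log2((m + pseudo) / (f + pseudo))`` of normalized depths.

    Windows whose female depth falls below ``min_depth`` are excluded; the
    count of exclusions is returned alongside the ratio table.
    """
    if not (male.normalized and female.normalized):
        raise ValueError("both tracks must be normalized first")
    if not male.same_windows(female):
        raise ValueError("male and female tracks must share an identical window set")
    m = male.windows["mean_depth"].to_numpy()
    f = female.windows["mean_depth"].to_numpy()
    keep = f >= min_depth
    out = male.windows[["scaffold", "start", "end"]].copy()
    out["log2_mf"] = np.log2((m + pseudo)) - np.log2((f + pseudo))
    n_excluded = int((~keep).sum())
    return out.loc[keep].reset_index(drop=True), n_excluded


def classify_scaffolds(
    ratios: pd.DataFrame,
    min_windows: int = 5,
    x_threshold: float = X_THRESHOLD,
    autosome_threshold: float = AUTOSOME_THRESHOLD,
) -> ScaffoldCoverageReport:
    """Classify each scaffold from its median per-window log2 M:F ratio.

    Strictly below ``x_threshold`` -> X-linked; strictly above
    ``autosome_threshold`` -> autosomal; anything on or between the
    thresholds, or with fewer than ``min_windows`` valid windows, is
    ambiguous (with the reason recorded).
    """
    rows = []
    for scaf, grp in ratios.groupby("scaffold", sort=False):
        n = len(grp)
        med = float(grp["log2_mf"].median()) if n else float("nan")
        if n < min_windows:
            cls, reason = "ambiguous", f"only {n} windows (< {min_windows})"
        elif med < x_threshold:
            cls, reason = "X-linked", ""
        elif med > autosome_threshold:
            cls, reason = "autosomal", ""
        else:
            cls, reason = "ambiguous", "median between thresholds"
        rows.append((scaf, n, med, cls, reason))
    table = pd.DataFrame(
        rows, columns=["scaffold", "n_windows", "median_log2_mf", "classification", "reason"]
    ).set_index("scaffold")
    return ScaffoldCoverageReport(table)


def identify_x(
    male: CoverageTrack,
    female: CoverageTrack,
    pseudo: float = 0.5,
    min_depth: float = 0.0,
    min_windows: int = 5,
) -> ScaffoldCoverageReport:
    """Normalize, ratio and classify in one step (raw input tracks)."""
    ratios, _ = coverage_log2_ratio(
        normalize_track(male), normalize_track(female), pseudo=pseudo, min_depth=min_depth
    )
    return classify_scaffolds(ratios, min_windows=min_windows)
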