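"""Simple diagnostic plots (log2 M:F ratio boxes; windowed ChIP profile)."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .chip import EnrichmentProfile
from .io import GeneAnnotation


def plot_log2_ratio_boxes(log2_mf: pd.Series, annotation: GeneAnnotation, ax=None):
    """Boxplot of per-gene log2 M:F ratios, X vs pooled autosomes.

    The dashed line marks the two-fold reduction (log2 = -1) expected on the
    X without dosage compensation.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    values = log2_mf.dropna()
    is_x = annotation.is_x.reindex(values.index).fillna(False)
    ax.boxplot(
        [values[is_x], values[~is_x]],
        tick_labels=["X", "autosomes"],
        showfliers=False,
    )
    ax.axhline(0.0, color="grey", lw=0.8)
    ax.axhline(-1.0, color="grey", lw=0.8, ls="--")
    ax.set_ylabel("log2 male:female expression")
    return ax


def plot_enrichment_profile(profile: EnrichmentProfile, x_scaffolds=(), ax=None):
    """Windowed log2 ChIP/input along the genome, smoothed curve overlaid."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 3))
    offset = 0
    x_set = set(x_scaffolds)
    for i, (scaf, grp) in enumerate(profile.windows.groupby("scaffold", sort=False)):
        pos = offset + (grp["start"] + grp["end"]).to_numpy() / 2.0
        color = "tab:blue" if scaf in x_set else ("k" if i % 2 else "0.6")
        ax.scatter(pos, grp["log2_chip_input"], s=4, color=color)
        if "smoothed" in grp:
            ax.plot(pos, grp["smoothed"], color="white", lw=1.5)
        offset += grp["end"].max()
    ax.axhline(0.0, color="grey", lw=0.8)
    ax.set_xlabel("genome position (bp, concatenated scaffolds)")
    ax.set_ylabel("log2 ChIP / input")
    return ax
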