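"""Detect meiotic sex chromosome inactivation and invert the germ/soma mixture.

Bulk male gonad expression is modeled as a mixture of compensated somatic
cells and meiotic germ cells whose X is silenced down to a residual activity.
X expression then falls below even the two-fold reduction of an uncompensated
X (log2 M:F < -1) — the MSCI signature — and the relative X expression r
inverts to a germ-cell fraction estimate g = (1 - r) / (1 - residual).
"""

from xdose import (
    GroupSpec,
    SimConfig,
    estimate_germline_fraction,
    log2_sex_ratio,
    mean_by_sex,
    msci_test,
    normalize_group,
    relative_x_expression,
    simulate_annotation,
    simulate_counts,
)

config = SimConfig(
    groups=[GroupSpec(s, "reproductive_tract", "N4") for s in "MF"],
    dc_mode="msci_mixture",
    germ_fraction=0.8,
    residual_x_activity=0.1,
    seed=3,
)
annotation = simulate_annotation(config)
counts, sheet, truth = simulate_counts(config, annotation)
expr, _, _ = normalize_group(counts, sheet, "reproductive_tract", "N4", annotation)
means = mean_by_sex(expr, sheet)
ratios, _ = log2_sex_ratio(means)
x_ratios = ratios[annotation.is_x.reindex(ratios.index).fillna(False)]

res = msci_test(x_ratios, reference=-1.0)
r = relative_x_expression(means, annotation.is_x)
g_hat, _ = estimate_germline_fraction(r, residual=config.residual_x_activity)

print(f"median X log2 M:F        : {x_ratios.median():+.3f}  (two-fold line at -1)")
print(f"signed-rank V, one-sided p: V = {res.statistic:.0f}, p = {res.p_value:.2e}")
print(f"relative X expression r   : {r:.3f}")
print(f"estimated germ fraction   : {g_hat:.3f}  (simulated truth {config.germ_fraction})")
print(
    "\nThe X median falls significantly below -1, so the reduction exceeds the\n"
    "hemizygous two-fold expectation: evidence for meiotic X inactivation, with\n"
    "the mixture inversion recovering the simulated germ-cell fraction."
)
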