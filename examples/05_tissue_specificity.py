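"""Tissue-specificity index tau: is X-linked expression more tissue-specific?

tau = sum(1 - x_i / max x) / (N - 1) over N tissues ranges from 0 (uniform
expression) to 1 (single-tissue expression).  Here the simulation places
tissue-specific genes on the X at a higher rate than on autosomes, mirroring
the elevated X specificity reported for old, conserved X chromosomes.
"""

from xdose import (
    GroupSpec,
    SimConfig,
    normalize_group,
    simulate_annotation,
    simulate_counts,
    tau_by_sex,
    tau_chromosome_tests,
)

tissues = ["brain", "gut", "antenna", "reproductive_tract"]
config = SimConfig(
    groups=[GroupSpec(sex, t, "A") for t in tissues for sex in "MF"],
    tissue_specific_fraction=0.1,
    tissue_specific_fraction_x=0.4,
    seed=4,
)
annotation = simulate_annotation(config)
counts, sheet, _ = simulate_counts(config, annotation)
expr_by_group = {
    (t, s): normalize_group(counts, sheet, t, s, annotation)[0]
    for t, s in sheet.groups()
}
values = tau_by_sex(expr_by_group, sheet, tissues)

for sex in ("M", "F"):
    t = values[sex].dropna()
    is_x = annotation.is_x.reindex(t.index).fillna(False)
    tests = tau_chromosome_tests(values[sex], annotation, sex)
    pooled = tests[tests["group2"] == "autosomes"].iloc[0]
    print(
        f"sex {sex}: median tau X = {t[is_x].median():.3f}, "
        f"autosomes = {t[~is_x].median():.3f}, "
        f"X-vs-autosomes adjusted p = {pooled['p_adj']:.2e}"
    )
print(
    "\nThe X's higher share of tissue-specific genes raises its median tau in\n"
    "both sexes, and the rank-sum comparison against the pooled autosomes\n"
    "detects the shift after BH adjustment."
)
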