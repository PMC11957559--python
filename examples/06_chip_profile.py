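"""Windowed ChIP/input profiling of a silencing histone mark on the X.

ChIP and input coverage are normalized per million mapped reads, the log2
ChIP/input ratio is computed in 30 kb windows, smoothed per scaffold, and
the X is compared to the autosomes: a chromosome-wide heterochromatin mark
(as deposited during meiotic X inactivation) shows up as a constant offset.
"""

from xdose import SimConfig, enrichment_profile, simulate_chip_pair, smooth_profile, x_enrichment_test

config = SimConfig(seed=5)  # 2-fold X enrichment simulated by default
chip, chip_input = simulate_chip_pair(config, window=30_000)
profile = smooth_profile(enrichment_profile(chip, chip_input))
res = x_enrichment_test(profile, {config.x_scaffold_name})

print(profile.scaffold_medians().round(3))
print(
    f"\nX - autosome median log2 enrichment: {res['difference']:.3f} "
    f"(fold estimate {res['fold_estimate']:.2f}, simulated 2.0)"
)
print(f"rank-sum p over {res['n_x_windows']} X windows: {res['p']:.2e}")
print(
    "\nOnly the X scaffold carries a ~1 log2-unit offset; the smoothed\n"
    "per-scaffold curves make the chromosome-scale step visible."
)
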