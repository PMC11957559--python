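# Methods

This note documents the models, estimators, numerical choices and known
limitations of `xdose`. Everything quantitative stated here is computed by
the test suite or by `scripts/acceptance.py`; nothing is quoted from
external data.

## The biological model

In an X0/XX system, males carry one X copy and females two, while autosomes
are diploid in both sexes. `xdose` works on the per-gene *copy/regulation
factor*: the effective number of transcribed copy-equivalents. Autosomes
have factor 2 in both sexes. The X factor depends on the regulatory regime:

| regime | male X | female X | log2 M:F on X |
|---|---|---|---|
| `complete_upregulation` | 2 (single copy at double rate) | 2 | 0 |
| `none` | 1 | 2 | −1 |
| `female_downregulation` | 1 | 1 (each copy at half rate) | 0 |
| `msci_mixture` | (1−g)·2 + g·2ε | 2 | log2(1 − g(1−ε)) |

The `msci_mixture` regime models bulk male gonad tissue as a mixture of
somatic cells (fully compensated, factor 2) and meiotic germ cells whose X
is silenced down to residual activity ε; g is the germ-cell fraction. The
mixture is deliberately modeled at the tissue level, not per cell, matching
what bulk RNA-seq of a gonad measures. Inverting the autosome-normalized
relative X expression r = 1 − g(1−ε) yields the germ-fraction estimator
g = (1−r)/(1−ε), clamped to [0, 1] with a flag.

## Synthetic-study generator

The generator is first-class, tested code; its defaults define the study
conditions used throughout the tests and the acceptance script.

* **Genome**: 12 scaffolds, 1.6 Mb down to 1.0 Mb in 50 kb steps; the
  third-largest (`scaffold_3`) is the X — the size rank typical of old,
  conserved insect X chromosomes. 200 genes on the X, 182 per autosome
  (2002 autosomal genes).
* **Gene models**: exon-union lengths uniform in 500–3000 bp, 1–3 exons,
  placed without overlap with random intergenic gaps; deterministic given
  the seed (independent child streams per simulator, so e.g. coverage draws
  do not depend on whether counts were generated).
* **Counts**: negative binomial with variance μ + φμ², common dispersion
  φ = 0.05 (typical bulk RNA-seq replicate dispersion); per-gene baselines
  lognormal (meanlog 4, sdlog 1, count units, interpreted as the two-copy
  expectation); library sizes lognormal around 200 000 with σ = 0.2 to
  exercise normalization; 3 replicates per sex per tissue × stage group.
* **Effects**: 30 % of genes sex-biased (half male-, half female-biased) at
  4-fold; 20 % tissue-specific at 10-fold in a random home tissue, with an
  optional separate fraction on the X to emulate elevated X specificity.
* **DNA coverage**: per-window depth ~ Poisson(λ), λ = 50, halved on the
  male X. **ChIP/input**: input Poisson(λ), ChIP Poisson(λ·fold) on X
  windows (fold 2 by default). λ = 200 for the ChIP pair, chosen a priori so
  per-window Poisson noise (≈ 0.13 log2 units) is small relative to
  two-fold signals given the fixed pseudo-count (see below).
* **Germ fractions by stage** (full-study config): 0 at N1 (pre-meiotic
  gonad), 0.8 at N4 (mostly meiotic cells), 0.6 in adults (accessory-gland
  soma dilutes the germline). These are illustrative knobs: no quantitative
  stage-resolved germ-cell fractions are available to calibrate them.

What the generator does *not* emulate: read-level artifacts (mappability,
GC bias, PCR duplicates), per-gene dispersion variation, correlated gene
programs, partial dosage compensation gradients along the chromosome, and
cell-to-cell heterogeneity within tissues. Passing tests therefore validate
the statistical chain under an idealized generative model, not robustness
to every artifact of real libraries.

## Normalization chain

Filtering keeps genes with ≥ 0.5 CPM in ≥ 2 libraries *within the analysis
group* (tissue × stage), computed on raw library sizes because filtering
precedes normalization; a flag switches to a global filter. TMM follows the
published trimmed-mean-of-M-values recipe: reference sample by the
75th-percentile rule, 30 % two-sided trim on M and 5 % on A, inverse
asymptotic-variance weights, factors rescaled to geometric mean 1. The
implementation agrees with edgeR's `calcNormFactors` to ≤ 1e−8 on test
fixtures (one test uses edgeR via Rscript as an independent oracle). RPKM
uses the exon-union length ("gene size" as computed by exonic counting
tools), not the genomic span.

A property worth knowing: when a chromosome holding ~9 % of the
transcriptome is halved in one sex (the no-DC and MSCI regimes), TMM's
asymmetric trimming leaves a small upward bias (~+0.06 log2) on that sex's
autosomal median ratio. This is inherent to the method (we reproduce edgeR
exactly), and it cancels in X-minus-autosome differences — which is why the
germ-fraction estimator uses the difference of medians (below).

## Statistics

* **log2 M:F ratio**: ratio of sex-mean RPKM per gene ("rowMeans then
  ratio"); genes with zero mean in either sex are excluded (no pseudo-count
  by default; an optional pseudo-count exists but is off).
* **Wilcoxon tests**: average ranks for ties; zeros dropped (signed-rank);
  for total n ≤ 25 the exact null distribution of the observed midranks is
  computed by dynamic programming (so ties are handled exactly; two-sided
  exact p is min(1, 2·min(P≤, P≥)) as in R); larger samples use the normal
  approximation with tie and continuity corrections. Exact p-values match
  brute-force enumeration of all group assignments / sign vectors for all
  tested inputs with n ≤ 8.
* **MSCI test**: one-sided (less) signed-rank of X-linked ratios against
  −1 exactly, the dashed two-fold line; all-zero differences are degenerate
  (flagged, p = 1).
* **BH adjustment**: statsmodels step-up FDR, validated monotone and ≤ 1.
* **Sex-biased genes**: the QL F-test of the original tooling is replaced
  by an NB exact test with a common dispersion estimated by Cox–Reid
  adjusted profile likelihood on library-size-equalized pseudo-counts
  (counts rescaled to the geometric-mean effective library — a simpler
  equalization than edgeR's quantile adjustment). The output metadata
  records this deviation. Null false-positive fractions stay ≤ 5 % after BH
  in simulation; a 30 % biased fraction at 4-fold with 3 replicates/sex is
  recovered within ±7 percentage points.
* **Germ-fraction estimator**: r is estimated as the de-logged difference
  of median per-gene log2 ratios (X minus autosomes). The median form is
  robust to the lognormal × 4-fold sex-biased tails that dominate summed
  expression, and chromosome-scale normalization shifts cancel in the
  difference; the ratio-of-sums form remains available (`method="mean"`).
  Recovery is within ±0.05 of the simulated g across regimes (worst case
  ≈ 0.03 in the acceptance run).
* **Smoothing**: expression along the X uses tricube-weighted local linear
  regression (loess, span 0.5, no robustness iterations); ChIP profiles use
  a per-scaffold penalized cubic smoothing spline with the penalty chosen by
  generalized cross-validation (constant input short-circuits GCV, which is
  ill-posed there); scaffolds with < 10 windows keep raw values, flagged.

## X identification

Tracks are normalized to depth per million mapped reads (normalizing twice
raises), log2 ratios use a pseudo-count of 0.5 normalized-depth units, and
scaffolds are classified by median window ratio with thresholds −0.5 / −0.25
— midpoints between the expected −1 and 0; boundary values are ambiguous
(strict inequalities). The observed X median sits near −0.9 rather than −1:
per-million normalization inflates male autosomal depth slightly (the male
library lacks half an X), and the pseudo-count shrinks ratios toward 0. Both
effects are far from the decision boundary at the default λ = 50 with ≥ 20
windows per scaffold; identification is error-free over 20 seeded genomes in
the acceptance run. "Sliding" windows are implemented as non-overlapping
tiling (step = window).

## Windowed ChIP enrichment

Both libraries are normalized per million mapped reads, so genuinely
enriched ChIP libraries lose a little apparent enrichment to their larger
X signal (the normalization absorbs ~log2(13/12) genome-wide); together with
the pseudo-count this puts the measured X-minus-autosome difference for a
simulated 2-fold enrichment at ≈ 0.96–0.98 rather than 1.0. The
difference-of-medians statistic is invariant to per-library rescaling, and
the de-logged fold estimate lands within 15 % of the simulated fold at
window depths as low as λ = 30.

## Problem sizes

Tests and the acceptance script run at the default study size (2202 genes,
3 replicates/sex, 12 scaffolds, ~15 Mb genome): large enough for the
chromosome-scale medians to stabilize (standard error of the X median
≈ 0.02 log2 units) and small enough to run the thousand-replicate null
calibration in well under a minute. Type-I error of the X-vs-autosome test
is calibrated over 1000 simulated null studies; MSCI detection over 100;
X identification and ChIP recovery over 20. The measured null rejection
rate sits at 5–7 %: genes within a study share replicates and normalization
factors, so gene-level ranks are mildly correlated and the rank-sum test is
slightly anticonservative — a property of applying gene-level tests to
study-level data, not of the test implementation (which matches exact
enumeration on independent inputs).

## Known limitations

* Sex-bias testing is an exact-test approximation, not the QL F-test;
  borderline genes can differ from an edgeR analysis.
* Tau is computed on joint medians over stages and replicates per tissue; a
  per-stage option exists but stage-resolved specificity is not modeled.
* The germ/soma mixture assumes exactly two cell populations with uniform
  per-cell output; real gonads have graded meiotic stages.
* No Y-chromosome detection, CNV calling or mappability correction in the
  coverage classifier; no peak calling or replicate-aware differential
  binding in the ChIP module.
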