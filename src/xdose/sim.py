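"""Synthetic X0/XX study generator with known ground truth.

Emulates the data underlying a chromosome-level dosage-compensation study:
a genome of a dozen scaffolds with the third-largest carrying the X, gene
models placed along each scaffold, negative-binomial RNA-seq counts with
library-size variation and configurable X-regulation regimes, Poisson DNA-seq
coverage (halved on the male X), and a ChIP/input pair with enrichment
concentrated on the X.  Every draw is seeded and deterministic; the realized
design is recorded in a :class:`GroundTruth` sidecar so downstream estimators
can be tested against known parameters.

Regulation regimes (``dc_mode``)
--------------------------------
``complete_upregulation``
    The single male X is transcribed at twice the per-copy rate, so male X
    output matches the two female copies (log2 M:F = 0 on the X).
``none``
    No compensation: male X output is half of female (log2 M:F = -1).
``female_downregulation``
    Each female X copy runs at half rate; both sexes express one copy's
    worth (log2 M:F = 0 on the X, but X < autosomes within each sex).
``msci_mixture``
    Bulk male gonad modeled as a germ/soma mixture with germ fraction ``g``:
    somatic cells are fully compensated (factor 2) while meiotic germ cells
    retain only ``residual_x_activity`` of the compensated level, giving a
    male X factor of ``(1-g)*2 + g*2*residual``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io import (
    CountMatrix,
    CoverageTrack,
    GeneAnnotation,
    SampleSheet,
    make_windows,
    write_bedgraph,
    write_counts,
    write_gff3,
    write_sample_sheet,
)

__all__ = [
    "GroupSpec",
    "SimConfig",
    "GroundTruth",
    "default_groups",
    "simulate_annotation",
    "simulate_counts",
    "simulate_dna_coverage",
    "simulate_chip_pair",
    "write_study",
]

DC_MODES = ("complete_upregulation", "none", "female_downregulation", "msci_mixture")

# Distinct child-seed keys so each simulator draws an independent stream.
_KEY_ANNOTATION = 1
_KEY_COUNTS = 2
_KEY_DNA = 3
_KEY_CHIP = 4

READ_LENGTH = 150  # bp, used to convert summed depth to a mapped-read count


@dataclass(frozen=True)
class GroupSpec:
    """One sample group: a sex within a tissue x stage combination.

    ``dc_mode`` / ``germ_fraction`` override the config-wide values, so a
    single study can mix compensated somatic groups with MSCI gonad groups.
    """

    sex: str
    tissue: str
    stage: str
    n_replicates: int = 3
    dc_mode: str | None = None
    germ_fraction: float | None = None


def default_groups(
    tissues: Sequence[str] = ("brain", "gut", "antenna", "reproductive_tract"),
    stages: Sequence[str] = ("N1", "N4", "A"),
    n_replicates: int = 3,
) -> list[GroupSpec]:
    """Both sexes for every tissue x stage combination."""
    return [
        GroupSpec(sex, tissue, stage, n_replicates)
        for tissue in tissues
        for stage in stages
        for sex in ("M", "F")
    ]


def _default_scaffold_lengths() -> list[int]:
    # 12 scaffolds in decreasing size; the third-largest is the X.
    return [1_600_000 - 50_000 * i for i in range(12)]


def _default_genes_per_scaffold() -> list[int]:
    g = [182] * 12
    g[2] = 200  # 200 X-linked genes, 2002 autosomal
    return g


@dataclass
class SimConfig:
    """Full parameterization of a synthetic study.

    Counts are negative binomial with variance ``mu + dispersion * mu**2``;
    library sizes are lognormal around ``mean_library_size`` (sigma 0.2);
    baseline per-gene means are lognormal (meanlog 4, sdlog 1, count units,
    interpreted as the two-copy autosomal expectation at the nominal library
    size).  DNA and ChIP tracks draw per-window depths from Poisson
    distributions at the configured mean coverages.
    """

    n_scaffolds: int = 12
    scaffold_lengths: list[int] = field(default_factory=_default_scaffold_lengths)
    x_scaffold: int = 2  # index: the third-largest scaffold is the X
    genes_per_scaffold: list[int] = field(default_factory=_default_genes_per_scaffold)
    gene_length_range: tuple[int, int] = (500, 3000)
    groups: list[GroupSpec] = field(
        default_factory=lambda: [GroupSpec("M", "brain", "A"), GroupSpec("F", "brain", "A")]
    )
    mean_library_size: float = 200_000.0
    library_size_sigma: float = 0.2
    dispersion: float = 0.05
    baseline_meanlog: float = 4.0
    baseline_sdlog: float = 1.0
    dc_mode: str = "complete_upregulation"
    germ_fraction: float = 0.8
    residual_x_activity: float = 0.1
    sex_biased_fraction: float = 0.3
    sex_bias_fold: float = 4.0
    tissue_specific_fraction: float = 0.2
    tissue_specific_fraction_x: float | None = None
    tissue_specific_fold: float = 10.0
    dna_coverage_mean: float = 50.0
    chip_coverage_mean: float = 200.0
    chip_x_enrichment: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.scaffold_lengths) != self.n_scaffolds:
            raise ValueError("scaffold_lengths must have n_scaffolds entries")
        if any(length <= 0 for length in self.scaffold_lengths):
            raise ValueError("scaffold lengths must all be > 0")
        if not 0 <= self.x_scaffold < self.n_scaffolds:
            raise ValueError("x_scaffold is not a valid scaffold index")
        if isinstance(self.genes_per_scaffold, int):
            self.genes_per_scaffold = [self.genes_per_scaffold] * self.n_scaffolds
        if len(self.genes_per_scaffold) != self.n_scaffolds:
            raise ValueError("genes_per_scaffold must have n_scaffolds entries")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        for name in (
            "germ_fraction",
            "residual_x_activity",
            "sex_biased_fraction",
            "tissue_specific_fraction",
        ):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        if self.dc_mode not in DC_MODES:
            raise ValueError(f"dc_mode must be one of {DC_MODES}")
        if self.chip_x_enrichment <= 0:
            raise ValueError("chip_x_enrichment must be > 0")
        for grp in self.groups:
            if grp.dc_mode is not None and grp.dc_mode not in DC_MODES:
                raise ValueError(f"group dc_mode must be one of {DC_MODES}")

    @property
    def scaffold_names(self) -> list[str]:
        return [f"scaffold_{i + 1}" for i in range(self.n_scaffolds)]

    @property
    def x_scaffold_name(self) -> str:
        return self.scaffold_names[self.x_scaffold]

    def scaffold_length_map(self) -> dict[str, int]:
        return dict(zip(self.scaffold_names, self.scaffold_lengths))

    def _rng(self, key: int, subkey: int = 0) -> np.random.Generator:
        return np.random.default_rng([self.seed, key, subkey])


@dataclass
class GroundTruth:
    """Realized simulation parameters for downstream validation."""

    true_x_scaffold: str
    baseline_means: pd.Series  # per gene, two-copy expectation in count units
    sex_bias: pd.Series  # per gene: 'MB', 'FB' or 'unbiased'
    tissue_label: pd.Series  # per gene: home tissue name or 'broad'
    germ_fraction_by_group: dict[tuple[str, str, str], float]
    dc_mode_by_group: dict[tuple[str, str, str], str]

    def __post_init__(self) -> None:
        if not self.baseline_means.index.equals(self.sex_bias.index) or not (
            self.baseline_means.index.equals(self.tissue_label.index)
        ):
            raise ValueError("ground-truth labels must cover every gene exactly once")


def simulate_annotation(config: SimConfig) -> GeneAnnotation:
    """Place non-overlapping multi-exon gene models along each scaffold.

    Exon-union lengths are drawn uniformly from ``gene_length_range``; each
    gene gets 1-3 exons separated by short introns, and genes are separated
    by random intergenic gaps.  Raises a sizing error when the requested gene
    content cannot fit on a scaffold.
    """
    rng = config._rng(_KEY_ANNOTATION)
    lo, hi = config.gene_length_range
    genes: dict[str, dict] = {}
    exons: dict[str, list[tuple[int, int]]] = {}
    for si, (scaf, length, n_genes) in enumerate(
        zip(config.scaffold_names, config.scaffold_lengths, config.genes_per_scaffold)
    ):
        union_lengths = rng.integers(lo, hi + 1, size=n_genes)
        n_exons = rng.integers(1, 4, size=n_genes)
        spans = []
        gene_exons = []
        for ulen, k in zip(union_lengths, n_exons):
            k = min(int(k), int(ulen))  # at least 1 bp per exon
            # split the exonic length into k parts
            if k > 1:
                cuts = np.sort(rng.choice(np.arange(1, ulen), size=k - 1, replace=False))
                parts = np.diff(np.concatenate([[0], cuts, [ulen]]))
                introns = rng.integers(50, 201, size=k - 1)
            else:
                parts = np.array([ulen])
                introns = np.array([], dtype=int)
            gene_exons.append((parts, introns))
            spans.append(int(parts.sum() + introns.sum()))
        total_span = int(np.sum(spans))
        if total_span > length:
            raise ValueError(
                f"requested gene content ({total_span} bp) exceeds length of "
                f"{scaf} ({length} bp)"
            )
        slack = length - total_span
        gaps = rng.multinomial(slack, np.full(n_genes + 1, 1.0 / (n_genes + 1)))
        pos = 0
        for gi in range(n_genes):
            pos += int(gaps[gi])
            start = pos + 1  # 1-based
            parts, introns = gene_exons[gi]
            gid = f"g{si + 1:02d}_{gi + 1:04d}"
            ivals = []
            cursor = start
            for j, plen in enumerate(parts):
                ivals.append((cursor, cursor + int(plen) - 1))
                cursor += int(plen)
                if j < len(introns):
                    cursor += int(introns[j])
            end = ivals[-1][1]
            genes[gid] = dict(
                scaffold=scaf,
                strand="+" if rng.random() < 0.5 else "-",
                start=start,
                end=end,
            )
            exons[gid] = ivals
            pos += spans[gi]
    df = pd.DataFrame.from_dict(genes, orient="index")
    df.index.name = "gene_id"
    df["exon_union_length"] = [sum(e - s + 1 for s, e in exons[g]) for g in df.index]
    return GeneAnnotation(
        genes=df,
        exons=exons,
        scaffold_lengths=config.scaffold_length_map(),
        x_scaffolds=frozenset({config.x_scaffold_name}),
    )


def _x_factors(mode: str, germ: float, residual: float) -> tuple[float, float]:
    """(male, female) X-chromosome copy/regulation factors; autosomes are 2."""
    if mode == "complete_upregulation":
        return 2.0, 2.0
    if mode == "none":
        return 1.0, 2.0
    if mode == "female_downregulation":
        return 1.0, 1.0  # female copies each halved: 2 * 0.5
    if mode == "msci_mixture":
        return (1.0 - germ) * 2.0 + germ * 2.0 * residual, 2.0
    raise ValueError(f"unknown dc_mode {mode!r}")


def simulate_counts(
    config: SimConfig, annotation: GeneAnnotation
) -> tuple[CountMatrix, SampleSheet, GroundTruth]:
    """Draw the genes x samples negative-binomial count matrix.

    Per-gene/sample mean = baseline x (factor/2) x sex-bias and tissue
    multipliers x relative library size, where the factor encodes X copy
    number and the active regulation regime.  Sex-biased genes (half male-,
    half female-biased) get a ``sex_bias_fold`` multiplier in the favored sex;
    tissue-specific genes get ``tissue_specific_fold`` in their home tissue.
    """
    if not config.groups:
        raise ValueError("configuration error: no sample groups defined")
    rng = config._rng(_KEY_COUNTS)
    gene_ids = annotation.gene_ids
    n_genes = len(gene_ids)
    is_x = annotation.genes["scaffold"].eq(config.x_scaffold_name).to_numpy()

    baseline = np.exp(
        rng.normal(config.baseline_meanlog, config.baseline_sdlog, size=n_genes)
    )

    # sex-bias labels: half MB, half FB among the selected fraction
    sex_bias = np.full(n_genes, "unbiased", dtype=object)
    n_biased = int(round(config.sex_biased_fraction * n_genes))
    biased_idx = rng.choice(n_genes, size=n_biased, replace=False)
    half = n_biased // 2
    sex_bias[biased_idx[:half]] = "MB"
    sex_bias[biased_idx[half:]] = "FB"

    # tissue-specificity labels, with an optional different fraction on the X
    tissues = sorted({g.tissue for g in config.groups})
    tissue_label = np.full(n_genes, "broad", dtype=object)
    frac_x = (
        config.tissue_specific_fraction
        if config.tissue_specific_fraction_x is None
        else config.tissue_specific_fraction_x
    )
    for mask, frac in ((~is_x, config.tissue_specific_fraction), (is_x, frac_x)):
        idx = np.flatnonzero(mask)
        n_spec = int(round(frac * len(idx)))
        chosen = rng.choice(idx, size=n_spec, replace=False)
        tissue_label[chosen] = rng.choice(tissues, size=n_spec)

    sample_rows = []
    columns = {}
    germ_by_group: dict[tuple[str, str, str], float] = {}
    mode_by_group: dict[tuple[str, str, str], str] = {}
    for grp in config.groups:
        if grp.n_replicates < 1:
            raise ValueError("configuration error: group with no replicates")
        mode = grp.dc_mode or config.dc_mode
        germ = config.germ_fraction if grp.germ_fraction is None else grp.germ_fraction
        m_factor, f_factor = _x_factors(mode, germ, config.residual_x_activity)
        factor = np.where(is_x, m_factor if grp.sex == "M" else f_factor, 2.0)
        sb_mult = np.ones(n_genes)
        sb_mult[sex_bias == ("MB" if grp.sex == "M" else "FB")] = config.sex_bias_fold
        ts_mult = np.ones(n_genes)
        ts_mult[(tissue_label != "broad") & (tissue_label == grp.tissue)] = (
            config.tissue_specific_fold
        )
        key = (grp.sex, grp.tissue, grp.stage)
        mode_by_group[key] = mode
        germ_by_group[key] = germ if mode == "msci_mixture" else 0.0
        for rep in range(1, grp.n_replicates + 1):
            lib = np.exp(
                rng.normal(
                    np.log(config.mean_library_size) - config.library_size_sigma**2 / 2,
                    config.library_size_sigma,
                )
            )
            mu = (
                baseline
                * (factor / 2.0)
                * sb_mult
                * ts_mult
                * (lib / config.mean_library_size)
            )
            if config.dispersion <= 1e-12:
                counts = rng.poisson(mu)
            else:
                r = 1.0 / config.dispersion
                counts = rng.negative_binomial(r, r / (r + mu))
            sid = f"{grp.tissue}_{grp.stage}_{grp.sex}{rep}"
            columns[sid] = counts
            sample_rows.append((sid, grp.sex, grp.tissue, grp.stage, rep))

    counts_df = pd.DataFrame(columns, index=gene_ids)
    sheet = SampleSheet(
        pd.DataFrame(
            [r[1:] for r in sample_rows],
            index=pd.Index([r[0] for r in sample_rows], name="sample_id"),
            columns=["sex", "tissue", "stage", "replicate"],
        )
    )
    truth = GroundTruth(
        true_x_scaffold=config.x_scaffold_name,
        baseline_means=pd.Series(baseline, index=gene_ids, name="baseline_mean"),
        sex_bias=pd.Series(sex_bias, index=gene_ids, name="sex_bias"),
        tissue_label=pd.Series(tissue_label, index=gene_ids, name="tissue_label"),
        germ_fraction_by_group=germ_by_group,
        dc_mode_by_group=mode_by_group,
    )
    return CountMatrix(counts_df), sheet, truth


def _track_from_rates(
    rng: np.random.Generator, windows: pd.DataFrame, rates: np.ndarray
) -> CoverageTrack:
    depth = rng.poisson(rates).astype(float)
    lengths = (windows["end"] - windows["start"]).to_numpy()
    mapped = max(1.0, round(float((depth * lengths).sum()) / READ_LENGTH))
    out = windows.copy()
    out["mean_depth"] = depth
    return CoverageTrack(out, library_mapped_reads=mapped)


def simulate_dna_coverage(config: SimConfig, sex: str, window: int) -> CoverageTrack:
    """Per-window Poisson DNA-seq depth; the male X runs at half rate."""
    if window <= 0:
        raise ValueError("window must be > 0")
    if sex not in ("M", "F"):
        raise ValueError("sex must be 'M' or 'F'")
    windows = make_windows(config.scaffold_length_map(), window)
    lam = np.full(len(windows), config.dna_coverage_mean)
    if sex == "M":
        lam[windows["scaffold"].eq(config.x_scaffold_name).to_numpy()] /= 2.0
    rng = config._rng(_KEY_DNA, 0 if sex == "F" else 1)
    return _track_from_rates(rng, windows, lam)


def simulate_chip_pair(
    config: SimConfig, window: int
) -> tuple[CoverageTrack, CoverageTrack]:
    """ChIP and input coverage on a shared tiling.

    Input depth is Poisson(lambda) everywhere; ChIP depth is Poisson(lambda x
    chip_x_enrichment) on X windows and Poisson(lambda) elsewhere.
    """
    if window <= 0:
        raise ValueError("window must be > 0")
    windows = make_windows(config.scaffold_length_map(), window)
    lam = np.full(len(windows), config.chip_coverage_mean)
    on_x = windows["scaffold"].eq(config.x_scaffold_name).to_numpy()
    chip_lam = np.where(on_x, lam * config.chip_x_enrichment, lam)
    chip = _track_from_rates(config._rng(_KEY_CHIP, 0), windows, chip_lam)
    inp = _track_from_rates(config._rng(_KEY_CHIP, 1), windows, lam)
    return chip, inp


def write_study(
    config: SimConfig,
    outdir: str | Path,
    dna_window: int = 50_000,
    chip_window: int = 30_000,
) -> dict[str, Path]:
    """Simulate a full study and write all artifacts to ``outdir``.

    Emits GFF3 annotation, TSV counts and sample sheet, male/female DNA
    bedGraphs, ChIP/input bedGraphs and a JSON ground-truth sidecar; returns
    the mapping of artifact name to path.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    annotation = simulate_annotation(config)
    counts, sheet, truth = simulate_counts(config, annotation)
    paths = {
        "annotation": outdir / "annotation.gff3",
        "counts": outdir / "counts.tsv",
        "samples": outdir / "samples.tsv",
        "dna_male": outdir / "dna_male.bedgraph",
        "dna_female": outdir / "dna_female.bedgraph",
        "chip": outdir / "chip.bedgraph",
        "input": outdir / "input.bedgraph",
        "truth": outdir / "ground_truth.json",
    }
    write_gff3(annotation, paths["annotation"])
    write_counts(counts, paths["counts"])
    write_sample_sheet(sheet, paths["samples"])
    write_bedgraph(simulate_dna_coverage(config, "M", dna_window), paths["dna_male"])
    write_bedgraph(simulate_dna_coverage(config, "F", dna_window), paths["dna_female"])
    chip, inp = simulate_chip_pair(config, chip_window)
    write_bedgraph(chip, paths["chip"])
    write_bedgraph(inp, paths["input"])
    truth_json = {
        "true_x_scaffold": truth.true_x_scaffold,
        "sex_bias": truth.sex_bias.to_dict(),
        "tissue_label": truth.tissue_label.to_dict(),
        "baseline_means": {k: float(v) for k, v in truth.baseline_means.items()},
        "germ_fraction_by_group": {
            "|".join(k): v for k, v in truth.germ_fraction_by_group.items()
        },
        "dc_mode_by_group": {
            "|".join(k): v for k, v in truth.dc_mode_by_group.items()
        },
    }
    paths["truth"].write_text(json.dumps(truth_json, indent=1, sort_keys=True))
    return paths
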