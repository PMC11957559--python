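"""End-to-end study orchestration.

``run_study`` drives the whole analysis — simulate (or ingest) a study,
identify the X from DNA coverage, normalize expression per tissue x stage
group, compute dosage-compensation and MSCI statistics, tissue specificity
and the ChIP enrichment profile — and emits a deterministic TSV/JSON report
bundle.  Stages can be disabled individually; every threshold used is
recorded in the summary, together with per-group gene bookkeeping (how many
genes survive each filter).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .chip import enrichment_profile, smooth_profile, x_enrichment_test
from .io import (
    FLOAT_FMT,
    read_bedgraph,
    read_counts,
    read_gff3,
    read_sample_sheet,
    make_windows,
)
from .norm import mean_by_sex, normalize_group
from .sexlink import identify_x
from .sim import (
    GroupSpec,
    SimConfig,
    simulate_annotation,
    simulate_chip_pair,
    simulate_counts,
    simulate_dna_coverage,
)
from .stats import (
    bh_adjust,
    estimate_germline_fraction,
    log2_sex_ratio,
    msci_test,
    relative_x_expression,
    sex_biased_genes,
    within_sex_xa_test,
    xa_ratio_test,
)
from .tau import tau_by_sex, tau_chromosome_tests

__all__ = ["InputPaths", "StudyConfig", "StudyReport", "default_study_config", "run_study"]


@dataclass
class InputPaths:
    """File-based study inputs, used instead of simulation when given."""

    gff: str
    counts: str
    samples: str
    dna_male: str | None = None
    dna_female: str | None = None
    chip: str | None = None
    chip_input: str | None = None


@dataclass
class StudyConfig:
    """Resolved configuration of a full study run."""

    sim: SimConfig | None = None
    inputs: InputPaths | None = None
    stages: dict = field(
        default_factory=lambda: {
            "sexlink": True,
            "expression": True,
            "tau": True,
            "chip": True,
        }
    )
    dna_window: int = 50_000
    chip_window: int = 30_000
    min_cpm: float = 0.5
    min_libraries: int = 2
    msci_tissue: str = "reproductive_tract"
    msci_reference: float = -1.0
    # assumed residual meiotic X activity for the germ-fraction estimator;
    # taken from the simulation settings when simulating
    msci_residual: float | None = None
    tau_tissues: list[str] | None = None
    tau_stages: list[str] | None = None

    def resolved_yaml(self) -> str:
        return yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)

    def config_hash(self) -> str:
        return hashlib.sha256(self.resolved_yaml().encode()).hexdigest()[:16]


def default_study_config(seed: int = 0) -> StudyConfig:
    """The default synthetic study: compensated soma, MSCI gonads from N4 on.

    Somatic tissues run complete X upregulation at every stage; the
    reproductive tract is compensated at hatching (N1, pre-meiotic, germ
    fraction 0), then a germ/soma mixture with germ fraction 0.8 at N4 and
    0.6 at the adult stage (adult tracts carry more somatic accessory
    tissue).
    """
    germ = {"N1": 0.0, "N4": 0.8, "A": 0.6}
    groups = []
    for tissue in ("brain", "gut", "antenna", "reproductive_tract"):
        for stage in ("N1", "N4", "A"):
            for sex in ("M", "F"):
                if tissue == "reproductive_tract" and germ[stage] > 0:
                    groups.append(
                        GroupSpec(sex, tissue, stage, 3, "msci_mixture", germ[stage])
                    )
                else:
                    groups.append(GroupSpec(sex, tissue, stage, 3, "complete_upregulation"))
    sim = SimConfig(groups=groups, seed=seed)
    return StudyConfig(sim=sim, tau_stages=["N1", "N4", "A"])


@dataclass
class StudyReport:
    """Structured result surface of one study run."""

    metadata: dict
    scaffold_report: pd.DataFrame | None
    dc_table: pd.DataFrame | None
    within_sex_table: pd.DataFrame | None
    msci_table: pd.DataFrame | None
    sex_bias_table: pd.DataFrame | None
    tau_values: pd.DataFrame | None
    tau_tests: pd.DataFrame | None
    chip_profile: pd.DataFrame | None
    chip_summary: dict | None


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format=FLOAT_FMT)


def run_study(config: StudyConfig, outdir: str | Path) -> StudyReport:
    """Execute every enabled stage in order and write the report bundle."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages = config.stages
    if config.sim is None and config.inputs is None:
        raise ValueError("config must provide either simulation settings or input paths")

    # ---- validate stage inputs up front, before any computation
    if config.inputs is not None:
        inp = config.inputs
        if stages.get("sexlink") and not (inp.dna_male and inp.dna_female):
            raise ValueError("sexlink stage enabled but DNA coverage inputs missing")
        if stages.get("chip") and not (inp.chip and inp.chip_input):
            raise ValueError("chip stage enabled but ChIP/input coverage missing")

    metadata = {
        "config_hash": config.config_hash(),
        "seed": config.sim.seed if config.sim is not None else None,
        "version": __version__,
        "thresholds": {
            "min_cpm": config.min_cpm,
            "min_libraries": config.min_libraries,
            "dna_window": config.dna_window,
            "chip_window": config.chip_window,
            "msci_reference": config.msci_reference,
        },
        "stages": dict(stages),
    }
    (outdir / "resolved_config.yaml").write_text(config.resolved_yaml())

    # ---- inputs
    need_expression = any(stages.get(k) for k in ("expression", "tau"))
    annotation = counts = sheet = None
    dna_m = dna_f = chip_track = input_track = None
    if config.sim is not None:
        sim = config.sim
        annotation = simulate_annotation(sim)
        if need_expression:
            counts, sheet, _truth = simulate_counts(sim, annotation)
        if stages.get("sexlink"):
            dna_m = simulate_dna_coverage(sim, "M", config.dna_window)
            dna_f = simulate_dna_coverage(sim, "F", config.dna_window)
        if stages.get("chip"):
            chip_track, input_track = simulate_chip_pair(sim, config.chip_window)
    else:
        annotation = read_gff3(config.inputs.gff)
        if need_expression:
            sheet = read_sample_sheet(config.inputs.samples)
            counts = read_counts(config.inputs.counts, sheet)
        windows = make_windows(annotation.scaffold_lengths, config.dna_window)
        if stages.get("sexlink"):
            dna_m = read_bedgraph(config.inputs.dna_male, windows)
            dna_f = read_bedgraph(config.inputs.dna_female, windows)
        if stages.get("chip"):
            cwin = make_windows(annotation.scaffold_lengths, config.chip_window)
            chip_track = read_bedgraph(config.inputs.chip, cwin)
            input_track = read_bedgraph(config.inputs.chip_input, cwin)

    # ---- sexlink: classify scaffolds, then flag X-linked genes accordingly
    scaffold_report = None
    if stages.get("sexlink"):
        report = identify_x(dna_m, dna_f)
        scaffold_report = report.table.reset_index()
        annotation = annotation.with_x(report.x_scaffolds)
        _write_tsv(scaffold_report, outdir / "scaffold_report.tsv")
        metadata["x_scaffolds"] = report.x_scaffolds

    # ---- per-group expression statistics
    dc_table = within_table = msci_table = sexbias_table = None
    tau_values = tau_tests = None
    expr_by_group = {}
    if need_expression:
        dc_rows, within_rows, msci_rows, sb_rows = [], [], [], []
        for tissue, stage in sheet.groups():
            expr, kept, factors = normalize_group(
                counts, sheet, tissue, stage, annotation,
                min_cpm=config.min_cpm, min_libraries=config.min_libraries,
            )
            expr_by_group[(tissue, stage)] = expr
            if not stages.get("expression"):
                continue
            means = mean_by_sex(expr, sheet)
            ratios, excluded = log2_sex_ratio(means)
            is_x = annotation.is_x
            res = xa_ratio_test(ratios, is_x)
            dc_rows.append(
                {"tissue": tissue, "stage": stage, "n_genes_kept": len(kept),
                 "n_excluded_ratio": int(excluded.sum()), **res}
            )
            for sex in ("M", "F"):
                within_rows.append(
                    {"tissue": tissue, "stage": stage,
                     **within_sex_xa_test(means, is_x, sex)}
                )
            if tissue == config.msci_tissue:
                x_ratios = ratios[is_x.reindex(ratios.index).fillna(False)]
                m = msci_test(x_ratios, reference=config.msci_reference)
                r = relative_x_expression(means, is_x)
                residual = config.msci_residual
                if residual is None:
                    residual = (
                        config.sim.residual_x_activity if config.sim is not None else 0.0
                    )
                g_hat, clamped = estimate_germline_fraction(r, residual=residual)
                msci_rows.append(
                    {"tissue": tissue, "stage": stage, "n": m.n, "V": m.statistic,
                     "p": m.p_value, "degenerate": m.degenerate,
                     "relative_x_expression": r, "germ_fraction_estimate": g_hat,
                     "estimate_clamped": clamped}
                )
                _table, summary = sex_biased_genes(
                    counts, sheet, tissue, stage,
                    min_cpm=config.min_cpm, min_libraries=config.min_libraries,
                )
                sb_rows.append(summary)
        if stages.get("expression"):
            dc_table = pd.DataFrame(dc_rows)
            dc_table["p_adj"] = bh_adjust(dc_table["p"].to_numpy())
            within_table = pd.DataFrame(within_rows)
            within_table["p_adj"] = bh_adjust(within_table["p"].to_numpy())
            _write_tsv(dc_table, outdir / "dc_tests.tsv")
            _write_tsv(within_table, outdir / "within_sex_tests.tsv")
            if msci_rows:
                msci_table = pd.DataFrame(msci_rows)
                msci_table["p_adj"] = bh_adjust(msci_table["p"].to_numpy())
                _write_tsv(msci_table, outdir / "msci_tests.tsv")
            if sb_rows:
                sexbias_table = pd.DataFrame(sb_rows)
                _write_tsv(sexbias_table, outdir / "sex_biased_counts.tsv")

    # ---- tissue specificity
    if stages.get("tau"):
        tissues = config.tau_tissues or sorted({t for t, _ in expr_by_group})
        tau_values = tau_by_sex(expr_by_group, sheet, tissues, config.tau_stages)
        tau_tests = pd.concat(
            [
                tau_chromosome_tests(tau_values[sex], annotation, sex)
                for sex in ("M", "F")
            ],
            ignore_index=True,
        )
        _write_tsv(tau_values, outdir / "tau_values.tsv", index=True)
        _write_tsv(tau_tests, outdir / "tau_tests.tsv")

    # ---- ChIP enrichment
    chip_profile_df = chip_summary = None
    if stages.get("chip"):
        profile = smooth_profile(enrichment_profile(chip_track, input_track))
        chip_summary = x_enrichment_test(profile, annotation.x_scaffolds)
        chip_profile_df = profile.windows
        _write_tsv(chip_profile_df, outdir / "chip_profile.tsv")

    # ---- summary
    summary = {"metadata": metadata}
    if dc_table is not None:
        summary["dc_tests"] = json.loads(dc_table.to_json(orient="records"))
    if msci_table is not None:
        summary["msci_tests"] = json.loads(msci_table.to_json(orient="records"))
    if sexbias_table is not None:
        summary["sex_biased"] = json.loads(sexbias_table.to_json(orient="records"))
    if chip_summary is not None:
        summary["chip"] = chip_summary
    (outdir / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))

    return StudyReport(
        metadata=metadata,
        scaffold_report=scaffold_report,
        dc_table=dc_table,
        within_sex_table=within_table,
        msci_table=msci_table,
        sex_bias_table=sexbias_table,
        tau_values=tau_values,
        tau_tests=tau_tests,
        chip_profile=chip_profile_df,
        chip_summary=chip_summary,
    )
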