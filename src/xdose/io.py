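"""Readers, writers and genomic-window scaffolding.

This module owns the standard formats the pipeline touches — GFF3 gene
annotations, TSV count matrices and sample sheets, bedGraph coverage — and
the in-memory containers shared by all analysis stages.  Coordinate
conventions are enforced throughout: GFF3 intervals are 1-based inclusive,
BED/bedGraph intervals are 0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GeneAnnotation",
    "SampleSheet",
    "CountMatrix",
    "CoverageTrack",
    "GffParseError",
    "read_gff3",
    "write_gff3",
    "read_sample_sheet",
    "write_sample_sheet",
    "read_counts",
    "write_counts",
    "make_windows",
    "read_bedgraph",
    "write_bedgraph",
]

# Floats in every writer are printed with 6 significant digits.
FLOAT_FMT = "%.6g"


class GffParseError(ValueError):
    """Raised for malformed GFF3 input; the message names the offending line."""


def _union_length(intervals: Sequence[tuple[int, int]]) -> int:
    """Total length of the union of 1-based inclusive intervals."""
    total = 0
    last_end = 0
    for start, end in sorted(intervals):
        start = max(start, last_end + 1)
        if end >= start:
            total += end - start + 1
            last_end = max(last_end, end)
    return total


@dataclass
class GeneAnnotation:
    """Per-gene scaffold assignment, exon structure and X-linkage flags.

    Attributes
    ----------
    genes
        DataFrame indexed by gene id with columns ``scaffold``, ``strand``,
        ``start``, ``end`` (1-based inclusive gene span) and
        ``exon_union_length`` (bp of the union of the gene's exons — the
        "gene size" used for RPKM).
    exons
        Mapping gene id -> list of 1-based inclusive (start, end) exon
        intervals.
    scaffold_lengths
        Mapping scaffold name -> length in bp.
    x_scaffolds
        Scaffolds classified as X-linked; drives the per-gene ``is_x`` flag.
    """

    genes: pd.DataFrame
    exons: dict[str, list[tuple[int, int]]]
    scaffold_lengths: dict[str, int]
    x_scaffolds: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.genes.index.is_unique:
            dup = self.genes.index[self.genes.index.duplicated()][0]
            raise ValueError(f"duplicate gene id {dup!r}")
        if (self.genes["exon_union_length"] <= 0).any():
            raise ValueError("exon_union_length must be > 0 for every gene")
        for gid, ivals in self.exons.items():
            scaf = self.genes.at[gid, "scaffold"]
            length = self.scaffold_lengths[scaf]
            for s, e in ivals:
                if s < 1 or e > length or e < s:
                    raise ValueError(
                        f"exon ({s}, {e}) of gene {gid!r} outside [1, {length}] on {scaf}"
                    )
        self.x_scaffolds = frozenset(self.x_scaffolds)

    @property
    def is_x(self) -> pd.Series:
        """Boolean Series (per gene): gene lies on an X-classified scaffold."""
        return self.genes["scaffold"].isin(self.x_scaffolds)

    @property
    def gene_ids(self) -> pd.Index:
        return self.genes.index

    def with_x(self, x_scaffolds: Iterable[str]) -> "GeneAnnotation":
        """Return a copy with a new X-scaffold classification."""
        return replace(self, x_scaffolds=frozenset(x_scaffolds))

    def __len__(self) -> int:
        return len(self.genes)


def read_gff3(path: str | Path) -> GeneAnnotation:
    """Parse a GFF3 file with gene/exon features into a :class:`GeneAnnotation`.

    The exon-union length is computed from exon features; genes without any
    exon fall back to the gene-span length (a warning is emitted).  Malformed
    coordinates raise :class:`GffParseError` naming the line number.
    """
    import warnings

    scaffold_lengths: dict[str, int] = {}
    gene_rows: dict[str, dict] = {}
    exons: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if line.startswith("##sequence-region"):
                parts = line.split()
                scaffold_lengths[parts[1]] = int(parts[3])
                continue
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise GffParseError(f"line {lineno}: expected 9 columns, got {len(fields)}")
            scaf, _source, ftype, start_s, end_s, _score, strand, _frame, attrs = fields
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise GffParseError(f"line {lineno}: non-integer coordinates") from exc
            if end < start or start < 1:
                raise GffParseError(f"line {lineno}: malformed coordinates {start}..{end}")
            attr = dict(
                item.split("=", 1) for item in attrs.split(";") if "=" in item
            )
            if ftype == "gene":
                gid = attr.get("ID")
                if gid is None:
                    raise GffParseError(f"line {lineno}: gene feature without ID attribute")
                if gid in gene_rows:
                    raise GffParseError(f"line {lineno}: duplicate gene id {gid!r}")
                gene_rows[gid] = dict(scaffold=scaf, strand=strand, start=start, end=end)
                exons.setdefault(gid, [])
            elif ftype == "exon":
                parent = attr.get("Parent")
                if parent is None:
                    raise GffParseError(f"line {lineno}: exon without Parent attribute")
                exons.setdefault(parent, []).append((start, end))
    if not gene_rows:
        raise GffParseError("no gene features found")
    genes = pd.DataFrame.from_dict(gene_rows, orient="index")
    genes.index.name = "gene_id"
    lengths = []
    for gid in genes.index:
        if exons[gid]:
            lengths.append(_union_length(exons[gid]))
        else:
            warnings.warn(f"gene {gid!r} has no exons; using gene-span length")
            row = genes.loc[gid]
            lengths.append(int(row["end"] - row["start"] + 1))
            exons[gid] = [(int(row["start"]), int(row["end"]))]
    genes["exon_union_length"] = lengths
    for scaf in genes["scaffold"].unique():
        scaffold_lengths.setdefault(
            scaf, int(genes.loc[genes["scaffold"] == scaf, "end"].max())
        )
    return GeneAnnotation(genes=genes, exons=exons, scaffold_lengths=scaffold_lengths)


def write_gff3(annotation: GeneAnnotation, path: str | Path) -> None:
    """Write a :class:`GeneAnnotation` as GFF3 (1-based inclusive coordinates)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for scaf, length in annotation.scaffold_lengths.items():
            fh.write(f"##sequence-region {scaf} 1 {length}\n")
        for gid, row in annotation.genes.iterrows():
            fh.write(
                f"{row['scaffold']}\txdose\tgene\t{row['start']}\t{row['end']}\t.\t"
                f"{row['strand']}\t.\tID={gid}\n"
            )
            for i, (s, e) in enumerate(sorted(annotation.exons[gid]), start=1):
                fh.write(
                    f"{row['scaffold']}\txdose\texon\t{s}\t{e}\t.\t"
                    f"{row['strand']}\t.\tID={gid}.exon{i};Parent={gid}\n"
                )


@dataclass
class SampleSheet:
    """Sample metadata: sex, tissue, developmental stage and replicate index."""

    samples: pd.DataFrame  # index: sample id; columns: sex, tissue, stage, replicate

    def __post_init__(self) -> None:
        required = {"sex", "tissue", "stage", "replicate"}
        missing = required - set(self.samples.columns)
        if missing:
            raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
        if not self.samples.index.is_unique:
            raise ValueError("sample ids must be unique")
        bad_sex = set(self.samples["sex"]) - {"M", "F"}
        if bad_sex:
            raise ValueError(f"sex must be 'M' or 'F', got {sorted(bad_sex)}")
        key = self.samples[["sex", "tissue", "stage", "replicate"]]
        if key.duplicated().any():
            raise ValueError("(sex, tissue, stage, replicate) combinations must be unique")

    @property
    def sample_ids(self) -> pd.Index:
        return self.samples.index

    def group(self, tissue: str, stage: str) -> pd.DataFrame:
        """Samples of one tissue x stage analysis group."""
        sel = (self.samples["tissue"] == tissue) & (self.samples["stage"] == stage)
        return self.samples.loc[sel]

    def groups(self) -> list[tuple[str, str]]:
        """All (tissue, stage) combinations present, in sheet order."""
        seen = self.samples[["tissue", "stage"]].drop_duplicates()
        return list(seen.itertuples(index=False, name=None))


def read_sample_sheet(path: str | Path) -> SampleSheet:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str}, index_col="sample_id")
    df["replicate"] = df["replicate"].astype(int)
    return SampleSheet(df)


def write_sample_sheet(sheet: SampleSheet, path: str | Path) -> None:
    sheet.samples.to_csv(path, sep="\t", index_label="sample_id")


@dataclass
class CountMatrix:
    """Raw integer read counts (genes x samples) plus normalization factors.

    ``library_sizes`` are always the column sums of the *raw* matrix;
    ``norm_factors`` are multiplicative TMM-style factors (1.0 until
    normalization has been run) whose geometric mean is 1 after scaling.
    """

    counts: pd.DataFrame
    norm_factors: pd.Series = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")
        if self.norm_factors is None:
            self.norm_factors = pd.Series(1.0, index=self.counts.columns)
        self.norm_factors = self.norm_factors.reindex(self.counts.columns)
        if self.norm_factors.isna().any():
            raise ValueError("norm_factors must cover every sample")

    @property
    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    def subset(self, genes=None, samples=None) -> "CountMatrix":
        df = self.counts
        if genes is not None:
            df = df.loc[genes]
        if samples is not None:
            df = df[list(samples)]
        return CountMatrix(df, self.norm_factors.loc[df.columns].copy())


def read_counts(path: str | Path, sheet: SampleSheet) -> CountMatrix:
    """Read a TSV count matrix (gene_id + one column per sample).

    Columns are reordered to sample-sheet order; missing sample columns and
    non-integer or negative cells are errors.
    """
    df = pd.read_csv(path, sep="\t", index_col="gene_id")
    missing = [s for s in sheet.sample_ids if s not in df.columns]
    if missing:
        raise ValueError(f"count matrix missing sample columns: {missing}")
    df = df[list(sheet.sample_ids)]
    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.integer):
        if not np.allclose(values, np.round(values)):
            raise ValueError("count matrix contains non-integer cells")
        df = df.round().astype(np.int64)
    if (df.values < 0).any():
        raise ValueError("count matrix contains negative counts")
    return CountMatrix(df.astype(np.int64))


def write_counts(cm: CountMatrix, path: str | Path) -> None:
    cm.counts.to_csv(path, sep="\t", index_label="gene_id")


def make_windows(scaffold_lengths: Mapping[str, int], window: int) -> pd.DataFrame:
    """Tile every scaffold with consecutive non-overlapping windows.

    Windows are 0-based half-open ``[k*w, min((k+1)*w, L))``; a final partial
    window is retained and flagged in the ``partial`` column.
    """
    if window <= 0:
        raise ValueError("window size must be > 0")
    rows = []
    for scaf, length in scaffold_lengths.items():
        if length <= 0:
            raise ValueError(f"scaffold {scaf!r} has non-positive length")
        starts = np.arange(0, length, window)
        ends = np.minimum(starts + window, length)
        for s, e in zip(starts, ends):
            rows.append((scaf, int(s), int(e), bool(e - s < window)))
    return pd.DataFrame(rows, columns=["scaffold", "start", "end", "partial"])


@dataclass
class CoverageTrack:
    """Per-window mean sequencing depth over a shared genome tiling.

    ``library_mapped_reads`` carries the total mapped reads of the library the
    track came from, for per-million normalization; ``normalized`` flags that
    depths are already in per-million units (normalizing twice is an error).
    """

    windows: pd.DataFrame  # columns: scaffold, start, end, mean_depth [, partial]
    library_mapped_reads: float
    normalized: bool = False

    def __post_init__(self) -> None:
        if (self.windows["mean_depth"] < 0).any():
            raise ValueError("mean_depth must be >= 0")
        w = self.windows
        for scaf, grp in w.groupby("scaffold", sort=False):
            starts = grp["start"].to_numpy()
            ends = grp["end"].to_numpy()
            if not (starts[1:] == ends[:-1]).all() or starts[0] != 0:
                raise ValueError(f"windows on {scaf!r} must tile the scaffold contiguously")

    def same_windows(self, other: "CoverageTrack") -> bool:
        cols = ["scaffold", "start", "end"]
        return self.windows[cols].reset_index(drop=True).equals(
            other.windows[cols].reset_index(drop=True)
        )


def read_bedgraph(
    path: str | Path,
    windows: pd.DataFrame,
    library_mapped_reads: float | None = None,
) -> CoverageTrack:
    """Aggregate a bedGraph (0-based half-open) onto a window tiling.

    Each window's ``mean_depth`` is the length-weighted mean of overlapping
    bedGraph values; uncovered bases count as depth 0.  Intervals extending
    beyond the scaffold end (as defined by the tiling) are an error.
    If ``library_mapped_reads`` is not given it is estimated as total covered
    bases / 150 (single 150 bp reads).
    """
    scaf_end = windows.groupby("scaffold")["end"].max().to_dict()
    # accumulate depth*overlap per window, window width is uniform per scaffold
    acc: dict[str, np.ndarray] = {}
    width: dict[str, int] = {}
    for scaf, grp in windows.groupby("scaffold", sort=False):
        acc[scaf] = np.zeros(len(grp))
        width[scaf] = int(grp["end"].iloc[0] - grp["start"].iloc[0])
    total_bases = 0.0
    header_reads: float | None = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("# library_mapped_reads="):
                header_reads = float(line.split("=", 1)[1])
                continue
            if not line.strip() or line.startswith(("track", "#", "browser")):
                continue
            scaf, s_s, e_s, v_s = line.split()[:4]
            s, e, v = int(s_s), int(e_s), float(v_s)
            if scaf not in acc:
                continue
            if e > scaf_end[scaf]:
                raise ValueError(
                    f"line {lineno}: interval end {e} beyond scaffold end {scaf_end[scaf]}"
                )
            total_bases += v * (e - s)
            w = width[scaf]
            first, last = s // w, (e - 1) // w
            for k in range(first, last + 1):
                lo, hi = max(s, k * w), min(e, (k + 1) * w)
                acc[scaf][k] += v * (hi - lo)
    out = windows.copy()
    depths = np.concatenate(
        [acc[scaf] / (grp["end"] - grp["start"]).to_numpy()
         for scaf, grp in windows.groupby("scaffold", sort=False)]
    )
    out["mean_depth"] = depths
    if library_mapped_reads is None:
        if header_reads is not None:
            library_mapped_reads = header_reads
        else:
            library_mapped_reads = max(1.0, round(total_bases / 150.0))
    return CoverageTrack(out, library_mapped_reads=float(library_mapped_reads))


def write_bedgraph(track: CoverageTrack, path: str | Path) -> None:
    """Write per-window depths as bedGraph (0-based half-open), 6 sig. digits."""
    with open(path, "w") as fh:
        fh.write(f"# library_mapped_reads={track.library_mapped_reads:.12g}\n")
        for row in track.windows.itertuples(index=False):
            fh.write(
                f"{row.scaffold}\t{row.start}\t{row.end}\t{FLOAT_FMT % row.mean_depth}\n"
            )
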