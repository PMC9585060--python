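"""Genomic file I/O and the coordinate contract shared by all modules.

All internal coordinates are 0-based half-open (BED convention). GTF input,
which is 1-based inclusive, is converted on read and back on write. The TSS
of a minus-strand gene is ``end - 1``; "upstream" is always strand-aware.

Supported formats: BED6, ENCODE narrowPeak (10 columns), a GTF2.2 subset
(gene/exon features), bedGraph, read-anchor BED ("readbed": one anchor
position per read), and plain TSV tables with documented headers. All
readers accept gzip-compressed files transparently.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenomicInterval",
    "Peak",
    "GeneModel",
    "CoverageTrack",
    "FormatError",
    "read_peaks",
    "write_peaks",
    "read_gene_models",
    "write_gene_models",
    "read_coverage",
    "read_de_table",
    "write_de_table",
    "read_chrom_sizes",
]

DE_COLUMNS = ["gene_id", "log2fc", "fdr", "mean_count_control", "mean_count_mutant"]

BIOTYPES = ("protein_coding", "lncRNA", "miRNA", "pseudogene", "other")


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic interval [start, end) with optional strand."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not 0 <= self.start < self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True, order=True)
class Peak:
    """A called binding/enrichment peak with optional summit position."""

    interval: GenomicInterval
    name: str = "."
    score: float = 0.0
    summit: int | None = None

    def __post_init__(self) -> None:
        if self.score < 0:
            raise ValueError(f"peak {self.name}: negative score {self.score}")
        if self.summit is not None and not (
            self.interval.start <= self.summit < self.interval.end
        ):
            raise ValueError(
                f"peak {self.name}: summit {self.summit} outside "
                f"[{self.interval.start}, {self.interval.end})"
            )

    @property
    def point(self) -> int:
        """Representative single position: summit if present, else midpoint."""
        return self.summit if self.summit is not None else self.interval.midpoint

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def start(self) -> int:
        return self.interval.start

    @property
    def end(self) -> int:
        return self.interval.end


@dataclass(frozen=True)
class GeneModel:
    """A gene with strand-aware TSS/TES, exon structure and biotype.

    ``tss`` is the first transcribed base (interval start on +, end-1 on -);
    ``tes`` is the last (end-1 on +, start on -). Exons are stored sorted
    and must be non-overlapping and contained in the gene span.
    """

    gene_id: str
    interval: GenomicInterval
    exons: tuple[GenomicInterval, ...] = ()
    biotype: str = "protein_coding"

    def __post_init__(self) -> None:
        if self.interval.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand is mandatory")
        if self.biotype not in BIOTYPES:
            raise ValueError(f"gene {self.gene_id}: unknown biotype {self.biotype!r}")
        # exons inherit the gene's strand; store them unstranded so equality
        # does not depend on the source format
        exons = tuple(sorted(
            (GenomicInterval(e.chrom, e.start, e.end) for e in self.exons),
            key=lambda e: e.start))
        object.__setattr__(self, "exons", exons)
        prev_end = None
        for ex in exons:
            if ex.chrom != self.interval.chrom:
                raise ValueError(f"gene {self.gene_id}: exon on wrong chromosome")
            if ex.start < self.interval.start or ex.end > self.interval.end:
                raise FormatError(
                    f"gene {self.gene_id}: exon [{ex.start},{ex.end}) outside "
                    f"gene span [{self.interval.start},{self.interval.end})"
                )
            if prev_end is not None and ex.start < prev_end:
                raise ValueError(f"gene {self.gene_id}: overlapping exons")
            prev_end = ex.end

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def strand(self) -> str:
        return self.interval.strand

    @property
    def tss(self) -> int:
        return self.interval.start if self.strand == "+" else self.interval.end - 1

    @property
    def tes(self) -> int:
        return self.interval.end - 1 if self.strand == "+" else self.interval.start

    def tss_distance(self, point: int) -> int:
        """Signed strand-aware distance from TSS (negative = upstream)."""
        d = point - self.tss
        return d if self.strand == "+" else -d

    def contains(self, point: int, chrom: str) -> bool:
        return (
            chrom == self.interval.chrom
            and self.interval.start <= point < self.interval.end
        )


@dataclass
class CoverageTrack:
    """Read anchors of one sequencing track, sorted per chromosome.

    Each read contributes a single anchor position (its interval midpoint for
    paired/interval formats), which makes the within-window counting rule
    deterministic. ``library_size`` may exceed the stored anchor count when
    the track is a subset of the full library.
    """

    reads: dict[str, np.ndarray]
    library_size: int
    label: str = "track"

    def __post_init__(self) -> None:
        total = 0
        for chrom, pos in self.reads.items():
            arr = np.asarray(pos, dtype=np.int64)
            if arr.ndim != 1:
                raise ValueError("read positions must be one-dimensional")
            if arr.size and np.any(np.diff(arr) < 0):
                arr = np.sort(arr)
            self.reads[chrom] = arr
            total += arr.size
        self.n_reads = total
        if self.library_size <= 0:
            raise ValueError("library_size must be positive")
        if self.library_size < total:
            raise ValueError(
                f"library_size {self.library_size} < stored reads {total}"
            )

    def count_in(self, chrom: str, start: int, end: int) -> int:
        """Number of anchors with start <= pos < end on ``chrom``."""
        pos = self.reads.get(chrom)
        if pos is None or pos.size == 0:
            return 0
        return int(np.searchsorted(pos, end) - np.searchsorted(pos, start))


# ---------------------------------------------------------------------------
# low-level helpers


def _open_text(path: str | Path) -> io.TextIOBase:
    path = Path(path)
    if path.suffix == ".gz":
        return io.TextIOWrapper(gzip.open(path, "rb"), encoding="utf-8")
    return open(path, "rt", encoding="utf-8")


_SKIP_PREFIXES = ("#", "track", "browser")


def _data_lines(handle: Iterable[str]) -> Iterator[tuple[int, list[str]]]:
    for lineno, raw in enumerate(handle, start=1):
        line = raw.rstrip("\n").rstrip("\r")
        if not line or any(line.startswith(p) for p in _SKIP_PREFIXES):
            continue
        yield lineno, line.split("\t")


def _parse_int(text: str, what: str, lineno: int) -> int:
    try:
        return int(text)
    except ValueError:
        raise FormatError(f"line {lineno}: non-integer {what}: {text!r}") from None


# ---------------------------------------------------------------------------
# peaks


def read_peaks(path: str | Path, format: str = "bed6") -> list[Peak]:
    """Read peaks from a BED6 or ENCODE narrowPeak file.

    narrowPeak column 10 holds the summit offset relative to ``start``
    (-1 meaning absent) and is converted to an absolute summit position.
    """
    if format not in ("bed6", "narrowPeak"):
        raise ValueError(f"unknown peak format {format!r}")
    peaks: list[Peak] = []
    with _open_text(path) as fh:
        for lineno, fields in _data_lines(fh):
            if len(fields) < 3:
                raise FormatError(f"line {lineno}: expected >=3 tab-separated fields")
            chrom = fields[0]
            start = _parse_int(fields[1], "start", lineno)
            end = _parse_int(fields[2], "end", lineno)
            if start >= end:
                raise FormatError(f"line {lineno}: start {start} >= end {end}")
            name = fields[3] if len(fields) > 3 and fields[3] else "."
            score = float(fields[4]) if len(fields) > 4 and fields[4] not in (".", "") else 0.0
            summit = None
            if format == "narrowPeak":
                if len(fields) < 10:
                    raise FormatError(f"line {lineno}: narrowPeak needs 10 columns")
                offset = _parse_int(fields[9], "summit offset", lineno)
                if offset >= 0:
                    summit = start + offset
            try:
                peaks.append(
                    Peak(GenomicInterval(chrom, start, end), name=name,
                         score=score, summit=summit)
                )
            except ValueError as exc:
                raise FormatError(f"line {lineno}: {exc}") from None
    return peaks


def write_peaks(peaks: Sequence[Peak], path: str | Path, format: str = "bed6") -> None:
    """Write peaks as BED6 or narrowPeak; inverse of :func:`read_peaks`."""
    if format not in ("bed6", "narrowPeak"):
        raise ValueError(f"unknown peak format {format!r}")
    with open(path, "wt", encoding="utf-8") as fh:
        for pk in peaks:
            iv = pk.interval
            cols = [iv.chrom, str(iv.start), str(iv.end), pk.name,
                    format_score(pk.score), iv.strand]
            if format == "narrowPeak":
                offset = -1 if pk.summit is None else pk.summit - iv.start
                cols += ["0", "-1", "-1", str(offset)]
            fh.write("\t".join(cols) + "\n")


def format_score(score: float) -> str:
    return str(int(score)) if float(score).is_integer() else repr(score)


# ---------------------------------------------------------------------------
# gene models

GENE_TSV_COLUMNS = ["gene_id", "chrom", "start", "end", "strand", "biotype",
                    "exon_blocks"]


def _exons_from_blocks(chrom: str, blocks: str, gene_id: str) -> tuple[GenomicInterval, ...]:
    """Parse 'start-end,start-end' exon blocks (0-based half-open)."""
    if not blocks or blocks == ".":
        return ()
    exons = []
    for part in blocks.split(","):
        s, _, e = part.partition("-")
        try:
            exons.append(GenomicInterval(chrom, int(s), int(e)))
        except ValueError as exc:
            raise FormatError(f"gene {gene_id}: bad exon block {part!r}: {exc}") from None
    return tuple(exons)


def read_gene_models(path: str | Path, format: str = "tsv") -> list[GeneModel]:
    """Read gene models from GTF (gene/exon features) or the gene-model TSV.

    GTF 1-based inclusive coordinates are converted to the internal 0-based
    half-open convention; TSS/TES are derived from strand by the GeneModel
    type itself.
    """
    if format == "gtf":
        return _read_gtf(path)
    if format != "tsv":
        raise ValueError(f"unknown gene-model format {format!r}")
    genes: list[GeneModel] = []
    seen: set[str] = set()
    with _open_text(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[: len(GENE_TSV_COLUMNS)] != GENE_TSV_COLUMNS:
            raise FormatError(
                f"gene-model TSV header must start with {GENE_TSV_COLUMNS}, got {header}"
            )
        for lineno, fields in _data_lines(fh):
            if len(fields) < 7:
                raise FormatError(f"line {lineno}: expected 7 fields")
            gene_id, chrom, start, end, strand, biotype, blocks = fields[:7]
            if gene_id in seen:
                raise FormatError(f"line {lineno}: duplicate gene_id {gene_id!r}")
            seen.add(gene_id)
            iv = GenomicInterval(chrom, _parse_int(start, "start", lineno),
                                 _parse_int(end, "end", lineno), strand)
            genes.append(
                GeneModel(gene_id, iv, _exons_from_blocks(chrom, blocks, gene_id),
                          biotype)
            )
    return genes


def _parse_gtf_attributes(text: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for item in text.rstrip(";").split(";"):
        item = item.strip()
        if not item:
            continue
        key, _, value = item.partition(" ")
        attrs[key] = value.strip().strip('"')
    return attrs


def _read_gtf(path: str | Path) -> list[GeneModel]:
    gene_rows: dict[str, tuple[GenomicInterval, str]] = {}
    exon_rows: dict[str, list[GenomicInterval]] = {}
    order: list[str] = []
    with _open_text(path) as fh:
        for lineno, fields in _data_lines(fh):
            if len(fields) < 9:
                raise FormatError(f"line {lineno}: GTF needs 9 fields")
            chrom, _source, feature, start, end, _score, strand, _frame, attr = fields[:9]
            if feature not in ("gene", "exon"):
                continue
            attrs = _parse_gtf_attributes(attr)
            if "gene_id" not in attrs:
                raise FormatError(f"line {lineno}: missing gene_id attribute")
            gid = attrs["gene_id"]
            # GTF is 1-based inclusive: [start, end] -> [start-1, end)
            iv = GenomicInterval(chrom, _parse_int(start, "start", lineno) - 1,
                                 _parse_int(end, "end", lineno), strand)
            if feature == "gene":
                if gid in gene_rows:
                    raise FormatError(f"line {lineno}: duplicate gene {gid!r}")
                biotype = attrs.get("gene_biotype", "other")
                if biotype not in BIOTYPES:
                    biotype = "pseudogene" if biotype.endswith("pseudogene") else "other"
                gene_rows[gid] = (iv, biotype)
                order.append(gid)
            else:
                exon_rows.setdefault(gid, []).append(iv)
    genes = []
    for gid in order:
        iv, biotype = gene_rows[gid]
        genes.append(GeneModel(gid, iv, tuple(exon_rows.get(gid, ())), biotype))
    return genes


def write_gene_models(genes: Sequence[GeneModel], path: str | Path,
                      format: str = "tsv") -> None:
    """Write gene models; inverse of :func:`read_gene_models` per format."""
    if format == "gtf":
        with open(path, "wt", encoding="utf-8") as fh:
            for g in genes:
                iv = g.interval
                attr = f'gene_id "{g.gene_id}"; gene_biotype "{g.biotype}";'
                fh.write("\t".join([iv.chrom, "peakscape", "gene", str(iv.start + 1),
                                    str(iv.end), ".", iv.strand, ".", attr]) + "\n")
                for ex in g.exons:
                    fh.write("\t".join([iv.chrom, "peakscape", "exon",
                                        str(ex.start + 1), str(ex.end), ".",
                                        iv.strand, ".", attr]) + "\n")
        return
    if format != "tsv":
        raise ValueError(f"unknown gene-model format {format!r}")
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("\t".join(GENE_TSV_COLUMNS) + "\n")
        for g in genes:
            blocks = ",".join(f"{e.start}-{e.end}" for e in g.exons) or "."
            fh.write("\t".join([g.gene_id, g.chrom, str(g.interval.start),
                                str(g.interval.end), g.strand, g.biotype,
                                blocks]) + "\n")


# ---------------------------------------------------------------------------
# coverage


def read_coverage(path: str | Path, format: str = "readbed",
                  library_size: int | None = None,
                  label: str | None = None) -> CoverageTrack:
    """Read a coverage track as per-chromosome sorted read anchors.

    ``readbed``: one read interval per line; the anchor is the interval
    midpoint. ``bedgraph``: each line ``chrom start end value`` is expanded
    to ``value`` synthetic anchors at the bin midpoint (value must be a
    non-negative integer-valued number). ``library_size`` defaults to the
    total anchor count.
    """
    if format not in ("readbed", "bedgraph"):
        raise ValueError(f"unknown coverage format {format!r}")
    anchors: dict[str, list[int]] = {}
    with _open_text(path) as fh:
        for lineno, fields in _data_lines(fh):
            if len(fields) < 3:
                raise FormatError(f"line {lineno}: expected >=3 fields")
            chrom = fields[0]
            start = _parse_int(fields[1], "start", lineno)
            end = _parse_int(fields[2], "end", lineno)
            if start >= end:
                raise FormatError(f"line {lineno}: start {start} >= end {end}")
            mid = (start + end) // 2
            if format == "readbed":
                anchors.setdefault(chrom, []).append(mid)
            else:
                if len(fields) < 4:
                    raise FormatError(f"line {lineno}: bedGraph needs 4 fields")
                value = float(fields[3])
                if value < 0:
                    raise FormatError(f"line {lineno}: negative coverage {value}")
                count = int(round(value))
                if count:
                    anchors.setdefault(chrom, []).extend([mid] * count)
    reads = {c: np.sort(np.asarray(p, dtype=np.int64)) for c, p in anchors.items()}
    total = sum(a.size for a in reads.values())
    if library_size is None:
        library_size = total
    if total == 0 and library_size == 0:
        raise FormatError("empty coverage track with no explicit library_size")
    return CoverageTrack(reads, library_size, label or Path(path).stem)


# ---------------------------------------------------------------------------
# DE tables and chromosome sizes


def read_de_table(path: str | Path) -> pd.DataFrame:
    """Read a differential-expression table.

    Required columns: gene_id, log2fc (mutant relative to control), fdr,
    mean_count_control, mean_count_mutant. gene_id must be unique and fdr in
    [0, 1].
    """
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in DE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"DE table missing columns: {missing}")
    df = df[DE_COLUMNS].copy()
    dupes = df["gene_id"][df["gene_id"].duplicated()].unique().tolist()
    if dupes:
        raise FormatError(f"duplicate gene_id in DE table: {dupes}")
    for col in DE_COLUMNS[1:]:
        df[col] = pd.to_numeric(df[col], errors="raise")
    if len(df) and ((df["fdr"] < 0) | (df["fdr"] > 1)).any():
        bad = df.loc[(df["fdr"] < 0) | (df["fdr"] > 1), "gene_id"].tolist()
        raise FormatError(f"fdr outside [0,1] for genes: {bad}")
    if len(df) and ((df["mean_count_control"] < 0) | (df["mean_count_mutant"] < 0)).any():
        raise FormatError("negative mean counts in DE table")
    return df.reset_index(drop=True)


def write_de_table(df: pd.DataFrame, path: str | Path) -> None:
    df[DE_COLUMNS].to_csv(path, sep="\t", index=False)


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    """Read a two-column chrom<TAB>length file."""
    sizes: dict[str, int] = {}
    with _open_text(path) as fh:
        for lineno, fields in _data_lines(fh):
            if len(fields) < 2:
                raise FormatError(f"line {lineno}: expected chrom<TAB>length")
            length = _parse_int(fields[1], "length", lineno)
            if length <= 0:
                raise FormatError(f"line {lineno}: non-positive length")
            sizes[fields[0]] = length
    return sizes
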