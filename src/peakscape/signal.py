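"""Track signal quantification at peaks and profile matrices.

RPKM at a peak counts read anchors in the peak span padded by a flank
(default 1 kb each side), normalized to the window width in kb and the
library size in millions:

    rpkm = count / (window_bp / 1000) / (library_size / 1e6)

A read is inside a window iff its anchor position is; there is no
fractional overlap. Windows are truncated at chromosome edges (position 0,
and the chromosome length when known) with the width recomputed, so edge
peaks are not penalized for missing flank.

Profile matrices come in two flavours: peak-centered (fixed-width bins
around the summit/midpoint) and metagene (gene body linearly rescaled to a
fixed number of bins, with fixed-resolution flanks, always oriented
TSS -> TES).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .genome_io import CoverageTrack, GeneModel, Peak

__all__ = [
    "PeakSignal",
    "ProfileMatrix",
    "rpkm_at_peaks",
    "peak_centered_profile",
    "metagene_profile",
    "stratified_enrichment",
]


@dataclass(frozen=True)
class PeakSignal:
    peak: str
    rpkm: float
    track: str


@dataclass
class ProfileMatrix:
    row_names: list[str]
    columns: list[str]          # bin labels: bp offsets or metagene positions
    values: np.ndarray          # rows x bins, RPKM per bin
    n_skipped: int = 0

    def mean_profile(self) -> np.ndarray:
        return self.values.mean(axis=0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.row_names, columns=self.columns)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="row")


def _rpkm(count: int, width_bp: int, library_size: int) -> float:
    return count / (width_bp / 1000.0) / (library_size / 1e6)


def rpkm_at_peaks(peaks: Sequence[Peak], track: CoverageTrack,
                  flank: int = 1000,
                  chrom_sizes: Mapping[str, int] | None = None,
                  anchor: str = "span") -> list[PeakSignal]:
    """Per-peak RPKM of ``track`` in the peak window.

    ``anchor='span'`` (default) uses [start - flank, end + flank); the
    alternative ``anchor='summit'`` uses [point - flank, point + flank),
    discarding the span. Windows are clipped to [0, chrom length].
    """
    if flank < 0:
        raise ValueError("flank must be >= 0")
    if track.library_size <= 0:
        raise ValueError("library_size must be positive")
    if anchor not in ("span", "summit"):
        raise ValueError(f"unknown anchor {anchor!r}")
    out = []
    for p in peaks:
        if anchor == "span":
            lo, hi = p.start - flank, p.end + flank
        else:
            lo, hi = p.point - flank, p.point + flank
        lo = max(0, lo)
        if chrom_sizes is not None and p.chrom in chrom_sizes:
            hi = min(hi, chrom_sizes[p.chrom])
        width = hi - lo
        if width <= 0:
            raise ValueError(f"peak {p.name}: empty query window")
        count = track.count_in(p.chrom, lo, hi)
        out.append(PeakSignal(p.name, _rpkm(count, width, track.library_size),
                              track.label))
    return out


def _bin_counts(track: CoverageTrack, chrom: str, edges: np.ndarray) -> np.ndarray:
    """Anchor counts per bin for ascending genomic bin edges."""
    pos = track.reads.get(chrom)
    if pos is None or pos.size == 0:
        return np.zeros(len(edges) - 1, dtype=np.int64)
    idx = np.searchsorted(pos, edges)
    return np.diff(idx)


def peak_centered_profile(peaks: Sequence[Peak], track: CoverageTrack,
                          half_window: int = 2000,
                          bin_width: int = 50) -> ProfileMatrix:
    """RPKM profile matrix over fixed bins centered on each peak's point."""
    if half_window % bin_width != 0:
        raise ValueError("half_window must be a multiple of bin_width")
    n_bins = 2 * half_window // bin_width
    offsets = np.arange(-half_window, half_window, bin_width)
    rows = np.zeros((len(peaks), n_bins))
    scale = 1.0 / (bin_width / 1000.0) / (track.library_size / 1e6)
    for i, p in enumerate(peaks):
        center = p.point
        edges = center + np.arange(-half_window, half_window + bin_width, bin_width)
        rows[i] = _bin_counts(track, p.chrom, edges) * scale
    return ProfileMatrix([p.name for p in peaks],
                         [str(int(o)) for o in offsets], rows)


def metagene_profile(genes: Sequence[GeneModel], track: CoverageTrack,
                     flank: int = 3000, flank_bins: int = 100,
                     body_bins: int = 100) -> ProfileMatrix:
    """TSS->TES metagene RPKM matrix with scaled body and fixed flanks.

    Columns run 5' flank (fixed bp resolution), gene body (rescaled to
    ``body_bins``), 3' flank. Minus-strand rows are reversed so column
    order is always TSS->TES. Genes shorter than ``body_bins`` bp are
    skipped and counted in ``n_skipped``.
    """
    cols = ([f"up{i}" for i in range(flank_bins)]
            + [f"body{i}" for i in range(body_bins)]
            + [f"down{i}" for i in range(flank_bins)])
    rows = []
    names = []
    skipped = 0
    lib_m = track.library_size / 1e6
    for g in genes:
        span = g.interval.width
        if span < body_bins:
            skipped += 1
            continue
        left_edges = g.interval.start + np.linspace(-flank, 0, flank_bins + 1)
        body_edges = np.linspace(g.interval.start, g.interval.end, body_bins + 1)
        right_edges = g.interval.end + np.linspace(0, flank, flank_bins + 1)
        edges = np.concatenate([left_edges[:-1], body_edges[:-1], right_edges])
        edges = np.round(edges).astype(np.int64)
        counts = _bin_counts(track, g.chrom, edges).astype(float)
        widths = np.diff(edges).astype(float)
        widths[widths == 0] = 1.0
        row = counts / (widths / 1000.0) / lib_m
        if g.strand == "-":
            row = row[::-1]
        rows.append(row)
        names.append(g.gene_id)
    values = np.vstack(rows) if rows else np.zeros((0, len(cols)))
    return ProfileMatrix(names, cols, values, n_skipped=skipped)


def stratified_enrichment(signals: Sequence[PeakSignal],
                          strata: Mapping[str, str] | Callable[[str], str]
                          ) -> pd.DataFrame:
    """Per-stratum summary of RPKM values: n, median, mean, IQR.

    ``strata`` maps peak name -> stratum label. Empty strata simply do not
    appear. Raises if a peak has no label.
    """
    label_of = strata if callable(strata) else strata.__getitem__
    records: dict[str, list[float]] = {}
    for s in signals:
        try:
            label = label_of(s.peak)
        except KeyError:
            raise ValueError(f"peak {s.peak!r} has no stratum label") from None
        records.setdefault(label, []).append(s.rpkm)
    rows = []
    for label in sorted(records):
        vals = np.asarray(records[label])
        q1, med, q3 = np.percentile(vals, [25, 50, 75])
        rows.append({"stratum": label, "n": vals.size, "median": float(med),
                     "mean": float(vals.mean()), "iqr": float(q3 - q1)})
    return pd.DataFrame(rows, columns=["stratum", "n", "median", "mean", "iqr"])
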