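"""Peak region classification and nearest-promoter gene assignment.

Region definitions (all strand-aware):

* promoter — the 3 kb immediately upstream of a TSS, i.e. signed TSS
  distance in [-3000, 0);
* intragenic — inside a gene body (exons, introns, the UTR proxies) or up
  to 300 bp downstream of a TES;
* distal intergenic — everything else.

A peak is classified by a single point: its summit when present, else its
interval midpoint. When windows of different genes overlap, promoter takes
precedence over intragenic, which takes precedence over distal. Each peak
is assigned to the gene with the nearest TSS (absolute strand-aware
distance; ties broken by lexicographically smallest gene_id), except that a
nearest pseudogene is skipped in favour of the enclosing non-pseudogene
gene when the peak point lies inside one — small pseudogenes embedded in a
real gene's body would otherwise capture its peaks.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .genome_io import GeneModel, Peak

__all__ = [
    "PeakAnnotation",
    "PROMOTER_UPSTREAM",
    "DOWNSTREAM_WINDOW",
    "classify_region",
    "assign_gene",
    "annotate_peaks",
    "summarize_regions",
    "annotations_to_frame",
]

PROMOTER_UPSTREAM = 3000
DOWNSTREAM_WINDOW = 300

REGION_CLASSES = ("promoter", "intragenic", "distal_intergenic")
SUBREGIONS = ("5UTR-proxy:first-exon", "exon", "intron", "downstream<=300", "none")


@dataclass(frozen=True)
class PeakAnnotation:
    peak: Peak
    region_class: str
    subregion: str
    assigned_gene: str | None
    distance_to_tss: int | None  # signed; negative = upstream, strand-aware


class _GeneIndex:
    """Per-chromosome arrays for fast point queries against gene models."""

    def __init__(self, genes: Sequence[GeneModel],
                 promoter_upstream: int = PROMOTER_UPSTREAM,
                 downstream_window: int = DOWNSTREAM_WINDOW):
        self.promoter_upstream = promoter_upstream
        self.downstream_window = downstream_window
        self.by_chrom: dict[str, list[GeneModel]] = {}
        for g in genes:
            self.by_chrom.setdefault(g.chrom, []).append(g)
        # TSS arrays sorted by (tss, gene_id) so the lexicographic tie-break
        # falls out of a stable argmin
        self._tss: dict[str, tuple[np.ndarray, list[GeneModel]]] = {}
        for chrom, gs in self.by_chrom.items():
            gs_sorted = sorted(gs, key=lambda g: (g.tss, g.gene_id))
            self._tss[chrom] = (np.array([g.tss for g in gs_sorted], dtype=np.int64),
                                gs_sorted)

    def genes_on(self, chrom: str) -> list[GeneModel]:
        return self.by_chrom.get(chrom, [])

    def nearest_by_tss(self, chrom: str, point: int) -> GeneModel | None:
        entry = self._tss.get(chrom)
        if entry is None:
            return None
        tss, gs = entry
        dist = np.abs(tss - point)
        best = int(np.flatnonzero(dist == dist.min())[0])  # stable: smallest tss
        # among equal distances, pick lexicographically smallest gene_id
        cands = [gs[i] for i in np.flatnonzero(dist == dist.min())]
        return min(cands, key=lambda g: g.gene_id) if len(cands) > 1 else gs[best]

    def promoter_genes(self, chrom: str, point: int) -> list[GeneModel]:
        out = []
        for g in self.genes_on(chrom):
            d = g.tss_distance(point)
            if -self.promoter_upstream <= d < 0:
                out.append(g)
        return out

    def enclosing_genes(self, chrom: str, point: int) -> list[GeneModel]:
        return [g for g in self.genes_on(chrom) if g.contains(point, chrom)]

    def downstream_genes(self, chrom: str, point: int) -> list[GeneModel]:
        out = []
        for g in self.genes_on(chrom):
            if g.chrom != chrom:
                continue
            d = point - g.tes if g.strand == "+" else g.tes - point
            if 0 < d <= self.downstream_window:
                out.append(g)
        return out


def _tes_distance_ok(gene: GeneModel, point: int, window: int) -> bool:
    d = point - gene.tes if gene.strand == "+" else gene.tes - point
    return 0 < d <= window


def _subregion(gene: GeneModel, point: int, downstream: bool) -> str:
    if downstream:
        return "downstream<=300"
    if not gene.exons:
        return "none"
    first = gene.exons[0] if gene.strand == "+" else gene.exons[-1]
    for ex in gene.exons:
        if ex.start <= point < ex.end:
            return "5UTR-proxy:first-exon" if ex == first else "exon"
    return "intron"


def assign_gene(peak: Peak, genes: Sequence[GeneModel] | _GeneIndex) -> str | None:
    """Nearest-TSS gene for a peak, with the pseudogene reassignment rule.

    Returns None when no gene shares the peak's chromosome.
    """
    index = genes if isinstance(genes, _GeneIndex) else _GeneIndex(genes)
    point = peak.point
    nearest = index.nearest_by_tss(peak.chrom, point)
    if nearest is None:
        return None
    if nearest.biotype == "pseudogene":
        hosts = [g for g in index.enclosing_genes(peak.chrom, point)
                 if g.biotype != "pseudogene"]
        if hosts:
            return min(hosts, key=lambda g: g.gene_id).gene_id
    return nearest.gene_id


def classify_region(peak: Peak, genes: Sequence[GeneModel] | _GeneIndex) -> PeakAnnotation:
    """Classify one peak and assign it to a gene.

    Precedence when gene windows overlap: promoter > intragenic > distal.
    With an empty gene set every peak is distal_intergenic with no assigned
    gene. For promoter peaks the assigned gene is the nearest among the
    genes whose promoter window contains the point, so the reported TSS
    distance always satisfies -3000 <= d < 0.
    """
    index = genes if isinstance(genes, _GeneIndex) else _GeneIndex(genes)
    point = peak.point
    chrom = peak.chrom

    promoter = index.promoter_genes(chrom, point)
    if promoter:
        gene = min(promoter, key=lambda g: (abs(g.tss_distance(point)), g.gene_id))
        return PeakAnnotation(peak, "promoter", "none", gene.gene_id,
                              gene.tss_distance(point))

    enclosing = index.enclosing_genes(chrom, point)
    downstream = index.downstream_genes(chrom, point)
    if enclosing or downstream:
        assigned = assign_gene(peak, index)
        body = [g for g in enclosing if g.biotype != "pseudogene"] or enclosing
        if body:
            gene = min(body, key=lambda g: (abs(g.tss_distance(point)), g.gene_id))
            sub = _subregion(gene, point, downstream=False)
        else:
            gene = min(downstream, key=lambda g: g.gene_id)
            sub = "downstream<=300"
        ref = next((g for g in index.genes_on(chrom) if g.gene_id == assigned), gene)
        return PeakAnnotation(peak, "intragenic", sub, assigned,
                              ref.tss_distance(point))

    assigned = assign_gene(peak, index)
    if assigned is None:
        return PeakAnnotation(peak, "distal_intergenic", "none", None, None)
    ref = next(g for g in index.genes_on(chrom) if g.gene_id == assigned)
    return PeakAnnotation(peak, "distal_intergenic", "none", assigned,
                          ref.tss_distance(point))


def annotate_peaks(peaks: Iterable[Peak],
                   genes: Sequence[GeneModel]) -> list[PeakAnnotation]:
    """Classify and assign every peak against one shared gene index."""
    index = _GeneIndex(genes)
    return [classify_region(p, index) for p in peaks]


def annotations_to_frame(annotations: Sequence[PeakAnnotation]) -> pd.DataFrame:
    rows = []
    for a in annotations:
        rows.append({
            "peak": a.peak.name,
            "chrom": a.peak.chrom,
            "start": a.peak.start,
            "end": a.peak.end,
            "region_class": a.region_class,
            "subregion": a.subregion,
            "assigned_gene": a.assigned_gene if a.assigned_gene is not None else "none",
            "distance_to_tss": a.distance_to_tss,
        })
    return pd.DataFrame(rows, columns=["peak", "chrom", "start", "end",
                                       "region_class", "subregion",
                                       "assigned_gene", "distance_to_tss"])


def summarize_regions(annotations: Sequence[PeakAnnotation],
                      genes: Sequence[GeneModel] | None = None,
                      stratify_by_biotype: bool = False) -> pd.DataFrame:
    """Counts and percentages per region class, optionally per gene biotype.

    Percentages are over the total annotation count and sum to 100 up to
    rounding.
    """
    if not annotations:
        raise ValueError("no annotations to summarize")
    df = pd.DataFrame({
        "region_class": [a.region_class for a in annotations],
        "assigned_gene": [a.assigned_gene for a in annotations],
    })
    total = len(df)
    if stratify_by_biotype:
        if genes is None:
            raise ValueError("stratification requires the gene models")
        biotype = {g.gene_id: g.biotype for g in genes}
        df["biotype"] = df["assigned_gene"].map(lambda g: biotype.get(g, "none"))
        grouped = df.groupby(["region_class", "biotype"]).size()
        out = grouped.rename("count").reset_index()
    else:
        counts = df["region_class"].value_counts()
        out = pd.DataFrame({
            "region_class": list(REGION_CLASSES),
            "count": [int(counts.get(c, 0)) for c in REGION_CLASSES],
        })
    out["percent"] = 100.0 * out["count"] / total
    return out
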