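"""Synthetic genomes, peaks, coverage and DE tables with planted truth.

Every generator takes a :class:`SyntheticConfig` whose single integer seed
fully determines the output: each generator draws from its own named RNG
substream, so adding a new generator never perturbs the draws of existing
ones. The shapes emulated are those of a TF ChIP-seq study in embryonic
kidney: a peak set with a controllable promoter/intragenic/distal mix, a
companion open-chromatin peak set with a known bin-level colocalization
odds ratio, coverage tracks with fold-enrichment planted at a chosen peak
subset, and a differential-expression table with planted direct targets.

Defaults are desk-scale (2 x 1 Mb chromosomes, 200 genes, 500 peaks,
seconds on one CPU) with the study's composition: region mix
26/37/37 promoter/intragenic/distal and a colocalization odds ratio of 16.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np

from .genome_io import CoverageTrack, GeneModel, GenomicInterval, Peak

__all__ = [
    "SyntheticConfig",
    "generate_annotation",
    "generate_peaks",
    "generate_colocalized_peaks",
    "generate_coverage",
    "generate_de_table",
    "simulate_all",
]

# minimum inter-gene gap: promoter (3 kb) + downstream window (300 bp) +
# margin, so promoter windows never reach a neighbouring gene body and some
# distal space always remains
MIN_GENE_GAP = 3500


@dataclass
class SyntheticConfig:
    seed: int = 0
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"chr1": 1_000_000, "chr2": 1_000_000})
    n_genes: int = 200
    gene_length_range: tuple[int, int] = (1_000, 8_000)
    biotype_mix: dict[str, float] = field(default_factory=lambda: {
        "protein_coding": 0.80, "lncRNA": 0.08, "miRNA": 0.02,
        "pseudogene": 0.05, "other": 0.05})
    n_peaks: int = 500
    region_mix: tuple[float, float, float] = (0.26, 0.37, 0.37)
    peak_width_median: int = 300
    coloc_odds_ratio: float = 16.0
    coloc_base_rate: float = 0.05      # B-hit probability in non-A bins
    coloc_bin_width: int | None = None  # default: median A peak width
    enrichment_fold: float = 2.0
    background_rate: float = 0.01      # reads per bp
    signal_flank: int = 1000           # planted enrichment covers peak +/- flank
    library_size: int | None = None    # default: total generated reads
    n_direct_activated: int = 50
    n_direct_repressed: int = 50
    lfc_effect: float = 1.0
    fdr_noise: float = 0.02            # fraction of spurious significant nulls
    filtered_fraction: float = 0.05    # genes below the count filter

    def __post_init__(self) -> None:
        for name, mix in (("biotype_mix", list(self.biotype_mix.values())),
                          ("region_mix", list(self.region_mix))):
            if any(f < 0 or f > 1 for f in mix) or abs(sum(mix) - 1.0) > 1e-9:
                raise ValueError(f"{name} fractions must be in [0,1] and sum to 1")

    def rng(self, stream: str) -> np.random.Generator:
        """Named-substream RNG: deterministic in (seed, stream name)."""
        return np.random.default_rng(
            np.random.SeedSequence([self.seed, zlib.crc32(stream.encode())]))

    def to_dict(self) -> dict:
        return asdict(self)


def generate_annotation(config: SyntheticConfig) -> list[GeneModel]:
    """Non-overlapping genes with >=3.5 kb spacing, random strands/exons."""
    rng = config.rng("annotation")
    chroms = sorted(config.chrom_lengths)
    total_len = sum(config.chrom_lengths.values())
    # genes per chromosome proportional to length
    per_chrom = {c: int(round(config.n_genes * config.chrom_lengths[c] / total_len))
                 for c in chroms}
    drift = config.n_genes - sum(per_chrom.values())
    per_chrom[chroms[0]] += drift

    genes: list[GeneModel] = []
    gid = 0
    lo, hi = config.gene_length_range
    for chrom in chroms:
        n_c = per_chrom[chrom]
        if n_c == 0:
            continue
        L = config.chrom_lengths[chrom]
        lengths = rng.integers(lo, hi + 1, size=n_c)
        needed = int(lengths.sum()) + (n_c + 1) * MIN_GENE_GAP
        if needed > L:
            raise ValueError(
                f"cannot pack {n_c} genes into {chrom} ({L} bp, need {needed}); "
                "use a larger genome or fewer/shorter genes")
        slack = L - needed
        extra = rng.multinomial(slack, np.full(n_c + 1, 1.0 / (n_c + 1)))
        pos = 0
        for i in range(n_c):
            pos += MIN_GENE_GAP + int(extra[i])
            start, end = pos, pos + int(lengths[i])
            strand = "+" if rng.random() < 0.5 else "-"
            biotype = str(rng.choice(list(config.biotype_mix),
                                     p=list(config.biotype_mix.values())))
            exons = _random_exons(rng, chrom, start, end)
            genes.append(GeneModel(f"gene{gid:04d}",
                                   GenomicInterval(chrom, start, end, strand),
                                   exons, biotype))
            gid += 1
            pos = end
    return genes


def _random_exons(rng: np.random.Generator, chrom: str, start: int,
                  end: int) -> tuple[GenomicInterval, ...]:
    n_exons = int(rng.integers(1, 6))
    if n_exons == 1 or end - start < 2 * n_exons + 2:
        return (GenomicInterval(chrom, start, end),)
    cuts = np.sort(rng.choice(np.arange(start + 1, end - 1), size=2 * (n_exons - 1),
                              replace=False))
    bounds = [start, *cuts.tolist(), end]
    return tuple(GenomicInterval(chrom, bounds[i], bounds[i + 1])
                 for i in range(0, len(bounds) - 1, 2))


def _promoter_window(g: GeneModel) -> tuple[int, int]:
    if g.strand == "+":
        return g.tss - 3000, g.tss
    return g.tss + 1, g.tss + 3001


def _downstream_window(g: GeneModel) -> tuple[int, int]:
    if g.strand == "+":
        return g.tes + 1, g.tes + 301
    return g.tes - 300, g.tes


def _distal_space(genes: Sequence[GeneModel],
                  chrom_lengths: Mapping[str, int]) -> dict[str, list[tuple[int, int]]]:
    """Complement of gene bodies, promoter windows and downstream windows."""
    forbidden: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_lengths}
    for g in genes:
        spans = [(g.interval.start, g.interval.end), _promoter_window(g),
                 _downstream_window(g)]
        for s, e in spans:
            forbidden[g.chrom].append((max(0, s), min(chrom_lengths[g.chrom], e)))
    out: dict[str, list[tuple[int, int]]] = {}
    for chrom, spans in forbidden.items():
        spans.sort()
        merged: list[list[int]] = []
        for s, e in spans:
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        free: list[tuple[int, int]] = []
        prev = 0
        for s, e in merged:
            if s > prev:
                free.append((prev, s))
            prev = max(prev, e)
        if prev < chrom_lengths[chrom]:
            free.append((prev, chrom_lengths[chrom]))
        out[chrom] = [iv for iv in free if iv[1] - iv[0] > 2]
    return out


def generate_peaks(annotation: Sequence[GeneModel],
                   config: SyntheticConfig) -> list[Peak]:
    """Peaks whose summits fall in region classes sampled from region_mix."""
    rng = config.rng("peaks")
    if config.n_peaks == 0:
        return []
    genes = list(annotation)
    distal = _distal_space(genes, config.chrom_lengths)
    distal_flat = [(c, s, e) for c, ivs in distal.items() for s, e in ivs]
    if not distal_flat and config.region_mix[2] > 0:
        raise ValueError("no intergenic space left for distal peaks")
    distal_weights = np.array([e - s for _, s, e in distal_flat], dtype=float)
    distal_weights /= distal_weights.sum() if len(distal_weights) else 1.0

    peaks: list[Peak] = []
    classes = rng.choice(3, size=config.n_peaks, p=list(config.region_mix))
    widths = np.clip(rng.lognormal(np.log(config.peak_width_median), 0.35,
                                   size=config.n_peaks), 50, 2000).astype(int)
    for i in range(config.n_peaks):
        cls = int(classes[i])
        if cls in (0, 1) and not genes:
            raise ValueError("promoter/intragenic peaks need genes")
        if cls == 0:  # promoter
            g = genes[int(rng.integers(len(genes)))]
            d = int(rng.integers(1, 3001))
            summit = g.tss - d if g.strand == "+" else g.tss + d
        elif cls == 1:  # intragenic (gene body)
            g = genes[int(rng.integers(len(genes)))]
            summit = int(rng.integers(g.interval.start, g.interval.end))
        else:  # distal intergenic
            j = int(rng.choice(len(distal_flat), p=distal_weights))
            c, s, e = distal_flat[j]
            summit = int(rng.integers(s, e))
        chrom = g.chrom if cls in (0, 1) else distal_flat[j][0]
        L = config.chrom_lengths[chrom]
        summit = int(np.clip(summit, 0, L - 1))
        w = int(widths[i])
        start = max(0, summit - w // 2)
        end = min(L, start + w)
        if end <= summit:
            end = summit + 1
        peaks.append(Peak(GenomicInterval(chrom, start, end),
                          name=f"peak{i:05d}", score=float(rng.integers(10, 1000)),
                          summit=summit))
    return peaks


def generate_colocalized_peaks(A: Sequence[Peak], genome: Mapping[str, int],
                               theta: float,
                               config: SyntheticConfig) -> list[Peak]:
    """A companion peak set with bin-level odds ratio ``theta`` against A.

    The genome is tiled as in the colocalization test; bins already hit by
    A receive a companion peak with probability p1 and other bins with
    probability p0 = ``coloc_base_rate``, where odds(p1) = theta * odds(p0),
    so the expected bin-hit odds ratio equals theta. Each companion peak is
    placed entirely inside its bin.
    """
    if theta < 0:
        raise ValueError("theta must be >= 0")
    rng = config.rng("coloc")
    bin_width = config.coloc_bin_width
    if bin_width is None:
        bin_width = int(np.median([p.interval.width for p in A])) if A else 300
    p0 = config.coloc_base_rate
    if not 0 < p0 < 1:
        raise ValueError("coloc_base_rate must be in (0,1)")
    odds1 = theta * p0 / (1 - p0)
    p1 = odds1 / (1 + odds1)
    if max(p0, p1) >= 1:
        raise ValueError("requested colocalization density infeasible")

    a_bins: dict[str, set[int]] = {c: set() for c in genome}
    for p in A:
        nbins = -(-genome[p.chrom] // bin_width)
        first = p.start // bin_width
        last = min((p.end - 1) // bin_width, nbins - 1)
        a_bins[p.chrom].update(range(first, last + 1))

    out: list[Peak] = []
    k = 0
    for chrom in sorted(genome):
        nbins = -(-genome[chrom] // bin_width)
        hits_a = a_bins[chrom]
        u = rng.random(nbins)
        for b in range(nbins):
            p_hit = p1 if b in hits_a else p0
            if u[b] >= p_hit:
                continue
            bin_start = b * bin_width
            bin_end = min(bin_start + bin_width, genome[chrom])
            w = max(2, int(0.6 * (bin_end - bin_start)))
            start = bin_start + int(rng.integers(0, bin_end - bin_start - w + 1))
            out.append(Peak(GenomicInterval(chrom, start, start + w),
                            name=f"coloc{k:05d}", score=0.0))
            k += 1
    return out


def generate_coverage(signal_peaks: Sequence[Peak], config: SyntheticConfig,
                      label: str = "track") -> CoverageTrack:
    """Poisson background plus planted fold-enrichment at ``signal_peaks``.

    Background anchors arrive at ``background_rate`` reads/bp genome-wide;
    within each signal peak's quantification window (span padded by
    ``signal_flank``) additional anchors arrive at
    (enrichment_fold - 1) x background_rate, so the total in-window rate is
    enrichment_fold x background and the planted RPKM contrast equals
    ``enrichment_fold``.
    """
    if config.enrichment_fold < 1:
        raise ValueError("enrichment_fold must be >= 1")
    if config.library_size is not None and config.library_size <= 0:
        raise ValueError("library_size must be positive")
    rng = config.rng(f"coverage:{label}")
    anchors: dict[str, list[np.ndarray]] = {c: [] for c in config.chrom_lengths}
    for chrom, L in sorted(config.chrom_lengths.items()):
        n_bg = int(rng.poisson(config.background_rate * L))
        if n_bg:
            anchors[chrom].append(rng.integers(0, L, size=n_bg))
    extra_rate = (config.enrichment_fold - 1) * config.background_rate
    if extra_rate > 0:
        for p in signal_peaks:
            L = config.chrom_lengths[p.chrom]
            lo = max(0, p.start - config.signal_flank)
            hi = min(L, p.end + config.signal_flank)
            n_sig = int(rng.poisson(extra_rate * (hi - lo)))
            if n_sig:
                anchors[p.chrom].append(rng.integers(lo, hi, size=n_sig))
    reads = {c: np.sort(np.concatenate(a)) if a else np.empty(0, dtype=np.int64)
             for c, a in anchors.items()}
    total = sum(v.size for v in reads.values())
    lib = config.library_size if config.library_size is not None else max(total, 1)
    return CoverageTrack(reads, lib, label)


def generate_de_table(annotation: Sequence[GeneModel], bound_genes: set[str],
                      config: SyntheticConfig):
    """DE table over all genes with planted direct targets; returns (df, truth).

    Planted activated genes get log2fc <= -lfc_effect with fdr < 0.05;
    planted repressed genes mirrored. Remaining genes are null: a
    ``fdr_noise`` fraction become spuriously significant, a
    ``filtered_fraction`` fall below the 25-count expression filter, and
    the rest stay within the unchanged band. Planted genes are drawn from
    ``bound_genes`` only.
    """
    import pandas as pd

    rng = config.rng("de")
    gene_ids = [g.gene_id for g in annotation]
    n_planted = config.n_direct_activated + config.n_direct_repressed
    candidates = sorted(bound_genes & set(gene_ids))
    if n_planted > len(candidates):
        raise ValueError(
            f"cannot plant {n_planted} direct targets among "
            f"{len(candidates)} bound genes")
    chosen = rng.permutation(candidates)[:n_planted]
    act = set(chosen[: config.n_direct_activated].tolist())
    rep = set(chosen[config.n_direct_activated:].tolist())

    rows = []
    spurious: list[str] = []
    for gid in gene_ids:
        if gid in act or gid in rep:
            magnitude = config.lfc_effect + abs(rng.normal(0, 0.25))
            lfc = -magnitude if gid in act else magnitude
            fdr = float(rng.uniform(1e-8, min(0.049, 0.05)))
            control = float(rng.uniform(50, 500))
            mutant = control * 2.0 ** lfc
        else:
            r = rng.random()
            if r < config.filtered_fraction:
                control = float(rng.uniform(0, 24.9))
                mutant = float(rng.uniform(0, 24.9))
                lfc = float(rng.normal(0, 1.0))
                fdr = float(rng.uniform(0, 1))
            elif r < config.filtered_fraction + config.fdr_noise:
                sign = 1.0 if rng.random() < 0.5 else -1.0
                lfc = sign * (0.5 + abs(rng.normal(0, 0.3)))
                fdr = float(rng.uniform(1e-8, 0.049))
                control = float(rng.uniform(30, 500))
                mutant = control * 2.0 ** lfc
                spurious.append(gid)
            else:
                lfc = float(np.clip(rng.normal(0, 0.15), -0.49, 0.49))
                fdr = float(rng.uniform(0.05, 1.0))
                control = float(rng.uniform(30, 500))
                mutant = control * 2.0 ** lfc
        rows.append({"gene_id": gid, "log2fc": round(float(lfc), 4),
                     "fdr": fdr, "mean_count_control": round(control, 2),
                     "mean_count_mutant": round(mutant, 2)})
    df = pd.DataFrame(rows)
    truth = {"direct_activated": sorted(act), "direct_repressed": sorted(rep),
             "spurious_significant": spurious}
    return df, truth


def simulate_all(config: SyntheticConfig) -> dict:
    """Run every generator coherently and return all artifacts plus truth.

    The coverage track plants its enrichment at the peaks assigned to the
    planted directly-activated genes, emulating higher signal at
    activated-gene binding sites.
    """
    from .annotation import annotate_peaks

    genes = generate_annotation(config)
    peaks = generate_peaks(genes, config)
    annotations = annotate_peaks(peaks, genes)
    bound = {a.assigned_gene for a in annotations if a.assigned_gene is not None}
    de, truth = generate_de_table(genes, bound, config)
    coloc = generate_colocalized_peaks(peaks, config.chrom_lengths,
                                       config.coloc_odds_ratio, config)
    act = set(truth["direct_activated"])
    signal_peaks = [a.peak for a in annotations if a.assigned_gene in act]
    coverage = generate_coverage(signal_peaks, config, label="ATAC")
    truth = dict(truth)
    truth["signal_peaks"] = sorted(p.name for p in signal_peaks)
    truth["config"] = config.to_dict()
    return {"genes": genes, "peaks": peaks, "annotations": annotations,
            "coloc_peaks": coloc, "coverage": coverage, "de": de,
            "truth": truth}
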