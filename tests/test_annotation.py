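"""Region classification, gene assignment and their invariants."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from peakscape.annotation import (annotate_peaks, assign_gene, classify_region,
                                  summarize_regions)
from peakscape.genome_io import GenomicInterval, GeneModel

from conftest import make_gene, make_peak


# --- brute-force re-derivation of the region definitions (no indexes) ------

def oracle_region(chrom, point, genes):
    for g in genes:
        if g.chrom == chrom and -3000 <= g.tss_distance(point) < 0:
            return "promoter"
    for g in genes:
        if g.chrom != chrom:
            continue
        if g.interval.start <= point < g.interval.end:
            return "intragenic"
        d = point - g.tes if g.strand == "+" else g.tes - point
        if 0 < d <= 300:
            return "intragenic"
    return "distal_intergenic"


def oracle_nearest(chrom, point, genes):
    on_chrom = [g for g in genes if g.chrom == chrom]
    if not on_chrom:
        return None
    best = min(abs(g.tss - point) for g in on_chrom)
    nearest = min((g for g in on_chrom if abs(g.tss - point) == best),
                  key=lambda g: g.gene_id)
    if nearest.biotype == "pseudogene":
        hosts = [g for g in on_chrom if g.biotype != "pseudogene"
                 and g.interval.start <= point < g.interval.end]
        if hosts:
            return min(hosts, key=lambda g: g.gene_id).gene_id
    return nearest.gene_id


class TestClassifyRegion:
    def test_promoter_upstream_plus(self, plus_gene):
        ann = classify_region(make_peak("chr1", 3400, 3600), [plus_gene])
        assert ann.region_class == "promoter"
        assert ann.distance_to_tss == -1500

    def test_downstream_within_300(self, plus_gene):
        ann = classify_region(make_peak("chr1", 8100, 8301), [plus_gene])
        assert ann.region_class == "intragenic"
        assert ann.subregion == "downstream<=300"

    def test_far_point_is_distal(self, plus_gene):
        ann = classify_region(make_peak("chr1", 19900, 20100), [plus_gene])
        assert ann.region_class == "distal_intergenic"

    def test_minus_strand_promoter_is_rightward(self, minus_gene):
        # TSS at 7999; point 8500 is 501 bp upstream on the - strand
        ann = classify_region(make_peak("chr1", 8400, 8601), [minus_gene])
        assert ann.region_class == "promoter"
        assert ann.distance_to_tss == -501

    def test_summit_beats_midpoint(self, plus_gene):
        # midpoint would be distal; summit is in the promoter window
        pk = make_peak("chr1", 2000, 16000, summit=4000)
        assert classify_region(pk, [plus_gene]).region_class == "promoter"

    def test_empty_gene_set(self):
        ann = classify_region(make_peak("chr1", 100, 200), [])
        assert ann.region_class == "distal_intergenic"
        assert ann.assigned_gene is None

    def test_promoter_precedence_over_intragenic(self):
        # point inside gA's body and inside gB's promoter window
        ga = make_gene("gA", "chr1", 1000, 9000, "+")
        gb = make_gene("gB", "chr1", 10000, 12000, "+")
        ann = classify_region(make_peak("chr1", 8490, 8510), [ga, gb])
        assert ann.region_class == "promoter"
        assert ann.assigned_gene == "gB"
        assert -3000 <= ann.distance_to_tss < 0

    def test_first_exon_subregion(self, plus_gene):
        assert classify_region(make_peak("chr1", 5090, 5110),
                               [plus_gene]).subregion == "5UTR-proxy:first-exon"
        assert classify_region(make_peak("chr1", 6490, 6510),
                               [plus_gene]).subregion == "intron"
        assert classify_region(make_peak("chr1", 7490, 7510),
                               [plus_gene]).subregion == "exon"


class TestAssignGene:
    def test_equidistant_tie_breaks_lexicographically(self):
        ga = make_gene("geneA", "chr1", 10000, 12000, "+")  # TSS 10000
        gb = make_gene("geneB", "chr1", 6001, 8001, "-")    # TSS 8000
        pk = make_peak("chr1", 8999, 9001, summit=9000)     # 1000 bp from each
        assert assign_gene(pk, [ga, gb]) == "geneA"

    def test_pseudogene_reassigned_to_host(self):
        host = make_gene("geneX", "chr1", 1000, 20000, "+")
        pseudo = make_gene("pseudoP", "chr1", 9000, 9500, "+",
                           biotype="pseudogene")
        pk = make_peak("chr1", 9190, 9210)  # nearest TSS is the pseudogene's
        assert assign_gene(pk, [host, pseudo]) == "geneX"

    def test_pseudogene_kept_when_no_host(self):
        pseudo = make_gene("pseudoP", "chr1", 9000, 9500, "+",
                           biotype="pseudogene")
        pk = make_peak("chr1", 9190, 9210)
        assert assign_gene(pk, [pseudo]) == "pseudoP"

    def test_single_gene_always_wins(self, plus_gene):
        for pos in (0, 5000, 400000):
            pk = make_peak("chr1", pos, pos + 10)
            assert assign_gene(pk, [plus_gene]) == "geneP"


class TestSummarize:
    def test_counts_and_percentages(self, plus_gene):
        peaks = ([make_peak("chr1", 3000 + i, 3010 + i) for i in range(3)]
                 + [make_peak("chr1", 6000 + i, 6010 + i) for i in range(4)]
                 + [make_peak("chr1", 50000 + i, 50010 + i) for i in range(3)])
        anns = annotate_peaks(peaks, [plus_gene])
        out = summarize_regions(anns).set_index("region_class")
        assert out.loc["promoter", "count"] == 3
        assert out.loc["intragenic", "count"] == 4
        assert out.loc["distal_intergenic", "percent"] == 30.0
        assert out["count"].sum() == 10
        assert out["percent"].sum() == pytest.approx(100.0)

    def test_all_one_class(self, plus_gene):
        anns = annotate_peaks([make_peak("chr1", 4000, 4010)] * 5, [plus_gene])
        out = summarize_regions(anns).set_index("region_class")
        assert out.loc["promoter", "percent"] == 100.0

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            summarize_regions([])


# --- properties -------------------------------------------------------------

genes_strategy = st.lists(
    st.tuples(st.integers(0, 90_000), st.integers(200, 8000),
              st.sampled_from("+-"),
              st.sampled_from(["protein_coding", "pseudogene", "lncRNA"])),
    min_size=0, max_size=8)


@settings(max_examples=200, deadline=None, derandomize=True)
@given(genes=genes_strategy, point=st.integers(0, 99_999))
def test_matches_bruteforce_oracle(genes, point):
    """Classification and assignment agree with the unindexed oracle."""
    models = [make_gene(f"g{i:02d}", "chr1", s, s + w, strand, biotype)
              for i, (s, w, strand, biotype) in enumerate(genes)]
    pk = make_peak("chr1", point, point + 1, summit=point)
    ann = classify_region(pk, models)
    assert ann.region_class == oracle_region("chr1", point, models)
    assert assign_gene(pk, models) == oracle_nearest("chr1", point, models)


def test_partition_and_strand_mirror():
    """Every peak gets exactly one class; reflecting the genome and flipping
    strands leaves the class counts unchanged."""
    L = 100_000
    rng = np.random.default_rng(0)
    models = [make_gene("g0", "chr1", 10_000, 18_000, "+"),
              make_gene("g1", "chr1", 30_000, 31_500, "-"),
              make_gene("g2", "chr1", 60_000, 75_000, "+")]
    peaks = [make_peak("chr1", int(p), int(p) + 10, summit=int(p) + 5)
             for p in rng.integers(0, L - 10, size=400)]
    anns = annotate_peaks(peaks, models)
    counts = summarize_regions(anns).set_index("region_class")["count"]
    assert counts.sum() == len(peaks)

    flip = {"+": "-", "-": "+"}
    mirrored_models = [
        GeneModel(g.gene_id,
                  GenomicInterval("chr1", L - g.interval.end,
                                  L - g.interval.start, flip[g.strand]),
                  biotype=g.biotype)
        for g in models]
    mirrored_peaks = [make_peak("chr1", L - p.end, L - p.start,
                                summit=L - 1 - p.summit) for p in peaks]
    mcounts = summarize_regions(
        annotate_peaks(mirrored_peaks, mirrored_models)
    ).set_index("region_class")["count"]
    assert (counts == mcounts).all()
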