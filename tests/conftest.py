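import numpy as np
import pytest

from peakscape.genome_io import (CoverageTrack, GeneModel, GenomicInterval,
                                 Peak)


def make_peak(chrom, start, end, name=".", summit=None, score=0.0):
    return Peak(GenomicInterval(chrom, start, end), name=name, score=score,
                summit=summit)


def make_gene(gene_id, chrom, start, end, strand, biotype="protein_coding",
              exons=()):
    return GeneModel(gene_id, GenomicInterval(chrom, start, end, strand),
                     tuple(GenomicInterval(chrom, s, e) for s, e in exons),
                     biotype)


@pytest.fixture
def plus_gene():
    """Gene on + strand occupying [5000, 8000): TSS 5000, TES 7999."""
    return make_gene("geneP", "chr1", 5000, 8000, "+",
                     exons=[(5000, 5600), (7000, 8000)])


@pytest.fixture
def minus_gene():
    """Gene on - strand occupying [5000, 8000): TSS 7999, TES 5000."""
    return make_gene("geneM", "chr1", 5000, 8000, "-",
                     exons=[(5000, 5600), (7000, 8000)])


@pytest.fixture
def uniform_track():
    """Dense uniform random coverage on a 1 Mb chr1 (~0.3 reads/bp)."""
    rng = np.random.default_rng(42)
    pos = np.sort(rng.integers(0, 1_000_000, size=300_000))
    return CoverageTrack({"chr1": pos}, library_size=pos.size, label="uniform")
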