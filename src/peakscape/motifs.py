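"""IUPAC consensus motif scanning on both strands.

The default pattern is the HNF-1β consensus 5'-GGTTAATNATTAAC-3'. Matching
is exact against the degenerate alphabet: a pattern code matches exactly
its base set, so an N in the *subject* sequence is matched only by an N in
the pattern. Overlapping hits are all reported; minus-strand hits are
matches of the reverse-complement pattern reported with forward-strand
coordinates.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Mapping, Sequence

from pyfaidx import Fasta

from .genome_io import Peak

__all__ = ["MotifHit", "HNF1B_CONSENSUS", "scan_consensus", "peaks_with_motif",
           "reverse_complement", "iupac_regex"]

HNF1B_CONSENSUS = "GGTTAATNATTAAC"

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGTN",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


@dataclass(frozen=True)
class MotifHit:
    sequence: str
    start: int          # 0-based forward-strand offset
    strand: str         # + or -
    matched: str        # forward-strand text under the hit


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def iupac_regex(pattern: str) -> re.Pattern:
    parts = []
    for ch in pattern.upper():
        if ch not in IUPAC:
            raise ValueError(f"invalid IUPAC code {ch!r} in pattern")
        allowed = IUPAC[ch]
        parts.append(allowed if len(allowed) == 1 else f"[{allowed}]")
    # lookahead makes overlapping matches visible
    return re.compile(f"(?=({''.join(parts)}))")


def _validate_sequence(seq: str) -> str:
    seq = seq.upper()
    for i, ch in enumerate(seq):
        if ch not in "ACGTN":
            raise ValueError(f"invalid nucleotide {ch!r} at offset {i}")
    return seq


def scan_consensus(seq: str, pattern: str = HNF1B_CONSENSUS,
                   name: str = "seq") -> list[MotifHit]:
    """All hits of an IUPAC pattern in ``seq``, both strands.

    Minus-strand hits are located by scanning with the reverse-complement
    pattern; their ``start`` is the forward-strand offset of the matched
    window and ``matched`` is the forward-strand text.
    """
    seq = _validate_sequence(seq)
    hits: list[MotifHit] = []
    fwd = iupac_regex(pattern)
    for m in fwd.finditer(seq):
        hits.append(MotifHit(name, m.start(), "+", m.group(1)))
    # minus strand: scan with the reverse-complement pattern. A palindromic
    # pattern therefore reports every site on both strands.
    rc = iupac_regex(reverse_complement(pattern))
    for m in rc.finditer(seq):
        hits.append(MotifHit(name, m.start(), "-", m.group(1)))
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits


def peaks_with_motif(peaks: Sequence[Peak], genome: str | Mapping[str, str],
                     pattern: str = HNF1B_CONSENSUS
                     ) -> tuple[dict[str, int], float]:
    """Per-peak hit counts and the fraction of peaks with >=1 hit.

    ``genome`` is a FASTA path (indexed with pyfaidx) or a chrom->sequence
    mapping. Peaks extending past a chromosome end raise.
    """
    if isinstance(genome, (str, bytes)) or hasattr(genome, "__fspath__"):
        fa = Fasta(str(genome))
        get = lambda chrom: str(fa[chrom][:])
        length = lambda chrom: len(fa[chrom])
    else:
        get = lambda chrom: genome[chrom]
        length = lambda chrom: len(genome[chrom])
    seqs: dict[str, str] = {}
    counts: dict[str, int] = {}
    for p in peaks:
        if p.end > length(p.chrom):
            raise ValueError(f"peak {p.name} extends past end of {p.chrom}")
        if p.chrom not in seqs:
            seqs[p.chrom] = get(p.chrom).upper()
        window = seqs[p.chrom][p.start:p.end]
        counts[p.name] = len(scan_consensus(window, pattern, name=p.name))
    frac = sum(1 for c in counts.values() if c > 0) / len(counts) if counts else 0.0
    return counts, frac
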