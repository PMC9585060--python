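# Methods

This note documents the models, conventions and numerical choices behind
`peakscape`, and what the synthetic-data tests do and do not demonstrate
about real data.

## Coordinate contract

All internal coordinates are 0-based half-open (BED convention); GTF input
is converted on read and back on write. The TSS of a minus-strand gene is
`end − 1` and "upstream"/"downstream" are always strand-aware; the signed
TSS distance reported for a peak is negative upstream on either strand.
Keeping a single convention in one module (`genome_io`) is what prevents
off-by-one drift between the annotation, quantification and simulation
stages.

## Region classification

A peak is classified by one point — its summit when the peak caller
provided one, else its interval midpoint. A point rule makes the
promoter/intragenic/distal partition well-defined even for wide peaks that
straddle a boundary; the summit is preferred because it is the best single
estimate of the binding position. Definitions:

- promoter: signed TSS distance in [−3000, 0) for any gene;
- intragenic: inside any gene body, or 1–300 bp past any TES;
- distal intergenic: neither.

When windows of different genes overlap, promoter takes precedence, then
intragenic. Gene assignment is nearest-TSS with two refinements: ties are
broken by lexicographically smallest gene id (deterministic and
order-independent), and when the nearest TSS belongs to a pseudogene whose
locus sits inside a non-pseudogene gene body, the peak is reassigned to
the host gene — small processed pseudogenes embedded in a real gene would
otherwise capture its peaks. No distance cap is applied by default
(`max_tss_distance` restricts it when the user wants a conservative
"nearby" notion); the subregion column (first-exon proxy for the 5′ UTR,
exon, intron, downstream) is descriptive only, since the gene-model TSV
carries no CDS.

## Colocalization model

The hypergeometric test needs a finite universe, which interval data do
not naturally provide. The package makes it explicit: the genome is tiled
into non-overlapping bins of width equal to the median set-A peak width
(configurable), and a bin counts as hit by a set when any peak of the set
overlaps it. With a = both, b = A-only, c = B-only, d = neither and
N = a+b+c+d,

    p = P(X ≥ a),  X ~ Hypergeometric(N, K = a+b, n = a+c)

is accumulated in log space (log-binomials via `gammaln`, combined with
`logsumexp`) so it stays finite for N ~ 10⁶, and the odds ratio is
(a·d)/(b·c), with +0.5 added to all four cells when any cell is zero
(Haldane–Anscombe) so it is always finite. The peak-wise overlap fraction
reported next to the test is deliberately *not* bin-based: it counts each
A peak once if it shares ≥ 1 bp with any B peak, which is the quantity
usually quoted as "x% of peaks colocalized".

Because the bin construction is a modelling choice, a permutation null is
provided as an independent oracle: B peaks are re-placed uniformly on
their own chromosome with widths preserved and the empirical p-value is
(1 + #{perm ≥ obs}) / (n_perm + 1). One geometry caveat is worth
recording: the synthetic θ-generator places companion peaks strictly
inside bins, which is the right null for the *bin-level* hypergeometric
test but differs at sub-bin scale from the uniform-placement permutation
null; null calibration of the permutation p therefore uses uniformly
placed companion peaks (independence by construction), while calibration
of the hypergeometric p uses the bin-level θ = 1 generator. Both are
uniform in their matched null, which is what the test suite checks.

## Signal quantification

RPKM at a peak counts read anchors in the peak span padded by `flank`
(default 1000 bp per side, so a "within 1 kb" window that still scales
with peak width) and normalizes to window kilobases and library millions.
An alternative summit-anchored window (± flank around the summit,
discarding the span) is exposed as `anchor="summit"`. A read is in a
window iff its single anchor position is — the anchor is the read-interval
midpoint, fixed at parse time — so counting is deterministic with no
fractional-overlap rules. Windows are clipped at position 0 and at the
chromosome end when lengths are supplied, with the width recomputed, so
edge peaks are not penalized for missing flank.

Profile matrices normalize each bin by its own width, making rows
comparable between the fixed-width peak-centered layout and the metagene
layout (body linearly rescaled to `body_bins`, flanks at fixed
resolution); minus-strand rows are reversed so columns always run
TSS→TES. Genes shorter than `body_bins` bp are skipped and counted.

## Statistical tests

`hypergeom_sf` is described above. `mann_whitney` computes U with midranks
for ties; when min(n₁, n₂) ≤ 8 and the pooled data are tie-free it uses
the exact null distribution of U (the classic counting recurrence —
equivalently, partitions of u into at most n₁ parts ≤ n₂), otherwise a
normal approximation with tie-corrected variance and a continuity
correction (on by default, recorded in the result's `method` field). The
two-sided p doubles the smaller tail and is capped at 1. The cutoff of 8
keeps exactness where enumeration is cheap; the suite verifies the two
branches agree within 0.02 at n = 8/8 and that the test's type-I error at
α = 0.05 sits in [0.04, 0.06] over 10⁴ null replicates. Significance-star
encoding in reports follows the usual legend cutpoints literally
(`****` ≤ 10⁻⁴, `***` ≤ 10⁻³, `**` ≤ 0.01, `*` < 0.05, `ns` ≥ 0.05 — note
p = 0.05 is "ns" and p = 0.01 is "**"), and no multiple-testing
correction is applied across a comparison panel by default.

## Motif scanning

Exact degenerate matching of an IUPAC consensus (default the HNF-1β site
GGTTAATNATTAAC) with no mismatches and no PWM: a pattern code matches
exactly its base set, so an N in the subject is matched only by a
pattern N. Minus-strand hits are matches of the reverse-complement
pattern, reported in forward coordinates; overlapping hits are all
reported, and a palindromic pattern legitimately reports each site on
both strands. The scanner is checked against a naive O(n·m)
sliding-window oracle.

## Synthetic data: what it emulates, and what it does not

The generators emulate the *shapes* of a TF ChIP-seq study and its
companion assays with planted, recoverable parameters. Defaults are the
study conditions at desk scale: 2 × 1 Mb chromosomes, 200 genes
(1–8 kb, ≥ 3.5 kb apart so promoter windows are unambiguous and distal
space exists), 500 peaks with a 26/37/37 promoter/intragenic/distal
summit mix and ~300 bp lognormal widths, a companion peak set with
bin-level odds ratio θ = 16, Poisson coverage at 0.01 reads/bp, and a DE
table with 50 + 50 planted direct targets at |log2fc| ≥ 1, a 2% spurious
significance rate and 5% of genes under the 25-count filter. A single
integer seed drives one named RNG substream per generator, so outputs are
byte-reproducible and adding a generator never perturbs the others.

Two generator choices matter for interpretation. First, coverage
enrichment is planted over the peak span padded by the same 1 kb flank the
quantifier reads, so the planted fold is exactly the quantity the RPKM
contrast estimates; planting only within the span would dilute the
contrast by the flank background and conflate generator geometry with
estimator error. Second, the θ-generator gives each A-hit bin a companion
peak with probability p₁ and other bins p₀ = 0.05, with odds(p₁) =
θ·odds(p₀), so the expected bin-hit odds ratio equals θ by construction.

Passing planted-recovery tests shows the estimators are consistent under
the generating model; it does not show robustness to what real data add:
GC and mappability bias, fragment-length effects, duplicate reads,
copy-number variation, overlapping genes and alternative TSSs, or DE
effect sizes correlated with expression level. Those are out of scope by
design — the pipeline consumes peaks and DE tables called by specialist
upstream tools rather than re-deriving them.

## Numerical and degenerate-input choices

- Hypergeometric tails: log-space accumulation; `a = 0` returns exactly 1.
- Odds ratios: +0.5 on all cells only when a cell is zero.
- Mann–Whitney with zero variance (all pooled values identical): p = 1.
- Empty gene set: every peak is distal intergenic with no assigned gene;
  empty companion set B: overlap (0, 0.0); empty set A: an error (the
  fraction would be undefined).
- RPKM windows truncated at chromosome edges recompute their width; a
  zero-read window is exactly 0 RPKM.
- Metagene bin edges are computed in float and rounded once; zero-width
  bins (only possible for degenerate flank settings) are guarded.
- DE thresholds: inclusive on |log2fc| ≥ 0.5, strict on FDR < 0.05,
  filter at max(mean counts) < 25 — boundary rows at log2fc = ±0.5 are
  called, rows at FDR = 0.05 are not.

## Problem sizes in the test and acceptance runs

Oracle-equivalence suites enumerate exhaustively (N ≤ 12 for the
hypergeometric; n₁, n₂ ≤ 8 for rank assignments). Calibration uses 200
generator seeds for each colocalization null and 10⁴ replicates for the
rank-test error rate; recovery uses 5000 peaks for the region mix, 20,000
bins (median over 10–20 seeds) for θ, and 500 + 500 peaks for the RPKM
contrast. These sizes make the whole suite run in well under a minute on
one core while keeping Monte-Carlo error comfortably inside the asserted
tolerances.
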