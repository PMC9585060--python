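# peakscape

Peak-centric integration of transcription-factor ChIP-seq with chromatin
state and differential expression.

When a TF's genome-wide binding sites have been called (e.g. HNF-1β in the
embryonic mouse kidney), the recurring analysis questions are always the
same: *where* does the factor bind relative to genes, does binding
*colocalize* with open chromatin and activating histone marks, how strong
is the *signal* of each companion assay at the binding sites, and which
differentially expressed genes are *direct* targets. `peakscape`
implements this pipeline as a small, fully tested library with a thin CLI,
plus a synthetic-data generator so every stage can be exercised with
planted ground truth and no external downloads.

## What it computes

**Region annotation.** Each peak is classified by a single point (summit,
falling back to the interval midpoint) into:

- *promoter* — within 3 kb upstream of a TSS (strand-aware,
  −3000 ≤ d < 0),
- *intragenic* — inside a gene body or ≤ 300 bp downstream of a TES,
- *distal intergenic* — everything else,

with promoter > intragenic > distal precedence, and assigned to the gene
with the nearest TSS (pseudogenes are skipped in favour of an enclosing
non-pseudogene gene).

**Colocalization.** The genome is tiled into bins of width equal to the
median peak width of set A; a bin is "hit" when any peak overlaps it. From
the 2×2 bin-hit table (a, b, c, d) with N = a+b+c+d bins, the test reports
the upper-tail hypergeometric probability

  p = P(X ≥ a),  X ~ Hypergeom(N, K = a+b, n = a+c)

computed in log space, and the odds ratio ad/bc (Haldane–Anscombe +0.5 on
zero cells). A width-preserving permutation null is available as an
independent check, and the peak-wise overlap fraction (share of A peaks
touching ≥ 1 B peak) is reported alongside.

**Signal quantification.** Per-peak RPKM of a read-anchor track over the
peak span padded by 1 kb per side: `rpkm = count / window_kb /
(library_size / 1e6)`; plus peak-centered profile matrices and TSS→TES
metagene matrices (gene body rescaled, fixed-resolution flanks).

**Direct-target calling.** DE rows (log2fc is mutant vs control) are
filtered at 25 mean counts, then called *activated* (log2fc ≤ −0.5,
FDR < 0.05 — the TF was driving expression), *repressed* (log2fc ≥ +0.5,
FDR < 0.05) or unchanged. A gene is a *direct* target when it is also the
assigned gene of ≥ 1 peak.

**Motif scanning.** Exact IUPAC-consensus matching (default
5′-GGTTAATNATTAAC-3′, the HNF-1β site) on both strands, overlapping hits
included.

## Worked example

```python
import peakscape as pk

cfg = pk.SyntheticConfig(seed=1, n_peaks=1000)   # planted 26/37/37 mix, θ=16
sim = pk.simulate_all(cfg)

print(pk.summarize_regions(sim["annotations"]))
res = pk.colocalization_test(sim["peaks"], sim["coloc_peaks"], cfg.chrom_lengths)
print(f"overlap fraction: {res.fraction_A:.2f}  p = {res.p_value:.3g}  OR = {res.odds_ratio:.1f}")
calls, summary = pk.call_direct_targets(sim["de"], sim["annotations"])
print(summary)
```

prints

```
        region_class  count  percent
0           promoter    281     28.1
1         intragenic    352     35.2
2  distal_intergenic    367     36.7
overlap fraction: 0.61  p = 7.16e-321  OR = 17.1
TargetSummary(n_activated=50, n_repressed=51, n_direct_activated=50,
n_direct_repressed=51, pct_direct_activated=100.0, pct_direct_repressed=100.0)
```

The classifier recovers the planted 26/37/37 region mix to sampling noise;
the estimated odds ratio (17.1) recovers the planted θ = 16; and all 100
planted direct targets are recalled (one spuriously significant null gene
also lands in the repressed set at the default 2% FDR-noise setting).

The same stages are available from the shell:

```sh
peakscape simulate --seed 1 --out data/
peakscape annotate --peaks data/peaks.narrowPeak --genes data/genes.tsv
peakscape coloc --peaks-a data/peaks.narrowPeak --peaks-b data/coloc_peaks.bed \
    --genome data/genome.sizes
peakscape targets --de data/de.tsv --peaks data/peaks.narrowPeak --genes data/genes.tsv
peakscape run --config pipeline.yaml --out report.json
```

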