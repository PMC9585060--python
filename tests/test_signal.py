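"""RPKM quantification and profile matrices, with a per-read loop oracle."""

import numpy as np
import pytest

from peakscape.genome_io import CoverageTrack
from peakscape.signal import (metagene_profile, peak_centered_profile,
                              rpkm_at_peaks, stratified_enrichment)

from conftest import make_gene, make_peak


def track_of(positions, library_size=None, label="t"):
    pos = np.asarray(sorted(positions), dtype=np.int64)
    return CoverageTrack({"chr1": pos}, library_size or pos.size, label)


class TestRpkmAtPeaks:
    def test_formula(self):
        # 500 bp peak + 1 kb flanks = 2.5 kb window; 10 reads; 1e6 library
        tr = track_of(range(100, 2500, 250), library_size=1_000_000)
        (sig,) = rpkm_at_peaks([make_peak("chr1", 1000, 1500, "p")], tr)
        assert sig.rpkm == pytest.approx(10 / 2.5 / 1.0)

    def test_zero_reads_zero_rpkm(self):
        tr = track_of([900_000], library_size=100)
        (sig,) = rpkm_at_peaks([make_peak("chr1", 1000, 1500)], tr)
        assert sig.rpkm == 0.0

    def test_scale_invariance(self):
        reads = list(range(0, 3000, 100))
        tr1 = track_of(reads, library_size=10_000)
        tr2 = track_of(reads + reads, library_size=20_000)
        peaks = [make_peak("chr1", 1000, 1500)]
        assert rpkm_at_peaks(peaks, tr1)[0].rpkm == pytest.approx(
            rpkm_at_peaks(peaks, tr2)[0].rpkm)

    def test_window_truncated_at_chromosome_start(self):
        tr = track_of(range(0, 600, 100), library_size=1_000_000)
        (sig,) = rpkm_at_peaks([make_peak("chr1", 100, 500)], tr)
        # window [0, 1500) of width 1500, holds all 6 reads
        assert sig.rpkm == pytest.approx(6 / 1.5 / 1.0)

    def test_summit_anchor_mode(self):
        tr = track_of(range(1400, 1600, 10))  # 20 reads near the summit
        pk = make_peak("chr1", 1000, 2000, summit=1500)
        (span,) = rpkm_at_peaks([pk], tr, flank=500, anchor="span")
        (summit,) = rpkm_at_peaks([pk], tr, flank=500, anchor="summit")
        # same reads, but 2 kb vs 1 kb windows: summit-anchored RPKM doubles
        assert summit.rpkm == pytest.approx(2 * span.rpkm)

    def test_against_per_read_loop_oracle(self):
        rng = np.random.default_rng(5)
        reads = sorted(rng.integers(0, 50_000, size=100).tolist())
        tr = track_of(reads, library_size=100)
        peaks = [make_peak("chr1", int(s), int(s) + 400, name=f"p{i}")
                 for i, s in enumerate(rng.integers(0, 49_000, size=20))]
        for sig, pk in zip(rpkm_at_peaks(peaks, tr), peaks):
            lo, hi = max(0, pk.start - 1000), pk.end + 1000
            count = sum(1 for r in reads if lo <= r < hi)
            assert sig.rpkm == pytest.approx(
                count / ((hi - lo) / 1000) / (100 / 1e6))


class TestPeakCenteredProfile:
    def test_row_sum_conserves_window_reads(self):
        rng = np.random.default_rng(6)
        reads = rng.integers(0, 100_000, size=500)
        tr = track_of(reads.tolist())
        peaks = [make_peak("chr1", 5_000, 5_400, summit=5_200),
                 make_peak("chr1", 50_000, 50_600, summit=50_300)]
        prof = peak_centered_profile(peaks, tr, half_window=2000, bin_width=50)
        for row, pk in zip(prof.values, peaks):
            window_reads = np.sum((reads >= pk.summit - 2000)
                                  & (reads < pk.summit + 2000))
            counts = row * (50 / 1000) * (tr.library_size / 1e6)
            assert counts.sum() == pytest.approx(window_reads)

    def test_flat_under_uniform_coverage(self, uniform_track):
        rng = np.random.default_rng(7)
        peaks = [make_peak("chr1", int(s), int(s) + 200, summit=int(s) + 100)
                 for s in rng.integers(3000, 900_000, size=1000)]
        mean = peak_centered_profile(peaks, uniform_track).mean_profile()
        assert mean.max() / mean.min() < 1.2

    def test_summit_bin_maximal_for_planted_signal(self):
        summits = list(range(10_000, 60_000, 1000))
        reads = [s for s in summits for _ in range(5)]
        tr = track_of(reads)
        peaks = [make_peak("chr1", s - 200, s + 200, summit=s) for s in summits]
        mean = peak_centered_profile(peaks, tr).mean_profile()
        center = len(mean) // 2
        assert mean[center] == mean.max() and mean[center] > 0

    def test_single_read_single_bin(self):
        tr = track_of([5000], library_size=1)
        prof = peak_centered_profile(
            [make_peak("chr1", 4900, 5100, summit=5000)], tr)
        assert (prof.values[0] > 0).sum() == 1

    def test_half_window_must_divide(self):
        with pytest.raises(ValueError):
            peak_centered_profile([make_peak("chr1", 0, 10)], track_of([5]),
                                  half_window=1000, bin_width=33)


class TestMetageneProfile:
    def test_flat_under_uniform_coverage(self, uniform_track):
        genes = [make_gene(f"g{i}", "chr1", s, s + 20_000, "+")
                 for i, s in enumerate(range(10_000, 800_000, 40_000))]
        prof = metagene_profile(genes, uniform_track)
        mean = prof.mean_profile()
        assert mean.std() / mean.mean() < 0.2

    def test_upstream_signal_lands_in_upstream_flank(self):
        gene = make_gene("g", "chr1", 50_000, 60_000, "+")
        reads = list(range(49_500, 50_000, 10))  # only [TSS-500, TSS)
        prof = metagene_profile([gene], track_of(reads), flank=3000,
                                flank_bins=100, body_bins=100)
        row = prof.values[0]
        up = row[:100]
        assert row[100:].sum() == 0
        # 30 bp per flank bin: 500 bp of signal fills the last ~17 bins
        assert (up[:82].sum() == 0) and up[83:].sum() > 0

    def test_minus_strand_reversed_to_tss_first(self):
        gene = make_gene("g", "chr1", 50_000, 60_000, "-")
        # TSS of the minus-strand gene is at 59_999; plant reads there
        reads = list(range(59_900, 60_000, 2))
        prof = metagene_profile([gene], track_of(reads))
        row = prof.values[0]
        body = row[100:200]
        assert body[:5].sum() > 0 and body[50:].sum() == 0

    def test_short_genes_skipped(self, uniform_track):
        genes = [make_gene("tiny", "chr1", 100, 150, "+"),
                 make_gene("ok", "chr1", 10_000, 30_000, "+")]
        prof = metagene_profile(genes, uniform_track, body_bins=100)
        assert prof.n_skipped == 1 and prof.row_names == ["ok"]

    def test_against_per_read_loop_oracle(self):
        rng = np.random.default_rng(8)
        reads = sorted(rng.integers(0, 30_000, size=100).tolist())
        gene = make_gene("g", "chr1", 8_000, 20_000, "+")
        prof = metagene_profile([gene], track_of(reads), flank=3000,
                                flank_bins=10, body_bins=10)
        edges = np.concatenate([
            np.linspace(5_000, 8_000, 11)[:-1],
            np.linspace(8_000, 20_000, 11)[:-1],
            np.linspace(20_000, 23_000, 11)]).round().astype(int)
        counts = np.array([sum(1 for r in reads if lo <= r < hi)
                           for lo, hi in zip(edges[:-1], edges[1:])])
        widths = np.diff(edges)
        expected = counts / (widths / 1000) / (100 / 1e6)
        assert prof.values[0] == pytest.approx(expected)


class TestStratifiedEnrichment:
    def test_constant_values(self):
        from peakscape.signal import PeakSignal
        sigs = [PeakSignal(f"p{i}", 4.0, "t") for i in range(10)]
        out = stratified_enrichment(sigs, {f"p{i}": "all" for i in range(10)})
        assert out.loc[0, "median"] == 4.0 and out.loc[0, "iqr"] == 0.0

    def test_single_element_stratum(self):
        from peakscape.signal import PeakSignal
        out = stratified_enrichment([PeakSignal("p", 2.5, "t")], {"p": "solo"})
        assert out.loc[0, "median"] == 2.5 and out.loc[0, "n"] == 1

    def test_unlabeled_peak_errors(self):
        from peakscape.signal import PeakSignal
        with pytest.raises(ValueError):
            stratified_enrichment([PeakSignal("p", 1.0, "t")], {})
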