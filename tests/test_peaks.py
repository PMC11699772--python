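"""Peak calling, signal filters, TSS overlap and Venn partitions."""

from itertools import combinations

import numpy as np
import pytest

from xciseq.annotation import GeneModel
from xciseq.errors import ConfigurationError, DataError
from xciseq.peaks import (
    Peak,
    call_peaks,
    filter_peaks_by_signal,
    peaks_at_tss,
    tss_regions,
    venn_counts,
    xi_specific_gains,
)
from xciseq.tracks import CoverageTrack


def _track(values, bin_size=50):
    arr = np.asarray(values, dtype=float)
    return CoverageTrack(
        bin_size=bin_size,
        values={"chr1": arr},
        chrom_lengths={"chr1": bin_size * len(arr)},
        normalization="RPKM",
        total_units=1000,
    )


class TestCallPeaks:
    def test_flat_zero_track_has_no_peaks(self):
        assert call_peaks(_track(np.zeros(100))) == []

    def test_single_planted_block(self):
        values = np.ones(200)
        values[40:80] = 10.0  # 2-kb block at 10x background, 50-bp bins
        peaks = call_peaks(_track(values), threshold_quantile=0.75)
        assert len(peaks) == 1
        p = peaks[0]
        inter = max(0, min(p.end, 80 * 50) - max(p.start, 40 * 50))
        union = (p.end - p.start) + 2000 - inter
        assert inter / union >= 0.8

    def test_two_blocks_with_wide_gap(self):
        values = np.ones(200)
        values[40:60] = 10.0
        values[70:90] = 10.0  # gap of 10 bins > bridge
        peaks = call_peaks(_track(values), threshold_quantile=0.75)
        assert len(peaks) == 2

    def test_single_bin_gap_is_bridged(self):
        values = np.ones(100)
        values[40:50] = 10.0
        values[45] = 1.0  # one sub-threshold bin inside the block
        peaks = call_peaks(_track(values), threshold_quantile=0.75)
        assert len(peaks) == 1
        assert peaks[0].start == 2000 and peaks[0].end == 2500

    def test_signal_statistics(self):
        values = np.ones(100)
        values[10:13] = (4.0, 8.0, 6.0)
        peaks = call_peaks(_track(values), threshold_quantile=0.5)
        assert len(peaks) == 1
        assert peaks[0].total_signal == pytest.approx(18.0)
        assert peaks[0].max_signal == pytest.approx(8.0)
        assert peaks[0].total_signal >= peaks[0].max_signal > 0

    def test_peaks_disjoint_and_sorted(self):
        rng = np.random.default_rng(2)
        values = rng.exponential(1.0, 500)
        peaks = call_peaks(_track(values), threshold_quantile=0.8)
        for a, b in zip(peaks, peaks[1:]):
            assert a.end <= b.start


class TestFilterPeaksBySignal:
    def _peak(self, signal):
        return Peak("chr1", 0, 100, signal, signal)

    @pytest.mark.parametrize("signal,kept", [(9.0, False), (10.0, True), (11.0, True)])
    def test_h3k27me3_cutoff_10(self, signal, kept):
        assert bool(filter_peaks_by_signal([self._peak(signal)], 10)) is kept

    @pytest.mark.parametrize("signal,kept", [(4.0, False), (5.0, True)])
    def test_kdm6a_cutoff_5(self, signal, kept):
        assert bool(filter_peaks_by_signal([self._peak(signal)], 5)) is kept

    def test_empty_input(self):
        assert filter_peaks_by_signal([], 10) == []

    def test_idempotent_and_order_preserving(self):
        peaks = [self._peak(s) for s in (12, 3, 40, 10, 9)]
        once = filter_peaks_by_signal(peaks, 10)
        assert filter_peaks_by_signal(once, 10) == once
        assert [p.total_signal for p in once] == [12, 40, 10]

    def test_negative_threshold_raises(self):
        with pytest.raises(ConfigurationError):
            filter_peaks_by_signal([], -1)


def _gene(gene_id, start, end, strand="+", chrom="chr1"):
    return GeneModel(gene_id, chrom, strand, ((start, end),))


class TestTSSRegions:
    LENGTHS = {"chr1": 1_000_000}

    def test_plus_strand_window(self):
        (r,) = tss_regions([_gene("g", 100_000, 105_000)], self.LENGTHS)
        assert (r.start, r.end) == (95_000, 105_000)

    def test_clamped_at_chromosome_start(self):
        (r,) = tss_regions([_gene("g", 2_000, 3_000)], self.LENGTHS)
        assert (r.start, r.end) == (0, 7_000)

    def test_minus_strand_uses_rightmost_coordinate(self):
        (r,) = tss_regions([_gene("g", 100_000, 105_000, strand="-")], self.LENGTHS)
        tss = 105_000 - 1
        assert (r.start, r.end) == (tss - 5000, tss + 5000)

    def test_width_and_containment_invariants(self):
        genes = [_gene(f"g{i}", s, s + 4000) for i, s in enumerate((0, 3000, 996_000))]
        for r, g in zip(tss_regions(genes, self.LENGTHS), genes):
            assert r.end - r.start <= 10_000
            assert r.start <= g.tss < r.end

    def test_unknown_chromosome_raises(self):
        with pytest.raises(DataError):
            tss_regions([_gene("g", 0, 100, chrom="chrZ")], self.LENGTHS)


class TestPeaksAtTSS:
    def test_gene_with_two_transcript_windows_counted_once(self):
        regions = tss_regions(
            [_gene("g", 10_000, 12_000), _gene("g", 30_000, 32_000)],
            {"chr1": 1_000_000},
        )
        peaks = [Peak("chr1", 9_000, 9_100, 5, 5), Peak("chr1", 29_000, 29_100, 5, 5)]
        assert peaks_at_tss(peaks, regions) == {"g"}

    def test_no_overlap_empty(self):
        regions = tss_regions([_gene("g", 500_000, 501_000)], {"chr1": 1_000_000})
        assert peaks_at_tss([Peak("chr1", 0, 10, 1, 1)], regions) == set()

    def test_matches_all_pairs_oracle(self):
        rng = np.random.default_rng(7)
        genes = [
            _gene(f"g{i}", int(s), int(s) + 2000)
            for i, s in enumerate(rng.integers(0, 900_000, 200))
        ]
        regions = tss_regions(genes, {"chr1": 1_000_000})
        peaks = [
            Peak("chr1", int(s), int(s) + 500, 1, 1)
            for s in rng.integers(0, 990_000, 50)
        ]
        expected = {
            r.gene_id
            for r in regions
            for p in peaks
            if p.start < r.end and r.start < p.end
        }
        assert peaks_at_tss(peaks, regions) == expected


class TestVennCounts:
    def test_identical_sets(self):
        out = venn_counts({"A": {1, 2, 3}, "B": {1, 2, 3}})
        assert out[("A", "B")] == 3
        assert out[("A",)] == out[("B",)] == 0

    def test_disjoint_sets(self):
        out = venn_counts({"A": {1}, "B": {2}})
        assert out[("A", "B")] == 0

    def test_three_set_partition_matches_set_arithmetic(self):
        rng = np.random.default_rng(9)
        sets = {n: set(rng.integers(0, 60, 40).tolist()) for n in "ABC"}
        out = venn_counts(sets)
        assert sum(out.values()) == len(sets["A"] | sets["B"] | sets["C"])
        for r in range(1, 4):
            for combo in combinations("ABC", r):
                inside = set.intersection(*(sets[n] for n in combo))
                for n in sets:
                    if n not in combo:
                        inside -= sets[n]
                assert out[tuple(sorted(combo))] == len(inside)

    def test_more_than_three_sets_rejected(self):
        with pytest.raises(ConfigurationError):
            venn_counts({n: set() for n in "ABCD"})


class TestXiSpecificGains:
    def test_identical_test_and_background(self):
        peaks = [Peak("chrX", 100, 500, 5, 5)]
        report = xi_specific_gains(peaks, peaks, "chrX", 10_000)
        assert report.gained == [] and report.covered_fraction == 0

    def test_covered_fraction_is_width_sum(self):
        test = [Peak("chrX", 0, 1000, 5, 5), Peak("chrX", 5000, 5500, 5, 5)]
        report = xi_specific_gains(test, [], "chrX", 10_000)
        assert report.covered_fraction == (1000 + 500) / 10_000

    def test_context_counts(self):
        genes = [GeneModel("g", "chrX", "+", ((50_000, 60_000),))]
        test = [
            Peak("chrX", 46_000, 46_500, 5, 5),   # midpoint in TSS window
            Peak("chrX", 57_000, 57_500, 5, 5),   # gene body
            Peak("chrX", 90_000, 90_500, 5, 5),   # intergenic
        ]
        report = xi_specific_gains(test, [], "chrX", 100_000, genes=genes)
        assert report.context_counts == {"tss": 1, "gene_body": 1, "intergenic": 1}

    def test_chromosome_mismatch_raises(self):
        with pytest.raises(DataError):
            xi_specific_gains([Peak("chr1", 0, 10, 1, 1)], [], "chrX", 100)
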