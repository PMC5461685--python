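import numpy as np
import pytest

from sekit.algebra import SignalTrack
from sekit.calling import (
    apply_threshold,
    call_superenhancers,
    find_threshold,
    rank_stitched,
    score_stitched,
    stitch_peaks,
)
from sekit.errors import DegenerateInputError, UsageError
from sekit.intervals import GenomicInterval, Peak, Read, StitchedEnhancer
from sekit.simulate import make_hockey_curve


def peak(chrom, start, end, pileup=1.0):
    return Peak(GenomicInterval(chrom, start, end), pileup)


class TestStitch:
    def test_gap_rule(self):
        peaks = [peak("chr1", 0, 1000), peak("chr1", 5000, 6000), peak("chr1", 20000, 21000)]
        regions = stitch_peaks(peaks, distance=12_500)
        assert [(r.interval.start, r.interval.end, r.n_subpeaks) for r in regions] == [
            (0, 6000, 2),
            (20000, 21000, 1),
        ]

    def test_exact_threshold_gap_does_not_stitch(self):
        peaks = [peak("chr1", 0, 1000), peak("chr1", 13_500, 14_000)]
        assert len(stitch_peaks(peaks, distance=12_500)) == 2

    def test_distance_zero_is_identity(self):
        peaks = [peak("chr1", i * 100, i * 100 + 50) for i in range(5)]
        assert len(stitch_peaks(peaks, distance=0)) == 5

    def test_never_crosses_chromosomes(self):
        peaks = [peak("chr1", 0, 1000), peak("chr2", 1500, 2000)]
        assert len(stitch_peaks(peaks, distance=12_500)) == 2

    def test_unsorted_input_sorted_internally(self):
        peaks = [peak("chr1", 5000, 6000), peak("chr1", 0, 1000)]
        regions = stitch_peaks(peaks, distance=12_500)
        assert len(regions) == 1
        assert regions[0].interval == GenomicInterval("chr1", 0, 6000)

    def test_region_count_monotone_in_distance(self):
        rng = np.random.default_rng(2)
        starts = np.cumsum(rng.integers(100, 20_000, 40))
        peaks = [peak("chr1", int(s), int(s) + 50) for s in starts]
        counts = [len(stitch_peaks(peaks, distance=d)) for d in (0, 500, 5000, 15000, 50000)]
        assert counts[0] == len(peaks)
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_stitched_regions_disjoint_with_large_gaps(self):
        rng = np.random.default_rng(4)
        starts = np.cumsum(rng.integers(100, 30_000, 60))
        peaks = [peak("chr1", int(s), int(s) + int(rng.integers(50, 2000))) for s in starts]
        regions = stitch_peaks(peaks, distance=12_500)
        for a, b in zip(regions, regions[1:]):
            assert b.interval.start - a.interval.end >= 12_500


class TestScore:
    def test_fully_contained_reads(self):
        region = StitchedEnhancer(GenomicInterval("chr1", 0, 1000))
        reads = [Read(GenomicInterval("chr1", i * 200, i * 200 + 100)) for i in range(3)]
        assert score_stitched(region, reads=reads) == 300

    def test_partial_overlap_counts_only_inside_bases(self):
        region = StitchedEnhancer(GenomicInterval("chr1", 0, 1000))
        assert score_stitched(region, reads=[Read(GenomicInterval("chr1", 950, 1050))]) == 50

    def test_no_overlap_zero(self):
        region = StitchedEnhancer(GenomicInterval("chr1", 0, 1000))
        assert score_stitched(region, reads=[Read(GenomicInterval("chr2", 0, 100))]) == 0

    def test_track_score_is_area(self):
        region = StitchedEnhancer(GenomicInterval("chr1", 100, 200))
        track = SignalTrack([("chr1", 50, 150, 2.0), ("chr1", 150, 300, 1.0)])
        assert score_stitched(region, track=track) == 2.0 * 50 + 1.0 * 50

    def test_requires_exactly_one_source(self):
        region = StitchedEnhancer(GenomicInterval("chr1", 0, 10))
        with pytest.raises(UsageError):
            score_stitched(region)

    def test_matches_dense_coverage_oracle(self):
        rng = np.random.default_rng(8)
        for _ in range(30):
            genome = 100_000
            reads = []
            for _ in range(int(rng.integers(1, 200))):
                s = int(rng.integers(0, genome - 150))
                reads.append(Read(GenomicInterval("chr1", s, s + int(rng.integers(30, 150)))))
            s = int(rng.integers(0, genome - 5000))
            region = StitchedEnhancer(GenomicInterval("chr1", s, s + int(rng.integers(500, 5000))))
            cov = np.zeros(genome)
            for r in reads:
                cov[r.interval.start : r.interval.end] += 1
            expected = cov[region.interval.start : region.interval.end].sum()
            assert score_stitched(region, reads=reads) == expected


class TestRank:
    def test_descending_counts(self):
        regions = [StitchedEnhancer(GenomicInterval("chr1", i * 1000, i * 1000 + 100)) for i in range(3)]
        for r, c in zip(regions, [10, 50, 30]):
            r.count = c
        ranked = rank_stitched(regions)
        assert [r.count for r in ranked] == [50, 30, 10]
        by_pos = sorted(ranked, key=lambda r: r.interval.start)
        assert [r.rank for r in by_pos] == [3, 1, 2]

    def test_ties_follow_genomic_order(self):
        regions = [
            StitchedEnhancer(GenomicInterval("chr2", 0, 100), count=5),
            StitchedEnhancer(GenomicInterval("chr1", 500, 600), count=5),
            StitchedEnhancer(GenomicInterval("chr1", 0, 100), count=5),
        ]
        ranked = rank_stitched(regions)
        assert [(r.chrom, r.interval.start) for r in ranked] == [
            ("chr1", 0),
            ("chr1", 500),
            ("chr2", 0),
        ]
        assert [r.rank for r in ranked] == [1, 2, 3]

    def test_single_region_rank_one(self):
        ranked = rank_stitched([StitchedEnhancer(GenomicInterval("chr1", 0, 10), count=1)])
        assert ranked[0].rank == 1


class TestThreshold:
    def test_brute_force_slope_scan_agreement(self):
        """find_threshold equals an independent argmin-|slope-1| scan."""
        rng = np.random.default_rng(12)
        for _ in range(20):
            counts = np.sort(rng.gamma(2.0, 100.0, 150))[::-1]
            asc = counts[::-1]
            y = (asc - asc.min()) / (asc.max() - asc.min())
            x = np.arange(len(asc)) / (len(asc) - 1)
            dev = np.abs(np.diff(y) / np.diff(x) - 1)
            best = max(i for i in range(dev.size) if dev[i] == dev.min())
            assert find_threshold(counts) == len(counts) - best - 1

    def test_planted_inflection_recovered(self):
        counts = make_hockey_curve(200, 30)
        assert find_threshold(counts) == 30

    def test_linear_curve_tie_breaks_to_fewest_ses(self):
        # 33 points: scaled values are exact multiples of 1/32, so every
        # slope is exactly 1 and the tie rule decides
        counts = np.arange(33, 0, -1, dtype=float)
        assert find_threshold(counts) == 1

    def test_tiny_input_warns_and_flags_all_te(self):
        with pytest.warns(UserWarning):
            assert find_threshold(np.array([5.0, 1.0])) == 0

    def test_constant_counts_degenerate(self):
        with pytest.raises(DegenerateInputError):
            find_threshold(np.full(10, 3.0))

    def test_se_flag_downward_closed(self):
        regions = [
            StitchedEnhancer(GenomicInterval("chr1", i * 1000, i * 1000 + 10), count=100 - i)
            for i in range(10)
        ]
        ranked = rank_stitched(regions)
        apply_threshold(ranked, 4)
        flags = [r.is_se for r in sorted(ranked, key=lambda r: r.rank)]
        assert flags == [True] * 4 + [False] * 6


class TestCallPipeline:
    def test_empty_peaks(self):
        regions, curve = call_superenhancers([], reads=[])
        assert regions == [] and curve is None

    def test_deterministic(self, landscape):
        r1, _ = call_superenhancers(landscape["peaks"], reads=landscape["reads"])
        r2, _ = call_superenhancers(landscape["peaks"], reads=landscape["reads"])
        assert [(x.rank, x.count, x.is_se) for x in r1] == [
            (x.rank, x.count, x.is_se) for x in r2
        ]

    def test_planted_clusters_recovered(self, landscape):
        regions, _ = call_superenhancers(landscape["peaks"], reads=landscape["reads"])
        se = {(r.chrom, r.interval.start, r.interval.end) for r in regions if r.is_se}
        truth = landscape["truth"]
        hits = sum((t.chrom, t.start, t.end) in se for t in truth.itertuples())
        assert hits >= 19

    def test_track_wins_over_reads_with_warning(self, landscape):
        track = SignalTrack.from_reads(landscape["reads"])
        with pytest.warns(UserWarning):
            r1, _ = call_superenhancers(
                landscape["peaks"], reads=landscape["reads"], track=track
            )
        r2, _ = call_superenhancers(landscape["peaks"], track=track)
        assert [x.count for x in r1] == [x.count for x in r2]

    def test_ranks_are_permutation_counts_nonincreasing(self, called):
        ranked = called["regions"]
        assert sorted(r.rank for r in ranked) == list(range(1, len(ranked) + 1))
        counts = [r.count for r in sorted(ranked, key=lambda r: r.rank)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))
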