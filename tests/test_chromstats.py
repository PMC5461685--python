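import numpy as np
import pytest
from scipy import stats as sps

from sekit import chromstats as cs
from sekit.errors import SekitError, UsageError
from sekit.intervals import GenomicInterval, StitchedEnhancer
from sekit.pipeline import subpeak_table


def se_at(chrom, start, end, rank=0):
    return StitchedEnhancer(GenomicInterval(chrom, start, end), rank=rank, is_se=True)


class TestCloseness:
    def test_three_ses(self):
        ses = [se_at("chr1", 0, 100, 1), se_at("chr1", 500, 600, 2), se_at("chr1", 2000, 2100, 3)]
        values = [r.closeness for r in cs.closeness(ses)]
        assert values == [400, 400, 1400]

    def test_single_se_is_na(self):
        assert cs.closeness([se_at("chr1", 0, 100, 1)])[0].closeness is None

    def test_two_ses_share_one_gap(self):
        ses = [se_at("chr1", 0, 100, 1), se_at("chr1", 700, 800, 2)]
        assert [r.closeness for r in cs.closeness(ses)] == [600, 600]

    def test_overlapping_ses_rejected(self):
        with pytest.raises(SekitError):
            cs.closeness([se_at("chr1", 0, 200, 1), se_at("chr1", 100, 300, 2)])

    def test_agrees_with_brute_force_min_gap(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            pos, ses = 0, []
            for i in range(int(rng.integers(2, 50))):
                pos += int(rng.integers(200, 50_000))
                width = int(rng.integers(100, 5000))
                ses.append(se_at("chr1", pos, pos + width, i + 1))
                pos += width
            got = [r.closeness for r in cs.closeness(ses)]
            for i, se in enumerate(ses):
                gaps = []
                for j, other in enumerate(ses):
                    if j == i:
                        continue
                    if other.interval.start >= se.interval.end:
                        gaps.append(other.interval.start - se.interval.end)
                    else:
                        gaps.append(se.interval.start - other.interval.end)
                assert got[i] == min(gaps)


class TestEnrichment:
    def test_observed_equals_expectation_unmarked(self):
        res = cs.chromosome_enrichment("chr1", N=1000, K=100, n=100, k=10)
        assert res.mark == cs.MARK_NONE
        assert res.p_enrich > 0.05 and res.p_deplete > 0.05

    def test_certain_event_not_enriched(self):
        res = cs.chromosome_enrichment("chr1", N=50, K=100, n=50, k=100)
        assert res.p_enrich == 1.0
        assert res.mark == cs.MARK_NONE

    def test_decision_matches_hypergeometric_oracle(self):
        res = cs.chromosome_enrichment("chr1", N=1000, K=100, n=100, k=30)
        hg = sps.hypergeom(1000, 100, 100)  # M, n-genes-in-chrom, K draws
        p_hg = hg.sf(30 - 1)
        assert (res.p_enrich < 0.05) == (p_hg < 0.05)
        assert res.mark in (cs.MARK_ENRICH_05, cs.MARK_ENRICH_01)

    def test_tails_overlap_at_k(self):
        rng = np.random.default_rng(5)
        for _ in range(30):
            K = int(rng.integers(10, 300))
            k = int(rng.integers(0, K + 1))
            res = cs.chromosome_enrichment("c", N=5000, K=K, n=int(rng.integers(1, 900)), k=k)
            assert res.p_enrich + res.p_deplete >= 1.0
            assert 0.0 <= res.p_enrich <= 1.0 and 0.0 <= res.p_deplete <= 1.0

    def test_binomial_close_to_hypergeometric_on_large_genomes(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            N = int(rng.integers(2000, 30_000))
            n = int(rng.integers(1, int(0.2 * N)))
            K = int(rng.integers(10, max(11, N // 20)))
            k = int(rng.integers(0, K + 1))
            res = cs.chromosome_enrichment("c", N=N, K=K, n=n, k=k)
            hg = sps.hypergeom(N, n, K)
            assert abs(res.p_enrich - hg.sf(k - 1)) <= 0.01
            assert abs(res.p_deplete - hg.cdf(k)) <= 0.01

    def test_invalid_inputs(self):
        with pytest.raises(UsageError):
            cs.chromosome_enrichment("c", N=10, K=5, n=20, k=1)
        with pytest.raises(UsageError):
            cs.chromosome_enrichment("c", N=10, K=5, n=5, k=7)


class TestPercentileBins:
    def test_extreme_ranks(self):
        assert cs.rank_percentile_bins(np.array([1]), 100)[0] == 1
        assert cs.rank_percentile_bins(np.array([100]), 100)[0] == 10

    def test_partition_no_gaps_small_n(self):
        for n in range(1, 21):
            bins = cs.rank_percentile_bins(np.arange(1, n + 1), n)
            assert bins.min() >= 1 and bins.max() <= 10
            assert all(a <= b for a, b in zip(bins, bins[1:]))

    def test_equal_bin_sizes_when_divisible(self):
        bins = cs.rank_percentile_bins(np.arange(1, 101), 100)
        _, counts = np.unique(bins, return_counts=True)
        assert set(counts) == {10}


class TestSummaryStatistics:
    def test_all_se_contain_tss(self, called):
        table = called["table"].copy()
        table.loc[table["is_SE"], "percentage_outs"] = 50.0
        stats = cs.summary_statistics(table, subpeak_table(called["regions"]))
        row = stats["ins_outs"].set_index("class").loc["SE"]
        assert row["pct_with_tss"] == 100.0

    def test_se_regions_longer_than_te(self, called):
        table = called["table"]
        lengths = table["end"] - table["start"]
        assert lengths[table["is_SE"]].mean() > lengths[~table["is_SE"]].mean()

    def test_singleton_te_histogram_mass_at_one(self, called):
        stats = cs.summary_statistics(called["table"], subpeak_table(called["regions"]))
        hist = stats["subpeak_count_hist_10"]
        te = hist[hist["class"] == "TE"]
        mass = te[(te["bin_left"] < 1) & (te["bin_right"] >= 1)]["count"].sum()
        assert mass == te["count"].sum()  # every TE has exactly one subpeak
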