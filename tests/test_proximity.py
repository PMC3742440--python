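import math

import numpy as np
import pytest

from peakprox.models import (
    GeneList,
    GeneRecord,
    GenomeModel,
    GenomicInterval,
    PeakSet,
    ProximityCategory,
)
from peakprox.proximity import (
    categorize,
    dedup_unique_tss,
    enrichment_test,
    expected_count,
    filter_against_control,
    overlap_summary,
    peaks_per_gene,
    tss_histogram,
    uniform_background,
)


def iv(start, end, chrom="chr1"):
    return GenomicInterval(chrom, start, end)


def plus_gene(tss, body=5_000, chrom="chr1", gene_id="g"):
    return GeneRecord(gene_id, chrom, "+", tss, tss, tss + body)


def minus_gene(tss, body=5_000, chrom="chr1", gene_id="g"):
    return GeneRecord(gene_id, chrom, "-", tss, tss - body + 1, tss + 1)


class TestFilterAgainstControl:
    def test_manual_partition(self):
        t = PeakSet("t", [iv(0, 100), iv(200, 300), iv(400, 500)])
        c = PeakSet("c", [iv(250, 260)])
        retained, removed = filter_against_control(t, c)
        assert [x.start for x in retained] == [0, 400]
        assert [x.start for x in removed] == [200]

    def test_empty_control_retains_all(self):
        t = PeakSet("t", [iv(0, 100), iv(200, 300)])
        retained, removed = filter_against_control(t, PeakSet("c", []))
        assert len(retained) == 2 and len(removed) == 0

    def test_partition_is_exact(self):
        t = PeakSet("t", [iv(i * 10, i * 10 + 5) for i in range(50)])
        c = PeakSet("c", [iv(3, 25), iv(402, 403)])
        retained, removed = filter_against_control(t, c)
        assert len(retained) + len(removed) == len(t)
        kept = {(x.start, x.end) for x in retained} | {(x.start, x.end) for x in removed}
        assert kept == {(x.start, x.end) for x in t}

    def test_genome_mismatch_errors(self):
        g1 = GenomeModel({"chr1": 1000})
        g2 = GenomeModel({"chr1": 2000})
        with pytest.raises(ValueError, match="different genomes"):
            filter_against_control(
                PeakSet("t", [iv(0, 10)], g1), PeakSet("c", [iv(0, 10)], g2)
            )


class TestDedupUniqueTss:
    def test_identical_tss_keeps_first(self):
        gl = GeneList(
            "l",
            [
                plus_gene(1000, gene_id="iso1"),
                plus_gene(1000, body=9_000, gene_id="iso2"),
                plus_gene(50_000, gene_id="other"),
            ],
        )
        out = dedup_unique_tss(gl)
        assert [g.gene_id for g in out] == ["iso1", "other"]

    def test_different_strands_both_kept(self):
        gl = GeneList("l", [plus_gene(5000, gene_id="p"), minus_gene(5000, gene_id="m")])
        assert len(dedup_unique_tss(gl)) == 2


class TestPeaksPerGene:
    def test_both_flanks_counted(self):
        gene = plus_gene(1_000_000)
        peaks = PeakSet("p", [iv(949_900, 950_100), iv(1_049_900, 1_050_100)])
        res = peaks_per_gene(peaks, GeneList("l", [gene]))
        assert res.per_gene["g"] == 2
        assert res.tally == {"0": 0, "1": 0, "2": 1, "3+": 0}

    def test_boundary_midpoint_is_counted(self):
        gene = plus_gene(1_000_000)
        peaks = PeakSet("p", [iv(899_950, 900_050)])  # midpoint exactly -100 kb
        assert peaks_per_gene(peaks, GeneList("l", [gene])).per_gene["g"] == 1

    def test_shared_peak_counts_once_in_distinct_total(self):
        g1, g2 = plus_gene(1_000_000, gene_id="g1"), plus_gene(1_050_000, gene_id="g2")
        peaks = PeakSet("p", [iv(1_024_900, 1_025_100)])
        res = peaks_per_gene(peaks, GeneList("l", [g1, g2]))
        assert res.per_gene == {"g1": 1, "g2": 1}
        assert res.assignments == 2
        assert res.distinct_peaks == 1

    def test_any_overlap_mode_catches_straddling_peak(self):
        gene = plus_gene(1_000_000)
        straddler = iv(895_000, 900_500)  # midpoint outside, body crosses -100 kb
        peaks = PeakSet("p", [straddler])
        assert peaks_per_gene(peaks, GeneList("l", [gene])).per_gene["g"] == 0
        assert (
            peaks_per_gene(peaks, GeneList("l", [gene]), peak_point="any-overlap")
            .per_gene["g"] == 1
        )


class TestCategorize:
    @pytest.mark.parametrize(
        "gene, span, expected",
        [
            (plus_gene(10_000), (9_400, 9_600), ProximityCategory.UPSTREAM_0_1K),
            (plus_gene(10_000), (12_000, 12_001), ProximityCategory.GENE_BODY),
            (minus_gene(14_999), (7_900, 8_100), ProximityCategory.DOWNSTREAM_WITHIN_100K),
            (plus_gene(10_000), (4_000, 4_100), ProximityCategory.UPSTREAM_1_20K),
            (plus_gene(500_000), (430_000, 430_100), ProximityCategory.UPSTREAM_20_100K),
            (plus_gene(500_000), (100, 200), ProximityCategory.NONE),
            (plus_gene(10_000), (16_000, 16_100), ProximityCategory.DOWNSTREAM_WITHIN_100K),
        ],
    )
    def test_examples(self, gene, span, expected):
        assert categorize(iv(*span), gene) is expected

    def test_gene_body_takes_precedence_near_tss(self):
        # midpoint 500 bp into a long gene: inside body AND <1 kb downstream of TSS
        gene = plus_gene(10_000, body=50_000)
        assert categorize(iv(10_400, 10_600), gene) is ProximityCategory.GENE_BODY


class TestUniformBackground:
    def test_single_peak_spacing_is_genome_size(self):
        g = GenomeModel({"chr1": 123_456})
        assert uniform_background(1, g) == (1 / 123_456, 123_456.0)

    def test_density_direct_division(self):
        g = GenomeModel({"chr1": 1_000_000})
        density, spacing = uniform_background(10, g)
        assert density == pytest.approx(1e-5)
        assert spacing == pytest.approx(100_000)

    def test_zero_peaks_errors(self):
        with pytest.raises(ValueError):
            uniform_background(0, GenomeModel({"chr1": 100}))


class TestExpectedCount:
    def _list_of_200(self):
        return GeneList(
            "l", [plus_gene(i * 1_000_000, gene_id=f"g{i}") for i in range(1, 201)]
        )

    def test_naive_uniform_formula(self):
        genome = GenomeModel({"chr1": 2_750_000_000})
        value = expected_count(2_085, genome, self._list_of_200(), 100_000)
        assert value == pytest.approx(2_085 / 2.75e9 * 4.0e7, rel=1e-12)
        assert value == pytest.approx(30.33, abs=0.01)

    def test_window_spanning_genome_conserves_peaks(self):
        genome = GenomeModel({"chr1": 1_000_000})
        gl = GeneList("l", [plus_gene(500_000)])
        assert expected_count(50, genome, gl, 500_000) == pytest.approx(50.0)

    def test_empty_list_is_zero(self):
        genome = GenomeModel({"chr1": 1_000_000})
        assert expected_count(50, genome, GeneList("l", []), 100_000) == 0.0

    def test_merged_windows_not_larger_than_naive(self):
        genome = GenomeModel({"chr1": 10_000_000})
        gl = GeneList(
            "l", [plus_gene(1_000_000, gene_id="a"), plus_gene(1_050_000, gene_id="b")]
        )
        naive = expected_count(100, genome, gl, 100_000)
        merged = expected_count(100, genome, gl, 100_000, merge_windows=True)
        assert merged < naive


class TestEnrichmentTest:
    def test_observed_equal_expected_gives_p_one(self):
        rep = enrichment_test({"a": 15, "b": 15}, {"a": 15.0, "b": 15.0})
        assert rep.joint_statistic == pytest.approx(0.0)
        assert rep.joint_p_value == pytest.approx(1.0)

    def test_textbook_two_cell_example(self):
        rep = enrichment_test({"a": 10, "b": 20}, {"a": 15.0, "b": 15.0})
        assert rep.joint_statistic == pytest.approx(10 / 3, rel=1e-12)
        assert rep.joint_df == 1
        # independent route: chi2(1) upper tail via the normal tail
        expected_p = math.erfc(math.sqrt(10 / 3 / 2))
        assert rep.joint_p_value == pytest.approx(expected_p, rel=1e-12)

    def test_near_background_lists_have_fold_near_one(self):
        # counts like the non-target lists: 39/40 observed vs ~30 expected
        rep = enrichment_test({"n": 39, "a": 40}, {"n": 30.33, "a": 30.33})
        assert rep.per_list["n"].fold == pytest.approx(1.29, abs=0.01)
        assert rep.per_list["a"].fold == pytest.approx(1.32, abs=0.01)

    def test_nonpositive_expected_rejected(self):
        with pytest.raises(ValueError):
            enrichment_test({"a": 1}, {"a": 0.0})


class TestTssHistogram:
    def _peaks(self, mids, chrom="chr1"):
        return PeakSet("p", [iv(m - 50, m + 50, chrom) for m in mids])

    def test_manual_binning_around_plus_gene(self):
        gl = GeneList("l", [plus_gene(1_000_000)])
        hist = tss_histogram(self._peaks([997_000, 1_002_000]), gl)
        n_half = len(hist.counts) // 2
        assert hist.counts.sum() == 2
        assert hist.counts[n_half - 1] == 1  # [-5000, 0)
        assert hist.counts[n_half] == 1  # [0, 5000)

    def test_no_peaks_in_range_all_zero(self):
        gl = GeneList("l", [plus_gene(10_000_000)])
        hist = tss_histogram(self._peaks([1_000]), gl)
        assert hist.counts.sum() == 0

    def test_minus_strand_mirror_reproduces_plus_histogram(self):
        plus = GeneList("l", [plus_gene(1_000_000)])
        minus = GeneList("l", [minus_gene(1_000_000)])
        offsets = [-70_000, -3_000, 2_000, 44_000]
        h_plus = tss_histogram(self._peaks([1_000_000 + o for o in offsets]), plus)
        h_minus = tss_histogram(self._peaks([1_000_000 - o for o in offsets]), minus)
        np.testing.assert_array_equal(h_plus.counts, h_minus.counts)

    def test_invariant_under_renaming_and_translation(self):
        gl = GeneList("l", [plus_gene(1_000_000)])
        mids = [940_000, 997_000, 1_002_000, 1_060_000]
        base = tss_histogram(self._peaks(mids), gl)
        shift = 123_456
        gl2 = GeneList(
            "l", [GeneRecord("g", "chrX", "+", 1_000_000 + shift, 1_000_000 + shift,
                             1_005_000 + shift)]
        )
        moved = tss_histogram(self._peaks([m + shift for m in mids], chrom="chrX"), gl2)
        np.testing.assert_array_equal(base.counts, moved.counts)

    def test_counts_sum_matches_in_range_assignments(self):
        rng = np.random.default_rng(7)
        mids = rng.integers(0, 3_000_000, size=300)
        gl = GeneList("l", [plus_gene(1_500_000)])
        hist = tss_histogram(self._peaks(sorted(int(m) for m in mids)), gl)
        in_range = sum(abs(int(m) - 1_500_000) <= 100_000 for m in mids)
        assert hist.counts.sum() == in_range


class TestOverlapSummary:
    def test_self_overlap_fraction_one(self):
        a = PeakSet("a", [iv(0, 10), iv(20, 30)])
        assert overlap_summary(a, a).fraction_ab == 1.0

    def test_manual_fraction(self):
        a = PeakSet("a", [iv(0, 10), iv(20, 30), iv(40, 50)])
        b = PeakSet("b", [iv(5, 8), iv(41, 60)])
        res = overlap_summary(a, b)
        assert res.count_ab == 2
        assert res.fraction_ab == pytest.approx(2 / 3)

    def test_triple_with_empty_c_is_zero(self):
        a = PeakSet("a", [iv(0, 10)])
        b = PeakSet("b", [iv(5, 8)])
        res = overlap_summary(a, b, PeakSet("c", []))
        assert res.triple_count == 0

    def test_triple_requires_both_partners(self):
        a = PeakSet("a", [iv(0, 10), iv(20, 30), iv(40, 50)])
        b = PeakSet("b", [iv(0, 5), iv(25, 26)])
        c = PeakSet("c", [iv(8, 9), iv(45, 46)])
        res = overlap_summary(a, b, c)
        assert res.triple_count == 1  # only [0,10) touched by both
        assert res.triple_count <= min(res.count_ab, res.count_ac)
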