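import math
from fractions import Fraction

import pytest
from hypothesis import given
from hypothesis import strategies as st

from peakprox.motifs import (
    Motif,
    canonical_kmer,
    central_enrichment,
    discover,
    expand_iupac,
    revcomp,
    scan,
    scan_bruteforce,
    spaced_pair,
    _fisher_greater,
)


class TestExpandIupac:
    def test_consensus_with_one_degenerate_position(self):
        assert expand_iupac("CTGGYAC") == {"CTGGCAC", "CTGGTAC"}

    def test_exact_word_expands_to_itself(self):
        assert expand_iupac("ACGT") == {"ACGT"}

    def test_fully_degenerate_dimer(self):
        assert len(expand_iupac("NN")) == 16

    def test_invalid_letter_rejected(self):
        with pytest.raises(ValueError):
            Motif("CTGGXAC")


class TestRevcomp:
    @pytest.mark.parametrize(
        "seq, expected",
        [("CTGGCAC", "GTGCCAG"), ("CTGGYAC", "GTRCCAG"), ("ACWT", "AWGT")],
    )
    def test_examples(self, seq, expected):
        assert revcomp(seq) == expected

    @given(st.text(alphabet="ACGTRYSWKMBDHVN", min_size=1, max_size=30))
    def test_involution(self, seq):
        assert revcomp(revcomp(seq)) == seq


class TestScan:
    def test_forward_hit(self):
        hits = scan("AACTGGCACTT", "CTGGYAC")
        assert [(h.offset, h.strand, h.matched) for h in hits] == [(2, "+", "CTGGCAC")]

    def test_reverse_hit_reports_forward_offset(self):
        hits = scan("AAGTGCCAGTT", "CTGGYAC")
        assert [(h.offset, h.strand, h.matched) for h in hits] == [(2, "-", "CTGGCAC")]

    def test_empty_and_short_sequences_yield_no_hits(self):
        assert scan("", "CTGGYAC") == []
        assert scan("CTGG", "CTGGYAC") == []

    def test_n_in_sequence_never_matches(self):
        assert scan("AACTGGNACTT", "CTGGYAC") == []
        assert scan("ANA", "ANA", both_strands=False) == []  # N motif letter too

    def test_overlapping_hits_all_reported(self):
        hits = scan("AAAAA", "AA", both_strands=False)
        assert [h.offset for h in hits] == [0, 1, 2, 3]

    @given(
        seq=st.text(alphabet="ACGTN", min_size=0, max_size=300),
        motif=st.sampled_from(["CTGGYAC", "ACAAWG", "RYN", "GC", "ANAAWG"]),
    )
    def test_matches_all_offsets_oracle(self, seq, motif):
        assert scan(seq, motif) == scan_bruteforce(seq, motif)

    @given(seq=st.text(alphabet="ACGT", min_size=7, max_size=200))
    def test_strand_symmetry(self, seq):
        """Hit count is invariant under reverse-complementing either the
        motif or the sequence (offsets shift, counts must not)."""
        motif = "CTGGYAC"
        n = len(scan(seq, motif))
        assert len(scan(seq, revcomp(motif))) == n
        assert len(scan(revcomp(seq), motif)) == n


class TestCentralEnrichment:
    @staticmethod
    def _make_seq(offset, L=56, word="CTGGCAC"):
        # all-A background cannot produce spurious CTGGYAC/GTRCCAG hits
        return "A" * offset + word + "A" * (L - offset - len(word))

    def test_all_central_matches_closed_form_power(self):
        # L=56, m=7, width 9 -> 10 central of 50 offsets: null exactly 0.2
        seqs = [(f"s{i}", self._make_seq(24)) for i in range(10)]
        res = central_enrichment(seqs, "CTGGYAC", central_width=9)
        assert res.null_prob == pytest.approx(0.2, rel=1e-12)
        assert (res.n_sequences_with_hit, res.n_central) == (10, 10)
        assert res.p_value == pytest.approx(0.2**10, rel=1e-12)

    def test_nine_of_ten_matches_binomial_tail(self):
        seqs = [(f"s{i}", self._make_seq(24)) for i in range(9)]
        seqs.append(("s9", self._make_seq(0)))
        res = central_enrichment(seqs, "CTGGYAC", central_width=9)
        expected = 10 * 0.2**9 * 0.8 + 0.2**10
        assert (res.n_sequences_with_hit, res.n_central) == (10, 9)
        assert res.p_value == pytest.approx(expected, rel=1e-12)

    def test_no_hits_gives_p_one(self):
        seqs = [("s0", "A" * 56)]
        res = central_enrichment(seqs, "CTGGYAC", central_width=9)
        assert res.n_sequences_with_hit == 0
        assert res.p_value == 1.0

    def test_mixed_lengths_rejected(self):
        with pytest.raises(ValueError, match="length"):
            central_enrichment([("a", "ACGTACG"), ("b", "ACGT")], "GC")


class TestSpacedPair:
    def test_three_bp_gap_counted(self):
        rep = spaced_pair([("s", "CTGGCACNNNCTGGCAC")], "CTGGYAC", "CTGGYAC")
        assert rep.counts[3] == 1
        assert rep.best_gap == 3

    def test_uniform_gaps_not_significant(self):
        # one pair at every gap 0..10: perfectly uniform
        seqs = [
            (f"s{g}", "CTGGCAC" + "A" * g + "CTGGCAC") for g in range(11)
        ]
        rep = spaced_pair(seqs, "CTGGYAC", "CTGGYAC")
        assert rep.n_pairs == 11
        assert rep.p_value > 0.5

    def test_concentrated_gap_closed_form(self):
        seqs = [(f"s{i}", "CTGGCACAAACTGGCAC") for i in range(20)]
        rep = spaced_pair(seqs, "CTGGYAC", "CTGGYAC")
        assert rep.counts[3] == 20 and rep.n_pairs == 20
        assert rep.p_value == pytest.approx(11 * (1 / 11) ** 20, rel=1e-9)

    def test_overlapping_matches_excluded(self):
        rep = spaced_pair([("s", "AAAAAA")], "AAA", "AAA")
        # all AAA hits overlap each other except gap >= 0 pairs at offsets 0/3
        assert rep.counts.sum() == rep.n_pairs
        assert all(g >= 0 for g in range(len(rep.counts)))

    def test_distinct_motifs_both_orders_counted(self):
        # primary downstream of secondary still yields the same gap
        rep = spaced_pair([("s", "ACAATGAAACTGGCAC")], "CTGGYAC", "ACAAWG")
        assert rep.counts[3] == 1


class TestFisher:
    def test_hand_enumerated_hypergeometric_tail(self):
        # table [[8,2],[1,9]]: P(X >= 8) with margins 10/10 and 9/11
        exact = Fraction(45 * 10 + 10 * 1, math.comb(20, 9))
        p = _fisher_greater(8, 1, 10, 10)
        assert p == pytest.approx(float(exact), rel=1e-9)
        assert p == pytest.approx(0.00274, abs=5e-6)


class TestDiscover:
    def test_planted_consensus_recovered_rank_one(self):
        from peakprox.simulate import SimConfig, simulate_sequences, shuffle_sequences

        seqs, _ = simulate_sequences(SimConfig(seed=11, n_sequences=50))
        negs = shuffle_sequences(seqs, 11)
        found = discover(seqs, negs)
        assert found[0].iupac in ("CTGGYAC", "GTRCCAG")
        assert found[0].e_value < 1e-6

    def test_identical_sets_yield_no_signal(self):
        from peakprox.simulate import SimConfig, simulate_sequences

        seqs, _ = simulate_sequences(SimConfig(seed=5, n_sequences=20, plant_rate=0.0))
        found = discover(seqs, seqs)
        assert all(d.e_value >= 1.0 for d in found)

    def test_e_value_never_below_p(self):
        from peakprox.simulate import SimConfig, simulate_sequences, shuffle_sequences

        seqs, _ = simulate_sequences(SimConfig(seed=6, n_sequences=30))
        found = discover(seqs, shuffle_sequences(seqs, 6))
        assert all(d.e_value >= d.fisher_p for d in found)


def test_canonical_kmer_collapses_strands():
    assert canonical_kmer("CTGGCAC") == canonical_kmer("GTGCCAG")
    assert canonical_kmer("ACGT") == "ACGT"  # palindrome maps to itself
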