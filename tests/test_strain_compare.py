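import numpy as np
import pytest

from conftest import mutate, random_seq
from symbiodiff.genome_io import Feature, GenomeRecord, build_partition
from symbiodiff.reference import gotoh_score
from symbiodiff.strain_compare import (NotCollinearError, Variant,
                                       align_strain_pair, apply_variants,
                                       call_variants, classify_variants,
                                       left_normalize, score_alignment)


class TestAlignStrainPair:
    def test_identical_sequences(self):
        seq = random_seq(np.random.default_rng(0), 500)
        amap = align_strain_pair(seq, seq, k=11)
        assert amap.identity_percent == 100.0
        assert amap.identical_positions == 500
        assert amap.n_columns == 500

    def test_single_mismatch_column(self):
        # one substitution at position 3
        amap = align_strain_pair("ACGTACGTAC", "ACGAACGTAC", k=3)
        assert amap.n_columns == 10
        assert amap.identical_positions == 9
        variants = call_variants(amap, "ACGTACGTAC", "ACGAACGTAC")
        assert [(v.vtype, v.pos, v.ref, v.alt) for v in variants] == \
            [("substitution", 3, "T", "A")]

    def test_every_position_appears_exactly_once(self):
        rng = np.random.default_rng(1)
        a = random_seq(rng, 800)
        b = mutate(rng, a, 10, 3)
        amap = align_strain_pair(a, b, k=15)
        apos = amap.a_pos[amap.a_pos >= 0]
        bpos = amap.b_pos[amap.b_pos >= 0]
        assert np.array_equal(np.sort(apos), np.arange(len(a)))
        assert np.array_equal(np.sort(bpos), np.arange(len(b)))
        assert np.array_equal(apos, np.sort(apos))  # monotone

    def test_not_collinear_raises(self):
        rng = np.random.default_rng(2)
        a = random_seq(rng, 20_000)
        b = random_seq(rng, 20_000)
        with pytest.raises(NotCollinearError):
            align_strain_pair(a, b, k=31)

    @pytest.mark.parametrize("seed", range(12))
    def test_anchored_score_equals_full_dp(self, seed):
        """Anchored alignment attains the optimal affine-gap score."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(200, 2000))
        a = random_seq(rng, n)
        b = mutate(rng, a, max(1, n // 100), max(1, n // 400))
        amap = align_strain_pair(a, b, k=21)
        assert score_alignment(amap, a, b) == gotoh_score(a, b)


class TestCallVariants:
    def test_identical_yields_empty(self):
        seq = random_seq(np.random.default_rng(3), 300)
        amap = align_strain_pair(seq, seq, k=11)
        assert call_variants(amap, seq, seq) == []

    def test_deletion_left_normalized_in_homopolymer(self):
        a, b = "AAAAAG", "AAAAG"
        amap = align_strain_pair(a, b, k=3)
        (v,) = call_variants(amap, a, b)
        assert v.vtype == "deletion" and v.length == 1
        # leftmost equivalent placement: the run starts at position 0
        assert v.pos == 0 and v.seg_start in (0, 1)
        assert apply_variants(a, [v]) == b

    def test_mixed_gap_run_split_into_two_events(self):
        # B deletes CCC and inserts GGG at the same spot
        a = "ATATATA" + "CCC" + "TTTTGAGAGA"
        b = "ATATATA" + "GGG" + "TTTTGAGAGA"
        amap = align_strain_pair(a, b, k=5)
        variants = call_variants(amap, a, b)
        types = sorted(v.vtype for v in variants)
        # either 3 substitutions or a split deletion+insertion pair
        assert types in (["deletion", "insertion"],
                         ["substitution"] * 3)
        assert apply_variants(a, variants) == b

    @pytest.mark.parametrize("seed", range(10))
    def test_reconstruction_round_trip(self, seed):
        """Applying called variants to A reproduces B byte-for-byte, and the
        length bookkeeping balances."""
        rng = np.random.default_rng(100 + seed)
        a = random_seq(rng, 1500)
        b = mutate(rng, a, 12, 4)
        amap = align_strain_pair(a, b, k=15)
        variants = call_variants(amap, a, b)
        assert apply_variants(a, variants) == b
        ins = sum(v.length for v in variants if v.vtype == "insertion")
        dels = sum(v.length for v in variants if v.vtype == "deletion")
        assert len(b) - len(a) == ins - dels

    @pytest.mark.parametrize("seed", range(6))
    def test_swap_symmetry(self, seed):
        rng = np.random.default_rng(200 + seed)
        a = random_seq(rng, 1200)
        b = mutate(rng, a, 10, 3)
        va = call_variants(align_strain_pair(a, b, k=15), a, b)
        vb = call_variants(align_strain_pair(b, a, k=15), b, a)
        def counts(vs):
            return (sum(1 for v in vs if v.vtype == "substitution"),
                    sum(1 for v in vs if v.vtype == "insertion"),
                    sum(1 for v in vs if v.vtype == "deletion"))
        sa, ia, da = counts(va)
        sb, ib, db = counts(vb)
        assert sa == sb and ia == db and da == ib

    def test_n_columns_never_called_as_substitutions(self):
        a = "ACGTACGTNNACGTACGTAC"
        b = "ACGTACGTGGACGTACGTAC"
        amap = align_strain_pair(a, b, k=5)
        assert call_variants(amap, a, b) == []


class TestLeftNormalize:
    @pytest.mark.parametrize("seq,p,allele,want_p", [
        ("AAAAAG", 4, "A", 0),        # shift through the whole run
        ("ACACACG", 4, "AC", 0),      # dinucleotide rotation
        ("ACGTT", 3, "T", 3),         # already leftmost
    ])
    def test_known_shifts(self, seq, p, allele, want_p):
        got_p, got_allele = left_normalize(seq, p, allele)
        assert got_p == want_p
        # equivalence: deleting the segment yields the same string
        assert seq[:p] + seq[p + len(allele):] == \
            seq[:got_p] + seq[got_p + len(got_allele):]


class TestClassifyVariants:
    def _partition(self, n=100):
        rec = GenomeRecord(id="x", sequence="A" * n,
                           features=[Feature(kind="CDS", strand="+",
                                             intervals=[(0, 60)], name="g",
                                             qualifiers={})])
        return build_partition(rec)

    def test_c_to_t_is_transition_gc_to_at(self):
        v = Variant(vtype="substitution", pos=5, ref="C", alt="T", length=1)
        s = classify_variants([v], self._partition())
        assert v.labels["titv"] == "ti"
        assert v.labels["direction"] == "GCtoAT"
        assert v.labels["at_gaining_strain"] == "B"
        assert s.ti == 1 and s.direction_counts["GCtoAT"] == 1

    def test_direction_classes_partition_substitutions(self):
        subs = [Variant("substitution", i, r, a, 1) for i, (r, a) in
                enumerate([("G", "A"), ("A", "G"), ("A", "T"), ("G", "C"),
                           ("C", "A"), ("T", "G")])]
        s = classify_variants(subs, self._partition())
        assert sum(s.direction_counts.values()) == 6
        assert s.direction_counts == {"GCtoAT": 2, "ATtoGC": 2,
                                      "AtoT_or_TtoA": 1, "GtoC_or_CtoG": 1}
        assert s.gc_at_changes == 4
        assert s.at_gain_counts == {"A": 2, "B": 2}

    def test_planted_transition_count_recovered(self):
        rng = np.random.default_rng(9)
        ti_pairs = [("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")]
        tv_pairs = [("A", "C"), ("C", "A"), ("G", "T"), ("T", "A")]
        subs = []
        for i in range(100):
            r, a = ti_pairs[int(rng.integers(4))] if i < 70 else \
                tv_pairs[int(rng.integers(4))]
            subs.append(Variant("substitution", i, r, a, 1))
        s = classify_variants(subs, self._partition())
        assert s.ti == 70 and s.tv == 30

    def test_partition_class_taken_from_strain_a(self):
        v_cod = Variant("substitution", 10, "A", "G", 1)
        v_igr = Variant("substitution", 80, "A", "G", 1)
        s = classify_variants([v_cod, v_igr], self._partition())
        assert v_cod.labels["partition"] == "coding"
        assert v_igr.labels["partition"] == "igr"
        assert s.partition_counts["substitution"] == {"coding": 1, "igr": 1}
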