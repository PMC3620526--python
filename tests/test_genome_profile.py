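import numpy as np
import pytest
from scipy import stats

from symbiodiff.genome_io import (CDSRecord, Feature, GenomeRecord,
                                  build_partition)
from symbiodiff.genome_profile import (SYNONYMOUS_FAMILIES, aa_profile,
                                       amino_acid_gc_rank, codon_bias_test,
                                       codon_usage, summarize_genome,
                                       translate_cds)


def _cds(name, seq):
    return CDSRecord(name=name, sequence=seq, strand="+", start=0,
                     end=len(seq), in_frame=len(seq) % 3 == 0, n_positions=[])


class TestSummarizeGenome:
    def test_all_g_genome(self):
        rec = GenomeRecord(id="g", sequence="G" * 10)
        s = summarize_genome(rec, build_partition(rec))
        assert s.gc_overall == 100.0 and s.gc_igr == 100.0

    def test_stratified_gc_by_hand(self):
        # 60 bp: CDS [0,30) with 15 GC (50%), IGR [30,60) with 6 GC (20%)
        cds = "GC" * 7 + "G" + "AT" * 7 + "A"
        igr = "GGGCCC" + "A" * 24
        rec = GenomeRecord(id="h", sequence=cds + igr,
                           features=[Feature(kind="CDS", strand="+",
                                             intervals=[(0, 30)], name="g",
                                             qualifiers={})])
        s = summarize_genome(rec, build_partition(rec))
        assert s.gc_genes == pytest.approx(50.0)
        assert s.gc_igr == pytest.approx(20.0)
        assert s.gc_overall == pytest.approx(35.0)

    def test_gc_mixture_identity(self, annotated_300bp):
        part = build_partition(annotated_300bp)
        s = summarize_genome(annotated_300bp, part)
        mix = sum(part.class_lengths[c] * gc for c, gc in [
            ("coding", s.gc_genes), ("rna", s.gc_genes),
            ("pseudogene", s.gc_pseudogenes), ("igr", s.gc_igr)]
            if part.class_lengths[c]) / 300
        # genes class pools coding+rna; fixture has no rna, so exact
        assert mix == pytest.approx(s.gc_overall, abs=1e-9)

    def test_mean_lengths(self, tiny_record):
        s = summarize_genome(tiny_record, build_partition(tiny_record))
        assert s.mean_orf_length == 30.0
        assert s.mean_igr_length == pytest.approx(30.0)   # (10 + 50) / 2


class TestCodonUsage:
    def test_single_cds_counts(self):
        t = codon_usage([_cds("g", "ATGAAATAA")])
        assert t.codon_counts["ATG"] == 1 and t.codon_counts["AAA"] == 1
        assert t.stop_counts == {"TAA": 1, "TAG": 0, "TGA": 0}

    def test_stop_fraction_by_hand(self):
        cds = [_cds(f"g{i}", "ATGAAA" + stop)
               for i, stop in enumerate(["TAA", "TAA", "TAA", "TGA"])]
        t = codon_usage(cds)
        assert t.stop_fraction("TAA") == pytest.approx(75.0)

    def test_internal_stop_excluded_and_reported(self):
        t = codon_usage([_cds("bad", "ATGTAAAAATAA"), _cds("ok", "ATGAAATAA")])
        assert t.excluded == ["bad"] and t.n_cds == 1

    def test_codon_count_conservation(self):
        cds = [_cds("a", "ATGGCTGCAGCTTAA"), _cds("b", "ATGAAAGAACGTTGA")]
        t = codon_usage(cds)
        total_codons = sum(len(c.sequence) // 3 for c in cds)
        assert sum(t.codon_counts.values()) + sum(t.stop_counts.values()) \
            == total_codons


class TestCodonBiasTest:
    def _table_with(self, counts):
        t = codon_usage([])
        t.codon_counts.update(counts)
        return t

    def test_uniform_family_unbiased(self):
        res = codon_bias_test(self._table_with({"TTT": 50, "TTC": 50}),
                              alpha=0.01)
        assert res["F"]["status"] == "unbiased"

    def test_skewed_family_chi_square_statistic(self):
        # (90-50)^2/50 + (10-50)^2/50 = 64, df 1 -> decisively biased
        t = self._table_with({"TTT": 90, "TTC": 10})
        res = codon_bias_test(t, alpha=0.01)
        assert res["F"]["status"] == "biased"
        chi2, p = stats.chisquare([90, 10])
        assert chi2 == pytest.approx(64.0)
        assert res["F"]["p_value"] == pytest.approx(p)

    def test_empty_family_untestable(self):
        res = codon_bias_test(self._table_with({}), alpha=0.01)
        assert res["F"]["status"] == "untestable"
        assert res["M"]["status"] == "untestable"   # single-codon family

    def test_small_counts_use_exact_test(self):
        res = codon_bias_test(self._table_with({"TTT": 4, "TTC": 0}),
                              alpha=0.01)
        assert res["F"]["test"] == "exact-multinomial"
        # P(4:0 or 0:4) = 2 * (1/2)^4 = 0.125 under the uniform null
        assert res["F"]["p_value"] == pytest.approx(0.125)
        assert res["F"]["status"] == "unbiased"

    def test_type_one_error_rate_matches_alpha(self):
        """Uniform synonymous families are rejected at ~alpha rate."""
        rng = np.random.default_rng(0)
        alpha, n_fam, fam_total = 0.05, 1000, 400
        rejections = 0
        for _ in range(n_fam):
            counts = rng.multinomial(fam_total, [0.5, 0.5])
            t = self._table_with({"TTT": int(counts[0]), "TTC": int(counts[1])})
            if codon_bias_test(t, alpha=alpha)["F"]["status"] == "biased":
                rejections += 1
        sigma = np.sqrt(n_fam * alpha * (1 - alpha))
        assert abs(rejections - n_fam * alpha) <= 3 * sigma


class TestAAProfile:
    def test_poly_ala_protein(self):
        prof = aa_profile([_cds("a", "ATG" + "GCT" * 20 + "TAA")])
        # Met start + 20 Ala
        assert prof.frequencies["A"] == pytest.approx(20 / 21)

    def test_hand_counted_two_proteins(self):
        prof = aa_profile([_cds("a", "ATGGCTGCATAA"),      # M A A
                           _cds("b", "ATGAAAGAACGTTGA")])  # M K E R
        assert prof.n_residues == 7
        assert prof.frequencies["A"] == pytest.approx(2 / 7)
        assert prof.frequencies["M"] == pytest.approx(2 / 7)
        assert prof.frequencies["K"] == pytest.approx(1 / 7)

    def test_frequencies_sum_to_one(self, annotated_300bp):
        from symbiodiff.genome_io import extract_cds
        prof = aa_profile(extract_cds(annotated_300bp))
        assert sum(prof.frequencies.values()) == pytest.approx(1.0, abs=1e-9)

    def test_gc_rank_is_deterministic_and_sensible(self):
        rank = amino_acid_gc_rank()
        assert len(rank) == 20 and rank == amino_acid_gc_rank()
        # Gly/Ala/Pro codons are GC-rich; Lys/Ile/Phe are AT-rich
        assert rank.index("G") < rank.index("K")
        assert rank.index("A") < rank.index("F")
        assert set(rank[-4:]) <= {"K", "I", "F", "N", "Y"}

    def test_alternative_start_translated_as_met(self):
        assert translate_cds("GTGAAATAA") == "MK"
        with pytest.raises(ValueError):
            translate_cds("ATGTAAAAATAA")


def test_every_family_partitions_the_sense_codons():
    codons = [c for fam in SYNONYMOUS_FAMILIES.values() for c in fam]
    assert len(codons) == 61 and len(set(codons)) == 61
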