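"""Study conditions for the synthetic strain-pair scenarios.

Two annotated genome architectures and mutation loads are modelled on the
nested endosymbionts of the citrus mealybug: a tiny GC-rich genome
("tremblaya-like": 138,931 bp, 59% GC, 116 CDS, a duplicated rRNA-like
block and a 7,032 bp region flanked by 71 bp inverted repeats, 23
substitutions with 43.5% transitions and five 1-2 nt indels against its
sister strain) and a mid-sized AT-biased genome ("moranella-like":
538,203 bp, 44% GC, 406 CDS, 41 tRNAs, homopolymer-enriched IGRs, 262
substitutions of which 90.1% change GC content, 60 indels of mean size
5.4 nt with 58.3% in homopolymers, and 77 synonymous / 62 non-synonymous
coding changes).  A third, smaller pair supports fast end-to-end recovery
checks, and a fourth carries 10,000 substitutions for statistical recovery
of the planted class fractions.

Each scenario is a (GenomeSpec, MutationModel) pair; ``run_strain_pair``
executes the full comparison pipeline on it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .genome_io import GenomeRecord, GenomePartition, build_partition, extract_cds
from .indel_context import (IndelContextCall, classify_indel_context,
                            scan_homopolymers, scan_microsatellites,
                            summarize_contexts)
from .selection import SelectionSummary, estimate_dnds, pair_orthologs
from .strain_compare import (AlignmentMap, Variant, VariantSummary,
                             align_strain_pair, call_variants,
                             classify_variants)
from .synthetic_data import (GenomeSpec, MutationModel, TruthTable,
                             derive_strain, generate_genome)

__all__ = [
    "tremblaya_like", "moranella_like", "small_pair", "stat_pair",
    "StrainPairResult", "run_strain_pair", "simulate_pair",
]

# the default anticodon set minus CTT: the moranella-like genome decodes
# lysine AAA (anticodon TTT) but not AAG, mirroring the missing
# tRNA-Lys(AAG) of the real genome
_ANTICODONS_NO_CTT = (
    "TGC", "ACG", "GTT", "GTC", "GCA", "TTG", "TTC", "GCC", "GTG", "GAT",
    "TAG", "TTT", "CAT", "GAA", "TGG", "GCT", "TGT", "CCA", "GTA", "TAC")


def tremblaya_like(seed: int = 0) -> tuple[GenomeSpec, MutationModel]:
    """Tiny GC-rich genome; strain pair differing by 23 subs + 5 indels.

    Indels are fixed to four 1 nt and one 2 nt events with a net length
    change of -4 bp; 20/23 substitutions fall in coding sequence and all
    indels do, matching the observed concentration of changes in the coding
    fraction despite the low coding density.
    """
    spec = GenomeSpec(
        length=138_931, gc_content=0.590,
        n_cds=116, n_trna=7, n_pseudogenes=25,
        cds_length_mean=775.0, cds_length_sd=250.0,
        duplicated_block=(4_023, 2),
        ir_flanked=(71, 7_032),
        stop_weights=(0.40, 0.30, 0.30),
        seed=seed)
    model = MutationModel(
        n_substitutions=23,
        transition_fraction=10 / 23,
        gc_to_at_fraction=0.85,
        indel_events=[(1, "deletion"), (1, "deletion"), (1, "deletion"),
                      (1, "insertion"), (2, "deletion")],
        substitution_partition_weights={"coding": 20 / 23, "igr": 3 / 23},
        indel_partition_weights={"coding": 1.0},
        min_spacing=20,
        seed=seed + 1)
    return spec, model


def moranella_like(seed: int = 0) -> tuple[GenomeSpec, MutationModel]:
    """Mid-sized AT-biased genome; strain pair with the full mutational load.

    262 substitutions (90.1% GC<->AT; neutral remainder split 18:8 between
    A<->T and G<->C), 60 indels (mean 5.4 nt, 58.3% targeting homopolymers),
    substitutions split coding/IGR/pseudogene in proportion 139:123:12 and
    coding changes 77/139 synonymous.  IGRs are homopolymer-enriched so that
    A/T runs >= 6 nt number near 844 genome-wide.
    """
    spec = GenomeSpec(
        length=538_203, gc_content=0.440,
        n_cds=406, n_trna=41, n_pseudogenes=25,
        cds_length_mean=1_012.0, cds_length_sd=350.0,
        duplicated_block=(4_023, 2),
        # ~396 A/T runs >= 6 nt arise naturally at 44% GC over 538 kb; the
        # planted complement brings the expected total to ~844
        homopolymer_runs_per_kb=0.832,
        stop_weights=(0.5644, 0.2178, 0.2178),
        trna_anticodons=_ANTICODONS_NO_CTT,
        seed=seed)
    model = MutationModel(
        n_substitutions=262,
        transition_fraction=0.50,
        gc_to_at_fraction=236 / 262,
        neutral_split_at=18 / 26,
        n_indels=60,
        indel_size_mean=5.4,
        indel_size_max=75,
        homopolymer_targeting_prob=35 / 60,
        coding_synonymous_fraction=77 / 139,
        # the published per-partition counts (139 coding, 123 IGR, 12
        # pseudogene) sum to 274, not 262; the coding and pseudogene counts
        # are kept absolute (the selection analysis rests on 139) and the
        # IGR class absorbs the remainder
        substitution_partition_weights={"coding": 139 / 262, "igr": 111 / 262,
                                        "pseudogene": 12 / 262},
        indel_partition_weights={"igr": 40 / 60, "pseudogene": 7 / 60,
                                 "coding": 13 / 60},
        min_spacing=10,
        seed=seed + 1)
    return spec, model


def small_pair(seed: int = 0) -> tuple[GenomeSpec, MutationModel]:
    """150 kb pair with 23 substitutions and 5 indels for fast end-to-end
    planted-mutation recovery."""
    spec = GenomeSpec(
        length=150_000, gc_content=0.45,
        n_cds=110, n_trna=10, n_pseudogenes=8,
        cds_length_mean=900.0, cds_length_sd=300.0,
        homopolymer_runs_per_kb=0.8,
        seed=seed)
    model = MutationModel(
        n_substitutions=23,
        transition_fraction=10 / 23,
        gc_to_at_fraction=0.85,
        n_indels=5,
        indel_size_mean=1.5,
        indel_size_max=4,
        homopolymer_targeting_prob=0.4,
        min_spacing=20,
        seed=seed + 1)
    return spec, model


def stat_pair(seed: int = 0,
              n_substitutions: int = 10_000) -> tuple[GenomeSpec, MutationModel]:
    """IGR-heavy 300 kb pair carrying a large substitution load for
    statistical recovery of the planted class fractions (use k=15 anchors:
    at ~3% divergence unique 31-mers become sparse)."""
    spec = GenomeSpec(
        length=300_000, gc_content=0.45,
        n_cds=50, n_trna=5, n_pseudogenes=5,
        cds_length_mean=900.0, cds_length_sd=300.0,
        seed=seed)
    model = MutationModel(
        n_substitutions=n_substitutions,
        transition_fraction=0.435,
        gc_to_at_fraction=0.901,
        neutral_split_at=18 / 26,
        min_spacing=4,
        seed=seed + 1)
    return spec, model


@dataclass
class StrainPairResult:
    ancestor: GenomeRecord
    derived: GenomeRecord
    truth: TruthTable
    partition: GenomePartition
    amap: AlignmentMap
    variants: list[Variant]
    summary: VariantSummary
    context_calls: list[IndelContextCall] = field(default_factory=list)
    context_summary: dict = field(default_factory=dict)
    selection: SelectionSummary | None = None
    unmatched_genes: list[str] = field(default_factory=list)

    @property
    def length_difference(self) -> int:
        return len(self.derived) - len(self.ancestor)


def simulate_pair(spec: GenomeSpec, model: MutationModel,
                  ) -> tuple[GenomeRecord, GenomeRecord, TruthTable]:
    ancestor = generate_genome(spec)
    derived, truth = derive_strain(ancestor, model)
    return ancestor, derived, truth


def run_strain_pair(ancestor: GenomeRecord, derived: GenomeRecord,
                    truth: TruthTable | None = None,
                    k: int = 31,
                    with_selection: bool = True,
                    bootstrap_reps: int = 200,
                    seed: int = 0) -> StrainPairResult:
    """Full comparison pipeline: align, call, classify, indel context, and
    (optionally) NG86 selection over ortholog CDS pairs."""
    partition = build_partition(ancestor)
    amap = align_strain_pair(ancestor, derived, k=k)
    variants = call_variants(amap, ancestor, derived)
    summary = classify_variants(variants, partition)

    runs = scan_homopolymers(ancestor.sequence, min_len=6)
    tracts = scan_microsatellites(ancestor.sequence)
    calls = [classify_indel_context(v, runs, tracts)
             for v in variants if v.vtype != "substitution"]
    ctx_summary = summarize_contexts(calls)

    selection = None
    unmatched: list[str] = []
    if with_selection:
        cds_a = extract_cds(ancestor)
        cds_b = extract_cds(derived)
        alignments, unmatched = pair_orthologs(cds_a, cds_b)
        if alignments:
            selection = estimate_dnds(alignments, bootstrap_reps=bootstrap_reps,
                                      seed=seed)
    return StrainPairResult(
        ancestor=ancestor, derived=derived,
        truth=truth if truth is not None else TruthTable([], ancestor.id,
                                                         derived.id, 0),
        partition=partition, amap=amap, variants=variants, summary=summary,
        context_calls=calls, context_summary=ctx_summary,
        selection=selection, unmatched_genes=unmatched)
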