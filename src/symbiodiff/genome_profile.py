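"""Per-genome summary statistics.

Covers the descriptive layer of the comparison: genome size and feature
counts, gene density, GC content stratified by the positional partition
(genes / pseudogenes / IGRs), codon usage with a per-amino-acid bias test
against the uniform synonymous null, stop-codon incidence, and amino-acid
composition profiles ranked by the GC-richness of the encoding codons.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .genome_io import (CLASS_CODING, CLASS_IGR, CLASS_PSEUDO, CLASS_RNA,
                        CDSRecord, GenomePartition, GenomeRecord)

__all__ = [
    "GenomeSummary", "CodonUsageTable", "AAProfile",
    "summarize_genome", "codon_usage", "codon_bias_test", "aa_profile",
    "GENETIC_CODE", "SYNONYMOUS_FAMILIES", "STOP_CODONS", "amino_acid_gc_rank",
]

BASES = "TCAG"
CODONS = ["".join(c) for c in itertools.product("ACGT", repeat=3)]

# Standard bacterial code (translation table 11 has the same codon->aa map as
# the standard code; it differs only in which codons may initiate).
_CODE_STRING = (
    "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG")
GENETIC_CODE = {
    a + b + c: _CODE_STRING[16 * i + 4 * j + k]
    for i, a in enumerate(BASES)
    for j, b in enumerate(BASES)
    for k, c in enumerate(BASES)
}
STOP_CODONS = ("TAA", "TAG", "TGA")
START_CODONS_T11 = {"ATG", "GTG", "TTG", "ATT", "CTG", "ATA", "ATC"}

SYNONYMOUS_FAMILIES: dict[str, list[str]] = {}
for codon, aa in GENETIC_CODE.items():
    if aa != "*":
        SYNONYMOUS_FAMILIES.setdefault(aa, []).append(codon)
for fam in SYNONYMOUS_FAMILIES.values():
    fam.sort()

AA3 = {"A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp", "C": "Cys",
       "Q": "Gln", "E": "Glu", "G": "Gly", "H": "His", "I": "Ile",
       "L": "Leu", "K": "Lys", "M": "Met", "F": "Phe", "P": "Pro",
       "S": "Ser", "T": "Thr", "W": "Trp", "Y": "Tyr", "V": "Val"}


def amino_acid_gc_rank() -> list[str]:
    """Amino acids ordered by mean G+C fraction of their synonymous codons.

    Descending (GC-richest first); ties broken alphabetically by one-letter
    code, so the ordering is deterministic.
    """
    def mean_gc(aa: str) -> float:
        fams = SYNONYMOUS_FAMILIES[aa]
        return sum(sum(b in "GC" for b in c) / 3 for c in fams) / len(fams)

    return sorted(SYNONYMOUS_FAMILIES, key=lambda aa: (-mean_gc(aa), aa))


# ---------------------------------------------------------------------------
# Genome summary


@dataclass
class GenomeSummary:
    genome_id: str
    size: int
    n_cds: int
    n_rrna: int
    n_trna: int
    n_small_rna: int
    n_pseudogenes: int
    gene_density: float
    mean_orf_length: float
    mean_igr_length: float
    gc_overall: float
    gc_genes: float
    gc_pseudogenes: float
    gc_igr: float

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def _gc_percent(sub_gc: int, sub_at: int) -> float:
    denom = sub_gc + sub_at
    return 100.0 * sub_gc / denom if denom else 0.0


def summarize_genome(record: GenomeRecord, partition: GenomePartition) -> GenomeSummary:
    """Compute size, feature counts, density, mean lengths and stratified GC.

    GC per class is computed over the positions assigned to that class, with N
    excluded from numerator and denominator; the "genes" class is the union of
    coding and RNA positions.  Mean IGR length averages over maximal IGR
    intervals; mean ORF length averages over CDS features.
    """
    seq = np.frombuffer(record.sequence.encode(), dtype=np.uint8)
    is_gc = (seq == ord("G")) | (seq == ord("C"))
    is_at = (seq == ord("A")) | (seq == ord("T"))
    cls = partition.classes

    def gc_of(mask: np.ndarray) -> float:
        return _gc_percent(int(is_gc[mask].sum()), int(is_at[mask].sum()))

    genes_mask = (cls == CLASS_CODING) | (cls == CLASS_RNA)
    cds = record.features_of_kind("CDS")
    igrs = partition.igr_intervals()
    return GenomeSummary(
        genome_id=record.id,
        size=len(record),
        n_cds=len(cds),
        n_rrna=len(record.features_of_kind("rRNA")),
        n_trna=len(record.features_of_kind("tRNA")),
        n_small_rna=len(record.features_of_kind("smallRNA")),
        n_pseudogenes=len(record.features_of_kind("pseudogene")),
        gene_density=partition.gene_density,
        mean_orf_length=float(np.mean([f.length for f in cds])) if cds else 0.0,
        mean_igr_length=float(np.mean([e - s for s, e in igrs])) if igrs else 0.0,
        gc_overall=_gc_percent(int(is_gc.sum()), int(is_at.sum())),
        gc_genes=gc_of(genes_mask),
        gc_pseudogenes=gc_of(cls == CLASS_PSEUDO),
        gc_igr=gc_of(cls == CLASS_IGR),
    )


# ---------------------------------------------------------------------------
# Codon usage


@dataclass
class CodonUsageTable:
    codon_counts: dict[str, int]
    stop_counts: dict[str, int]
    n_cds: int
    excluded: list[str] = field(default_factory=list)  # CDS excluded (internal stop)

    @property
    def family_counts(self) -> dict[str, dict[str, int]]:
        """Per-amino-acid counts over its synonymous codons."""
        return {aa: {c: self.codon_counts[c] for c in fam}
                for aa, fam in SYNONYMOUS_FAMILIES.items()}

    @property
    def total_codons(self) -> int:
        return sum(self.codon_counts.values()) + sum(self.stop_counts.values())

    def stop_fraction(self, codon: str) -> float:
        """Percent of terminal stop codons that are `codon`."""
        total = sum(self.stop_counts.values())
        return 100.0 * self.stop_counts[codon] / total if total else 0.0


def codon_usage(cds_set: list[CDSRecord]) -> CodonUsageTable:
    """Tally codon usage over complete in-frame CDS.

    The final codon of each CDS goes to the stop tally (when it is a stop),
    never to the amino-acid tally.  CDS with an internal stop codon are
    excluded and reported in ``excluded``; out-of-frame or N-containing CDS
    are likewise excluded.
    """
    counts = {c: 0 for c in CODONS}
    stops = {c: 0 for c in STOP_CODONS}
    excluded = []
    n_used = 0
    for cds in cds_set:
        if not cds.in_frame or cds.n_positions:
            excluded.append(cds.name)
            continue
        codons = [cds.sequence[i:i + 3] for i in range(0, len(cds.sequence), 3)]
        body, last = codons[:-1], codons[-1]
        if any(GENETIC_CODE[c] == "*" for c in body):
            excluded.append(cds.name)
            continue
        n_used += 1
        for c in body:
            counts[c] += 1
        if GENETIC_CODE[last] == "*":
            stops[last] += 1
        else:
            counts[last] += 1
    return CodonUsageTable(codon_counts=counts, stop_counts=stops,
                           n_cds=n_used, excluded=excluded)


def _exact_multinomial_pvalue(observed: np.ndarray) -> float:
    """Two-sided exact multinomial test against the uniform null.

    p = sum of probabilities of all outcomes no more probable than the
    observed one.  Only used for small totals (expected count < 5), where
    enumeration is cheap.
    """
    n = int(observed.sum())
    k = len(observed)
    p = np.full(k, 1.0 / k)
    dist = stats.multinomial(n, p)
    p_obs = dist.pmf(observed)
    total = 0.0
    for combo in itertools.combinations(range(n + k - 1), k - 1):
        # stars and bars -> composition of n into k parts
        prev = -1
        parts = []
        for c in combo:
            parts.append(c - prev - 1)
            prev = c
        parts.append(n + k - 1 - prev - 1)
        pm = dist.pmf(parts)
        if pm <= p_obs * (1 + 1e-12):
            total += pm
    return min(1.0, float(total))


def codon_bias_test(table: CodonUsageTable, alpha: float = 0.01) -> dict[str, dict]:
    """Goodness-of-fit of each synonymous family against the uniform null.

    For every amino acid with >= 2 synonymous codons, the observed codon
    counts are tested against equal use of all family members: Pearson
    chi-square, replaced by an exact multinomial test when any expected count
    falls below 5.  Returns per amino acid a dict with ``status`` in
    {biased, unbiased, untestable}, the p-value and the test used.
    Single-codon families (Met, Trp) are untestable by construction.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    results: dict[str, dict] = {}
    for aa, fam in sorted(SYNONYMOUS_FAMILIES.items()):
        obs = np.array([table.codon_counts[c] for c in fam], dtype=float)
        n = obs.sum()
        if len(fam) < 2 or n == 0:
            results[aa] = {"status": "untestable", "p_value": None, "test": None}
            continue
        expected = n / len(fam)
        if expected < 5:
            pval = _exact_multinomial_pvalue(obs.astype(int))
            test = "exact-multinomial"
        else:
            _, pval = stats.chisquare(obs)
            test = "chi-square"
        results[aa] = {
            "status": "biased" if pval < alpha else "unbiased",
            "p_value": float(pval),
            "test": test,
        }
    return results


# ---------------------------------------------------------------------------
# Amino-acid profile


@dataclass
class AAProfile:
    frequencies: dict[str, float]   # 20 values summing to 1
    gc_rank: list[str]              # amino acids, GC-richest first
    n_residues: int

    def ranked_frequencies(self) -> list[tuple[str, float]]:
        return [(aa, self.frequencies[aa]) for aa in self.gc_rank]


def translate_cds(seq: str) -> str:
    """Translate an in-frame CDS with the bacterial code.

    Alternative initiator codons are rendered Met; the terminal stop (if any)
    is dropped; an internal stop raises ValueError.
    """
    if len(seq) % 3:
        raise ValueError("CDS length not a multiple of 3")
    codons = [seq[i:i + 3] for i in range(0, len(seq), 3)]
    if codons and GENETIC_CODE.get(codons[-1]) == "*":
        codons = codons[:-1]
    aas = []
    for i, c in enumerate(codons):
        aa = GENETIC_CODE.get(c)
        if aa is None:
            raise ValueError(f"untranslatable codon {c!r} at codon {i}")
        if aa == "*":
            raise ValueError(f"internal stop codon at codon index {i}")
        if i == 0 and c in START_CODONS_T11:
            aa = "M"
        aas.append(aa)
    return "".join(aas)


def aa_profile(cds_set: list[CDSRecord]) -> AAProfile:
    """Amino-acid composition of the proteome, with the GC-richness ranking."""
    counts = {aa: 0 for aa in SYNONYMOUS_FAMILIES}
    for cds in cds_set:
        if not cds.in_frame or cds.n_positions:
            continue
        try:
            prot = translate_cds(cds.sequence)
        except ValueError:
            continue
        for aa in prot:
            counts[aa] += 1
    total = sum(counts.values())
    freqs = {aa: (c / total if total else 0.0) for aa, c in counts.items()}
    return AAProfile(frequencies=freqs, gc_rank=amino_acid_gc_rank(),
                     n_residues=total)
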