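"""Sequence context of indels: homopolymer runs and short microsatellites.

Replication slippage makes mononucleotide runs and short tandem repeats the
dominant substrate for indels in reduced AT-rich genomes.  This module finds
maximal runs/tracts on the given strand and assigns each left-normalized
indel a single context label with precedence
homopolymer > microsatellite > other.
"""

from __future__ import annotations

from dataclasses import dataclass

from .strain_compare import Variant

__all__ = [
    "HomopolymerRun", "MicrosatelliteTract", "IndelContextCall",
    "scan_homopolymers", "scan_microsatellites", "classify_indel_context",
]


@dataclass(frozen=True)
class HomopolymerRun:
    base: str
    start: int      # 0-based
    length: int

    @property
    def end(self) -> int:
        return self.start + self.length


@dataclass(frozen=True)
class MicrosatelliteTract:
    motif: str
    start: int
    copies: int

    @property
    def length(self) -> int:
        return len(self.motif) * self.copies

    @property
    def end(self) -> int:
        return self.start + self.length


@dataclass
class IndelContextCall:
    variant: Variant
    context: str                 # homopolymer | microsatellite | other
    context_base: str | None = None
    motif: str | None = None


def scan_homopolymers(seq: str, min_len: int = 6) -> list[HomopolymerRun]:
    """All maximal single-base runs of length >= min_len, scanned on the
    given strand (no reverse-complement double counting)."""
    if min_len < 2:
        raise ValueError("min_len must be >= 2")
    runs = []
    n = len(seq)
    i = 0
    while i < n:
        j = i + 1
        while j < n and seq[j] == seq[i]:
            j += 1
        if j - i >= min_len and seq[i] in "ACGT":
            runs.append(HomopolymerRun(base=seq[i], start=i, length=j - i))
        i = j
    return runs


def scan_microsatellites(seq: str, motif_len: tuple[int, int] = (2, 8),
                         min_copies: int = 2,
                         min_tract: int = 6) -> list[MicrosatelliteTract]:
    """Maximal tandem tracts of short motifs.

    A tract reportable under several motif lengths is reported once with the
    smallest motif; pure homopolymer stretches are never reported here (they
    belong to :func:`scan_homopolymers`).  A tract qualifies when it has at
    least ``min_copies`` complete copies and spans at least ``min_tract`` bp.
    """
    lo, hi = motif_len
    if lo < 2:
        raise ValueError("motif lengths below 2 are homopolymers")
    n = len(seq)
    tracts: list[MicrosatelliteTract] = []
    claimed: set[tuple[int, int]] = set()   # (start, end) spans already taken
    for ml in range(lo, hi + 1):
        i = 0
        while i + ml <= n:
            motif = seq[i:i + ml]
            if len(set(motif)) == 1 or "N" in motif:
                i += 1
                continue
            # extend tandem copies rightward
            j = i + ml
            while j + ml <= n and seq[j:j + ml] == motif:
                j += ml
            copies = (j - i) // ml
            if copies >= min_copies and copies * ml >= min_tract:
                # smallest-motif precedence: skip if inside a claimed span
                # with a smaller motif (claimed spans were added first)
                span = (i, i + copies * ml)
                inside = any(s <= span[0] and span[1] <= e for s, e in claimed)
                # also skip motifs that are themselves tandem repeats of a
                # smaller unit (e.g. "ATAT" tract already reported as "AT")
                periodic = any(ml % p == 0 and motif == motif[:p] * (ml // p)
                               for p in range(1, ml))
                if not inside and not periodic:
                    tracts.append(MicrosatelliteTract(
                        motif=motif, start=i, copies=copies))
                    claimed.add(span)
                i = j
            else:
                i += 1
    tracts.sort(key=lambda t: (t.start, len(t.motif)))
    return tracts


def _indel_allele_and_pos(variant: Variant) -> tuple[int, str]:
    if variant.vtype == "substitution":
        raise ValueError("context classification applies to indels only")
    return variant.seg_start, variant.allele


def classify_indel_context(variant: Variant,
                           runs: list[HomopolymerRun],
                           tracts: list[MicrosatelliteTract]) -> IndelContextCall:
    """Assign one context label to a left-normalized indel.

    homopolymer: the inserted/deleted bases are all the run's base and the
    event lies inside or immediately abuts a qualifying run.  microsatellite:
    the allele is an integer number of motif copies and the event lies inside
    or abuts a tract.  Everything else: other.  Homopolymer takes precedence.
    """
    p, allele = _indel_allele_and_pos(variant)
    end = p + (len(allele) if variant.vtype == "deletion" else 0)
    for run in runs:
        if set(allele) == {run.base} and p >= run.start - 1 and end <= run.end + 1 \
                and not (end < run.start or p > run.end):
            call = IndelContextCall(variant, "homopolymer", context_base=run.base)
            variant.labels["context"] = "homopolymer"
            variant.labels["context_base"] = run.base
            return call
    for t in tracts:
        ml = len(t.motif)
        if len(allele) % ml == 0 and len(allele) > 0:
            # allele must be a rotation-consistent stack of motif copies
            k = len(allele) // ml
            if t.start <= p <= t.end and end <= t.end + ml:
                rot = t.motif * (k + 1)
                if allele in rot:
                    call = IndelContextCall(variant, "microsatellite", motif=t.motif)
                    variant.labels["context"] = "microsatellite"
                    variant.labels["motif"] = t.motif
                    return call
    variant.labels["context"] = "other"
    return IndelContextCall(variant, "other")


def summarize_contexts(calls: list[IndelContextCall]) -> dict:
    """Counts and percentages of indel contexts, per run base for homopolymers."""
    n = len(calls)
    n_homo = sum(1 for c in calls if c.context == "homopolymer")
    per_base = {}
    for c in calls:
        if c.context == "homopolymer":
            per_base[c.context_base] = per_base.get(c.context_base, 0) + 1
    return {
        "n_indels": n,
        "n_homopolymer": n_homo,
        "n_microsatellite": sum(1 for c in calls if c.context == "microsatellite"),
        "n_other": sum(1 for c in calls if c.context == "other"),
        "homopolymer_percent": round(100.0 * n_homo / n, 1) if n else 0.0,
        "homopolymer_by_base": per_base,
    }
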