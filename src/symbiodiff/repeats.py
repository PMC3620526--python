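"""Exact intragenomic repeat detection: direct/inverted duplications and
regions flanked by inverted-repeat arms.

Detection is k-mer seed-and-extend; the contract is exact output equality
with a quadratic per-diagonal brute force (see symbiodiff.reference), which
the tests enforce on small sequences.  Coordinates are 0-based half-open
internally and 1-based inclusive in report writers.
"""

from __future__ import annotations

from dataclasses import dataclass

from .genome_io import reverse_complement

__all__ = [
    "RepeatPair", "FlankedRegion",
    "find_exact_repeats", "find_ir_flanked_regions",
]


@dataclass(frozen=True)
class RepeatPair:
    """A maximal exact repeat: seq[startA:startA+length] equals
    seq[startB:startB+length] (direct) or its reverse complement (inverted);
    startA < startB."""
    startA: int
    startB: int
    length: int
    orientation: str            # direct | inverted


@dataclass(frozen=True)
class FlankedRegion:
    """Interior region bracketed by a pair of exact inverted-repeat arms."""
    start: int                  # start of interior (end of left arm)
    end: int                    # end of interior (start of right arm)
    arm_length: int
    arm_start_left: int
    arm_start_right: int
    arm_left: str
    arm_right: str

    @property
    def region_length(self) -> int:
        return self.end - self.start


def _seed_matches_direct(seq: str, k: int) -> set[tuple[int, int]]:
    index: dict[str, list[int]] = {}
    for i in range(len(seq) - k + 1):
        index.setdefault(seq[i:i + k], []).append(i)
    pairs = set()
    for positions in index.values():
        if len(positions) < 2:
            continue
        for ai in range(len(positions)):
            for bi in range(ai + 1, len(positions)):
                pairs.add((positions[ai], positions[bi]))
    return pairs


def _extend_direct(seq: str, i: int, j: int, k: int) -> tuple[int, int, int]:
    """Maximal extension of a direct seed match at (i, j)."""
    n = len(seq)
    while i > 0 and j > 0 and seq[i - 1] == seq[j - 1]:
        i -= 1
        j -= 1
    L = k
    while j + L < n and seq[i + L] == seq[j + L]:
        L += 1
    return i, j, L


def find_exact_repeats(seq: str, min_len: int = 1000) -> list[RepeatPair]:
    """All maximal exact repeat pairs >= min_len, direct and inverted.

    Sorted by length descending (ties: by coordinates).  A maximal pair both
    of whose copies lie inside the respective copies of a longer reported
    pair of the same orientation is suppressed as a contained sub-repeat.
    """
    if min_len < 20:
        raise ValueError("min_len must be >= 20")
    seq = seq.upper()
    n = len(seq)
    k = min(min_len, 31)
    found: set[RepeatPair] = set()

    # direct: skip seeds already inside an extended match on their diagonal
    diag_extents: dict[int, list[tuple[int, int]]] = {}
    for i, j in sorted(_seed_matches_direct(seq, k)):
        if i == j:
            continue
        diag = j - i
        if any(s <= i and i + k <= e for s, e in diag_extents.get(diag, ())):
            continue
        mi, mj, L = _extend_direct(seq, i, j, k)
        if mi == mj:
            continue
        diag_extents.setdefault(diag, []).append((mi, mi + L))
        if L >= min_len:
            a, b = (mi, mj) if mi < mj else (mj, mi)
            found.add(RepeatPair(a, b, L, "direct"))

    # inverted: match k-mers against the reverse-complement index
    index: dict[str, list[int]] = {}
    for i in range(n - k + 1):
        index.setdefault(seq[i:i + k], []).append(i)
    anti_extents: dict[int, list[tuple[int, int]]] = {}
    for i in range(n - k + 1):
        rc = reverse_complement(seq[i:i + k])
        for j in index.get(rc, ()):
            anti = i + j + k     # invariant under maximal extension
            if any(s <= i and i + k <= s + L
                   for s, L in anti_extents.get(anti, ())):
                continue
            # seq[i:i+k] == revcomp(seq[j:j+k]); extend outward:
            # left of copy1 pairs with right of copy2 and vice versa
            mi, mj, L = i, j, k
            while mi > 0 and mj + L < n and seq[mi - 1] == _COMP[seq[mj + L]]:
                mi -= 1
                L += 1
            while mi + L < n and mj > 0 and seq[mi + L] == _COMP[seq[mj - 1]]:
                mj -= 1
                L += 1
            anti_extents.setdefault(anti, []).append((mi, L))
            if mi >= mj or mi + L > mj:
                continue    # canonical: copy1 strictly first, no self-overlap
            if L >= min_len:
                found.add(RepeatPair(mi, mj, L, "inverted"))

    pairs = sorted(found, key=lambda p: (-p.length, p.startA, p.startB,
                                         p.orientation))
    kept: list[RepeatPair] = []
    for p in pairs:
        contained = False
        for q in kept:
            if q.orientation == p.orientation and q.length > p.length and \
                    q.startA <= p.startA and p.startA + p.length <= q.startA + q.length and \
                    q.startB <= p.startB and p.startB + p.length <= q.startB + q.length:
                contained = True
                break
        if not contained:
            kept.append(p)
    return kept


_COMP = {"A": "T", "T": "A", "G": "C", "C": "G", "N": "N"}


def find_ir_flanked_regions(seq: str, min_arm: int = 20,
                            max_region: int = 50_000) -> list[FlankedRegion]:
    """Regions bracketed by maximal exact inverted-repeat arms.

    Candidate arm pairs are maximal inverted repeats with arm length >=
    min_arm whose interior span is positive and at most max_region bp.
    Overlapping candidates are resolved longest-arm-first: a region whose
    span overlaps an already accepted region is dropped.
    """
    if min_arm < 20:
        raise ValueError("min_arm must be >= 20")
    seq = seq.upper()
    candidates = []
    for p in find_exact_repeats(seq, min_len=max(20, min_arm)):
        if p.orientation != "inverted" or p.length < min_arm:
            continue
        interior = (p.startA + p.length, p.startB)
        if interior[1] <= interior[0]:
            continue
        if interior[1] - interior[0] > max_region:
            continue
        candidates.append(FlankedRegion(
            start=interior[0], end=interior[1], arm_length=p.length,
            arm_start_left=p.startA, arm_start_right=p.startB,
            arm_left=seq[p.startA:p.startA + p.length],
            arm_right=seq[p.startB:p.startB + p.length]))
    candidates.sort(key=lambda r: (-r.arm_length, r.arm_start_left))
    accepted: list[FlankedRegion] = []
    for r in candidates:
        span = (r.arm_start_left, r.arm_start_right + r.arm_length)
        if any(not (span[1] <= a.arm_start_left
                    or a.arm_start_right + a.arm_length <= span[0])
               for a in accepted):
            continue
        accepted.append(r)
    accepted.sort(key=lambda r: r.arm_start_left)
    return accepted
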