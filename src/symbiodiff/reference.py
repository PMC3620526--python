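"""Naive reference implementations used as independent cross-checks.

Each function here recomputes, by the most transparent method available
(full dynamic programming, explicit enumeration, regular expressions,
per-diagonal scanning), a quantity that the optimized modules compute by
faster means.  They share no code path with the implementations they check:
the genetic code comes from Biopython's table rather than the package's own
map, the aligner is score-only Gotoh over full matrices, and repeat finding
scans every diagonal.  Tests and the acceptance checks compare the two
routes for exact agreement.
"""

from __future__ import annotations

import re

import numpy as np
from Bio.Data import CodonTable

from .repeats import FlankedRegion, RepeatPair

__all__ = [
    "gotoh_score", "ng86_sites", "ng86_differences",
    "regex_homopolymers", "brute_force_repeats", "brute_force_ir_regions",
]

_T11 = CodonTable.unambiguous_dna_by_id[11]


def _aa(codon: str) -> str:
    return "*" if codon in _T11.stop_codons else _T11.forward_table[codon]


# ---------------------------------------------------------------------------
# Full-matrix affine-gap global alignment score (Gotoh), row-vectorized.


def gotoh_score(a: str, b: str, match: int = 1, mismatch: int = -2,
                gap_open: int = 4, gap_ext: int = 1) -> int:
    """Optimal global alignment score; a gap of length L costs open + L*ext."""
    n, m = len(a), len(b)
    if n == 0 or m == 0:
        return 0 if n == m else -(gap_open + max(n, m) * gap_ext)
    NEG = -(10 ** 12)
    ac = np.frombuffer(a.encode(), dtype=np.uint8)
    bc = np.frombuffer(b.encode(), dtype=np.uint8)
    j_idx = np.arange(m + 1, dtype=np.int64)

    prevH = -(gap_open + j_idx * gap_ext)
    prevH[0] = 0
    prevX = np.full(m + 1, NEG, dtype=np.int64)
    for i in range(1, n + 1):
        M = np.full(m + 1, NEG, dtype=np.int64)
        s = np.where(ac[i - 1] == bc, match, mismatch).astype(np.int64)
        M[1:] = prevH[:-1] + s
        X = np.maximum(prevX - gap_ext, prevH - gap_open - gap_ext)
        X[0] = -(gap_open + i * gap_ext)
        W = np.maximum(M, X)
        W[0] = X[0]
        # E[j] = -open - j*ext + max_{j' <= j-1} (W[j'] + j'*ext)
        running = np.maximum.accumulate(W + j_idx * gap_ext)
        E = np.full(m + 1, NEG, dtype=np.int64)
        E[1:] = running[:-1] - gap_open - j_idx[1:] * gap_ext
        prevH = np.maximum(W, E)
        prevX = X
    return int(prevH[m])


# ---------------------------------------------------------------------------
# NG86 by explicit enumeration (Biopython's genetic code).


def ng86_sites(codon: str) -> tuple[float, float]:
    """Synonymous/non-synonymous site counts by per-position enumeration."""
    aa = _aa(codon)
    if aa == "*":
        raise ValueError("stop codon")
    s = 0.0
    for i in range(3):
        outcomes = []
        for base in "ACGT":
            if base == codon[i]:
                continue
            mutated = codon[:i] + base + codon[i + 1:]
            if _aa(mutated) != "*":
                outcomes.append(_aa(mutated) == aa)
        if outcomes:
            s += sum(outcomes) / len(outcomes)
    return s, 3.0 - s


def ng86_differences(codon_a: str, codon_b: str) -> tuple[float, float] | None:
    """Pathway-averaged difference counts by recursive enumeration."""
    results: list[tuple[int, int]] = []

    def walk(cur: str, sd: int, nd: int) -> None:
        if cur == codon_b:
            results.append((sd, nd))
            return
        for i in range(3):
            if cur[i] != codon_b[i]:
                nxt = cur[:i] + codon_b[i] + cur[i + 1:]
                if _aa(nxt) == "*":
                    continue
                if _aa(nxt) == _aa(cur):
                    walk(nxt, sd + 1, nd)
                else:
                    walk(nxt, sd, nd + 1)

    walk(codon_a, 0, 0)
    if not results:
        return None if codon_a != codon_b else (0.0, 0.0)
    return (sum(r[0] for r in results) / len(results),
            sum(r[1] for r in results) / len(results))


# ---------------------------------------------------------------------------
# Homopolymers by regular expression.


def regex_homopolymers(seq: str, min_len: int = 6) -> list[tuple[str, int, int]]:
    """Maximal runs >= min_len as (base, start, length) via backreference."""
    out = []
    for m in re.finditer(r"([ACGT])\1{" + str(min_len - 1) + r",}", seq):
        out.append((m.group(1), m.start(), m.end() - m.start()))
    return out


# ---------------------------------------------------------------------------
# Repeats by per-diagonal scanning.


def _maximal_runs(eq: np.ndarray, min_len: int) -> list[tuple[int, int]]:
    """(start, length) of maximal True-runs of length >= min_len."""
    if not eq.any():
        return []
    padded = np.concatenate(([False], eq, [False]))
    d = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    return [(int(s), int(e - s)) for s, e in zip(starts, ends) if e - s >= min_len]


_COMP = str.maketrans("ACGTN", "TGCAN")


def brute_force_repeats(seq: str, min_len: int) -> list[RepeatPair]:
    """Every maximal exact repeat pair >= min_len by scanning all diagonals.

    Same semantics as repeats.find_exact_repeats: direct pairs with
    startA < startB; inverted pairs canonicalized with the left copy
    strictly first and no self-overlap; contained sub-pairs of a longer
    reported pair (same orientation) suppressed; sorted length-descending.
    """
    seq = seq.upper()
    n = len(seq)
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    rc = np.frombuffer(seq.translate(_COMP)[::-1].encode(), dtype=np.uint8)
    found: list[RepeatPair] = []

    for d in range(1, n):
        eq = arr[:n - d] == arr[d:]
        for s, L in _maximal_runs(eq, min_len):
            found.append(RepeatPair(s, s + d, L, "direct"))

    # inverted: compare seq against its reverse complement R, where
    # R[p] = comp(seq[n-1-p]); a match run seq[i:i+L] == R[i+c:i+c+L] is the
    # inverted pair (i, j, L) with j = n - (i + c) - L.
    for c in range(-(n - 1), n):
        i_lo, i_hi = max(0, -c), min(n, n - c)
        if i_hi - i_lo < min_len:
            continue
        eq = arr[i_lo:i_hi] == rc[i_lo + c:i_hi + c]
        for s, L in _maximal_runs(eq, min_len):
            i = i_lo + s
            j = n - (i + c) - L
            if i < j and i + L <= j:
                found.append(RepeatPair(i, j, L, "inverted"))

    found.sort(key=lambda r: (-r.length, r.startA, r.startB, r.orientation))
    kept: list[RepeatPair] = []
    for pr in found:
        contained = False
        for q in kept:
            if q.orientation == pr.orientation and q.length > pr.length and \
                    q.startA <= pr.startA and \
                    pr.startA + pr.length <= q.startA + q.length and \
                    q.startB <= pr.startB and \
                    pr.startB + pr.length <= q.startB + q.length:
                contained = True
                break
        if not contained:
            kept.append(pr)
    return kept


def brute_force_ir_regions(seq: str, min_arm: int,
                           max_region: int) -> list[FlankedRegion]:
    """IR-flanked regions from the brute-force inverted pair list, applying
    the same longest-arm-first overlap resolution as the main implementation."""
    seq = seq.upper()
    candidates = []
    for p in brute_force_repeats(seq, min_len=max(20, min_arm)):
        if p.orientation != "inverted" or p.length < min_arm:
            continue
        start, end = p.startA + p.length, p.startB
        if end <= start or end - start > max_region:
            continue
        candidates.append(FlankedRegion(
            start=start, end=end, arm_length=p.length,
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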