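"""Whole-genome alignment of near-identical strain pairs and variant calling.

Two genomes of the same bacterial strain lineage differ by a handful of
substitutions and short indels.  Rather than running a general multiple
aligner, we chain maximal *unique* shared k-mer matches (anchors) and close
the short inter-anchor gaps with an exact affine-gap global alignment
(match +1, mismatch -2, gap open -4, gap extend -1; a gap of length L costs
open + L*extend).  The result is a full end-to-end column map of both
genomes, from which variants are called, left-normalized VCF-style and
classified by mutational class, direction, and genomic partition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genome_io import GenomePartition, GenomeRecord

try:
    from numba import njit
    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a hard dependency in practice
    _HAVE_NUMBA = False

    def njit(*a, **k):
        def wrap(f):
            return f
        return wrap(a[0]) if a and callable(a[0]) else wrap

__all__ = [
    "AlignmentMap", "Variant", "VariantSummary", "NotCollinearError",
    "align_strain_pair", "call_variants", "classify_variants",
    "apply_variants", "score_alignment", "left_normalize",
    "MATCH", "MISMATCH", "GAP_OPEN", "GAP_EXTEND",
]

MATCH = 1
MISMATCH = -2
GAP_OPEN = 4     # charged once per gap run, on top of per-base extension
GAP_EXTEND = 1

_MAX_DP_CELLS = 120_000_000  # guard for inter-anchor segments


class NotCollinearError(ValueError):
    """The two genomes share no usable co-linear anchor chain."""


@dataclass
class AlignmentMap:
    """End-to-end pairwise alignment as parallel position arrays.

    ``a_pos``/``b_pos`` have one entry per alignment column; the entry is the
    0-based position consumed in that genome, or -1 when the column is a gap
    in that genome.  Every position of both genomes appears exactly once.
    """

    a_pos: np.ndarray
    b_pos: np.ndarray
    identical_positions: int
    n_columns: int

    @property
    def identity_percent(self) -> float:
        return 100.0 * self.identical_positions / self.n_columns


@dataclass
class Variant:
    """One normalized difference between strain A (ref) and strain B (alt).

    ``pos`` is 0-based on genome A.  Substitutions carry single-base ref/alt.
    Indels are VCF-style: anchored on the base preceding the event after
    left-normalization (or on the following base when the event abuts the
    sequence start), so both alleles are non-empty.
    """

    vtype: str                   # substitution | insertion | deletion
    pos: int
    ref: str
    alt: str
    length: int
    labels: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.vtype == "substitution":
            if len(self.ref) != 1 or len(self.alt) != 1 or self.ref == self.alt:
                raise ValueError("substitution needs distinct single-base alleles")
        else:
            if not self.ref or not self.alt:
                raise ValueError("indel alleles must be non-empty")

    @property
    def left_anchored(self) -> bool:
        return self.ref[0] == self.alt[0]

    @property
    def seg_start(self) -> int:
        """Start (0-based, genome A) of the inserted/deleted segment."""
        if self.vtype == "substitution":
            return self.pos
        return self.pos + 1 if self.left_anchored else self.pos

    @property
    def allele(self) -> str:
        """The inserted or deleted bases themselves."""
        if self.vtype == "substitution":
            return self.alt
        longer = self.ref if self.vtype == "deletion" else self.alt
        return longer[1:] if self.left_anchored else longer[:-1]


# ---------------------------------------------------------------------------
# Affine-gap global alignment (Gotoh) with traceback, for gap closure.
# States: 0 = M (diagonal), 1 = X (gap in B, consumes A), 2 = E (gap in A).

_NEG = -(10 ** 15)


@njit(cache=False)
def _gotoh_core(a, b, match, mismatch, gap_open, gap_ext):  # pragma: no cover
    n = a.shape[0]
    m = b.shape[0]
    ptrH = np.zeros((n + 1, m + 1), dtype=np.uint8)
    ptrX = np.zeros((n + 1, m + 1), dtype=np.uint8)  # 0 = opened, 1 = extended
    ptrE = np.zeros((n + 1, m + 1), dtype=np.uint8)

    prevM = np.full(m + 1, _NEG, dtype=np.int64)
    prevX = np.full(m + 1, _NEG, dtype=np.int64)
    prevE = np.full(m + 1, _NEG, dtype=np.int64)
    prevH = np.full(m + 1, _NEG, dtype=np.int64)
    prevH[0] = 0
    for j in range(1, m + 1):
        prevE[j] = -(gap_open + j * gap_ext)
        prevH[j] = prevE[j]
        ptrH[0, j] = 2
        ptrE[0, j] = 1 if j > 1 else 0

    curM = np.empty(m + 1, dtype=np.int64)
    curX = np.empty(m + 1, dtype=np.int64)
    curE = np.empty(m + 1, dtype=np.int64)
    curH = np.empty(m + 1, dtype=np.int64)

    for i in range(1, n + 1):
        curM[0] = _NEG
        curE[0] = _NEG
        curX[0] = -(gap_open + i * gap_ext)
        curH[0] = curX[0]
        ptrH[i, 0] = 1
        ptrX[i, 0] = 1 if i > 1 else 0
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            curM[j] = prevH[j - 1] + s

            x_open = prevH[j] - gap_open - gap_ext
            x_ext = prevX[j] - gap_ext
            if x_ext >= x_open:
                curX[j] = x_ext
                ptrX[i, j] = 1
            else:
                curX[j] = x_open
                ptrX[i, j] = 0

            e_open = curH[j - 1] - gap_open - gap_ext
            e_ext = curE[j - 1] - gap_ext
            if e_ext >= e_open:
                curE[j] = e_ext
                ptrE[i, j] = 1
            else:
                curE[j] = e_open
                ptrE[i, j] = 0

            h = curM[j]
            st = 0
            if curX[j] > h:
                h = curX[j]
                st = 1
            if curE[j] > h:
                h = curE[j]
                st = 2
            curH[j] = h
            ptrH[i, j] = st
        prevM, curM = curM, prevM
        prevX, curX = curX, prevX
        prevE, curE = curE, prevE
        prevH, curH = curH, prevH

    return prevH[m], ptrH, ptrX, ptrE


def _gotoh_align(a: str, b: str) -> tuple[int, list[tuple[int, int]]]:
    """Optimal global alignment of two short segments.

    Returns (score, columns) with columns as (i, j) pairs, -1 for gaps;
    indices are local to the segments.
    """
    n, m = len(a), len(b)
    if n == 0 and m == 0:
        return 0, []
    if n == 0:
        return -(GAP_OPEN + m * GAP_EXTEND), [(-1, j) for j in range(m)]
    if m == 0:
        return -(GAP_OPEN + n * GAP_EXTEND), [(i, -1) for i in range(n)]
    if n * m > _MAX_DP_CELLS:
        raise NotCollinearError(
            f"inter-anchor segment of {n} x {m} bp is too large to align; "
            "the genomes are likely rearranged or too divergent")
    ac = np.frombuffer(a.encode(), dtype=np.uint8)
    bc = np.frombuffer(b.encode(), dtype=np.uint8)
    score, ptrH, ptrX, ptrE = _gotoh_core(
        ac, bc, MATCH, MISMATCH, GAP_OPEN, GAP_EXTEND)

    cols: list[tuple[int, int]] = []
    i, j = n, m
    state = ptrH[i, j]
    while i > 0 or j > 0:
        if state == 0:
            cols.append((i - 1, j - 1))
            i -= 1
            j -= 1
            state = ptrH[i, j]
        elif state == 1:
            cols.append((i - 1, -1))
            opened = ptrX[i, j] == 0
            i -= 1
            state = ptrH[i, j] if opened else 1
        else:
            cols.append((-1, j - 1))
            opened = ptrE[i, j] == 0
            j -= 1
            state = ptrH[i, j] if opened else 2
    cols.reverse()
    return int(score), cols


# ---------------------------------------------------------------------------
# Anchoring


def _unique_kmer_positions(seq: str, k: int) -> dict[str, int]:
    seen: dict[str, int] = {}
    dup: set[str] = set()
    for i in range(len(seq) - k + 1):
        km = seq[i:i + k]
        if km in dup:
            continue
        if km in seen:
            del seen[km]
            dup.add(km)
        else:
            seen[km] = i
    return seen


def _shared_anchors(a: str, b: str, k: int) -> list[tuple[int, int, int]]:
    """Maximal runs of co-diagonal unique shared k-mers as (pa, pb, length)."""
    ua = _unique_kmer_positions(a, k)
    ub = _unique_kmer_positions(b, k)
    matches = [(pa, ub[km]) for km, pa in ua.items() if km in ub]
    if not matches:
        return []
    by_diag: dict[int, list[int]] = {}
    for pa, pb in matches:
        by_diag.setdefault(pb - pa, []).append(pa)
    anchors = []
    for diag, pas in by_diag.items():
        pas.sort()
        start = prev_end = None
        for pa in pas:
            if start is None:
                start, prev_end = pa, pa + k
            elif pa <= prev_end:  # overlapping/adjacent on same diagonal
                prev_end = max(prev_end, pa + k)
            else:
                anchors.append((start, start + diag, prev_end - start))
                start, prev_end = pa, pa + k
        anchors.append((start, start + diag, prev_end - start))
    return anchors


def _chain_anchors(anchors: list[tuple[int, int, int]]) -> list[tuple[int, int, int]]:
    """Greedy co-linear chaining: longest anchors first, leftmost on ties.

    Two maximal anchors flanking an indel can overlap by a few bases on
    different diagonals (the flanking sequence matches on both); such
    candidates are trimmed to fit between their accepted neighbours rather
    than rejected, so the chain never leaves spurious giant gaps.
    """
    order = sorted(anchors, key=lambda t: (-t[2], t[0]))
    accepted: list[tuple[int, int, int]] = []  # kept sorted by pa
    import bisect
    for pa, pb, ln in order:
        idx = bisect.bisect_left(accepted, (pa, pb, ln))
        if idx > 0:
            qa, qb, ql = accepted[idx - 1]
            d = max(qa + ql - pa, qb + ql - pb, 0)
            pa += d
            pb += d
            ln -= d
        if idx < len(accepted) and ln > 0:
            qa, qb, ql = accepted[idx]
            d = max(pa + ln - qa, pb + ln - qb, 0)
            ln -= d
        if ln > 0:
            accepted.insert(idx, (pa, pb, ln))
    return accepted


def align_strain_pair(a: GenomeRecord | str, b: GenomeRecord | str,
                      k: int = 31) -> AlignmentMap:
    """Align two near-identical genomes end to end.

    Anchors are maximal runs of k-mers unique in both genomes; they are
    chained co-linearly (longest first) and the inter-anchor gaps are closed
    by exact affine-gap global alignment.  Raises NotCollinearError when no
    usable chain exists (e.g. rearranged genomes) rather than returning a
    silent partial alignment.
    """
    sa = a.sequence if isinstance(a, GenomeRecord) else a.upper()
    sb = b.sequence if isinstance(b, GenomeRecord) else b.upper()

    chain = _chain_anchors(_shared_anchors(sa, sb, k)) if (
        len(sa) >= k and len(sb) >= k) else []
    if not chain:
        if len(sa) * len(sb) > _MAX_DP_CELLS:
            raise NotCollinearError(
                "no shared unique anchors between genomes of "
                f"{len(sa)} and {len(sb)} bp; cannot align")
        chain = []
    else:
        covered = sum(ln for _, _, ln in chain)
        if covered < 0.5 * min(len(sa), len(sb)) and min(len(sa), len(sb)) > 10_000:
            raise NotCollinearError(
                "anchor chain covers only "
                f"{covered} of {min(len(sa), len(sb))} bp; genomes appear "
                "rearranged — refusing a partial alignment")

    a_cols: list[int] = []
    b_cols: list[int] = []

    def close_gap(a0, a1, b0, b1):
        _, cols = _gotoh_align(sa[a0:a1], sb[b0:b1])
        for ia, ib in cols:
            a_cols.append(a0 + ia if ia >= 0 else -1)
            b_cols.append(b0 + ib if ib >= 0 else -1)

    pa_prev = pb_prev = 0
    for pa, pb, ln in chain:
        close_gap(pa_prev, pa, pb_prev, pb)
        a_cols.extend(range(pa, pa + ln))
        b_cols.extend(range(pb, pb + ln))
        pa_prev, pb_prev = pa + ln, pb + ln
    close_gap(pa_prev, len(sa), pb_prev, len(sb))

    ap = np.array(a_cols, dtype=np.int64)
    bp = np.array(b_cols, dtype=np.int64)
    both = (ap >= 0) & (bp >= 0)
    aa = np.frombuffer(sa.encode(), dtype=np.uint8)
    bb = np.frombuffer(sb.encode(), dtype=np.uint8)
    eq = np.zeros(len(ap), dtype=bool)
    eq[both] = aa[ap[both]] == bb[bp[both]]
    not_n = np.ones(len(ap), dtype=bool)
    n_code = ord("N")
    not_n[both] = (aa[ap[both]] != n_code) & (bb[bp[both]] != n_code)
    identical = int((eq & not_n).sum())
    return AlignmentMap(a_pos=ap, b_pos=bp, identical_positions=identical,
                        n_columns=len(ap))


def score_alignment(amap: AlignmentMap, a: str, b: str) -> int:
    """Affine-gap score of an alignment map under the package's scheme."""
    score = 0
    prev_gap = None  # 'a' or 'b' gap run currently open
    for ia, ib in zip(amap.a_pos.tolist(), amap.b_pos.tolist()):
        if ia >= 0 and ib >= 0:
            score += MATCH if a[ia] == b[ib] else MISMATCH
            prev_gap = None
        else:
            side = "a" if ia < 0 else "b"
            if side != prev_gap:
                score -= GAP_OPEN
                prev_gap = side
            score -= GAP_EXTEND
    return score


# ---------------------------------------------------------------------------
# Variant calling


def left_normalize(seq_a: str, seg_start: int, allele: str) -> tuple[int, str]:
    """Shift an indel to its lowest equivalent position on genome A.

    ``seg_start`` is the 0-based start of the inserted/deleted segment
    (insertions sit *before* that position); the placement is equivalent
    after shifting one left whenever the base preceding the segment equals
    the allele's last base.
    """
    p, al = seg_start, allele
    while p > 0 and al and seq_a[p - 1] == al[-1]:
        al = seq_a[p - 1] + al[:-1]
        p -= 1
    return p, al


def _anchored(vtype: str, seq_a: str, p: int, allele: str) -> Variant:
    if p > 0:
        anchor = seq_a[p - 1]
        if vtype == "deletion":
            ref, alt = anchor + allele, anchor
        else:
            ref, alt = anchor, anchor + allele
        pos = p - 1
    else:  # event at the very start: anchor on the following base
        nxt = seq_a[len(allele)] if vtype == "deletion" else seq_a[0]
        if vtype == "deletion":
            ref, alt = allele + nxt, nxt
        else:
            ref, alt = nxt, allele + nxt
        pos = 0
    return Variant(vtype=vtype, pos=pos, ref=ref, alt=alt, length=len(allele))


def call_variants(amap: AlignmentMap, a: GenomeRecord | str,
                  b: GenomeRecord | str) -> list[Variant]:
    """Call substitutions and left-normalized indels from an alignment map.

    Consecutive gap columns on the same side merge into one indel event; a
    run mixing both sides is split into separate insertion and deletion
    events at the boundary.  Columns containing N never yield substitutions.
    """
    sa = a.sequence if isinstance(a, GenomeRecord) else a.upper()
    sb = b.sequence if isinstance(b, GenomeRecord) else b.upper()
    ap, bp = amap.a_pos, amap.b_pos
    variants: list[Variant] = []

    both = (ap >= 0) & (bp >= 0)
    aa = np.frombuffer(sa.encode(), dtype=np.uint8)
    bb = np.frombuffer(sb.encode(), dtype=np.uint8)
    sub_mask = np.zeros(len(ap), dtype=bool)
    sub_mask[both] = (aa[ap[both]] != bb[bp[both]]) \
        & (aa[ap[both]] != ord("N")) & (bb[bp[both]] != ord("N"))
    for c in np.flatnonzero(sub_mask).tolist():
        variants.append(Variant(
            vtype="substitution", pos=int(ap[c]),
            ref=sa[ap[c]], alt=sb[bp[c]], length=1))

    # indel runs: group consecutive columns gapped on the same side
    gap_side = np.where(ap < 0, 1, np.where(bp < 0, 2, 0)).astype(np.int8)
    c = 0
    ncol = len(ap)
    while c < ncol:
        side = gap_side[c]
        if side == 0:
            c += 1
            continue
        start = c
        while c < ncol and gap_side[c] == side:
            c += 1
        if side == 2:  # gap in B -> deletion of A bases
            seg = sa[ap[start]:ap[c - 1] + 1]
            p0 = int(ap[start])
            vtype = "deletion"
        else:          # gap in A -> insertion of B bases
            seg = sb[bp[start]:bp[c - 1] + 1]
            # insertion sits before the next A position consumed to the right
            later = ap[c:]
            nz = later[later >= 0]
            p0 = int(nz[0]) if len(nz) else len(sa)
            vtype = "insertion"
        p, allele = left_normalize(sa, p0, seg)
        variants.append(_anchored(vtype, sa, p, allele))

    variants.sort(key=lambda v: (v.seg_start, v.vtype))
    return variants


def apply_variants(seq_a: str, variants: list[Variant]) -> str:
    """Reconstruct genome B by applying called variants to genome A."""
    events = sorted(variants, key=lambda v: v.seg_start)
    out = []
    cursor = 0
    for v in events:
        s = v.seg_start
        if s < cursor:
            raise ValueError(f"overlapping variants at {s}")
        out.append(seq_a[cursor:s])
        if v.vtype == "substitution":
            out.append(v.alt)
            cursor = s + 1
        elif v.vtype == "deletion":
            cursor = s + v.length
        else:
            out.append(v.allele)
            cursor = s
    out.append(seq_a[cursor:])
    return "".join(out)


# ---------------------------------------------------------------------------
# Classification

_PURINES = frozenset("AG")
_GC = frozenset("GC")
_AT = frozenset("AT")

DIRECTION_CLASSES = ("GCtoAT", "ATtoGC", "AtoT_or_TtoA", "GtoC_or_CtoG")


def _direction(ref: str, alt: str) -> tuple[str, str]:
    """(direction class, AT-gaining strain) for a substitution A:ref -> B:alt."""
    if ref in _GC and alt in _AT:
        return "GCtoAT", "B"
    if ref in _AT and alt in _GC:
        return "ATtoGC", "A"
    if ref in _AT:
        return "AtoT_or_TtoA", "neither"
    return "GtoC_or_CtoG", "neither"


def is_transition(ref: str, alt: str) -> bool:
    return (ref in _PURINES) == (alt in _PURINES)


@dataclass
class VariantSummary:
    n_substitutions: int
    n_insertions: int
    n_deletions: int
    ti: int
    tv: int
    direction_counts: dict[str, int]
    partition_counts: dict[str, dict[str, int]]   # vclass -> partition -> n
    at_gain_counts: dict[str, int]                # strain -> n (GC<->AT only)
    indel_sizes: list[int]

    @property
    def ti_fraction(self) -> float:
        return self.ti / self.n_substitutions if self.n_substitutions else 0.0

    @property
    def gc_at_changes(self) -> int:
        return self.direction_counts["GCtoAT"] + self.direction_counts["ATtoGC"]

    @property
    def gc_at_percent(self) -> float:
        return (100.0 * self.gc_at_changes / self.n_substitutions
                if self.n_substitutions else 0.0)

    def at_gain_percent(self, strain: str) -> float:
        tot = self.gc_at_changes
        return 100.0 * self.at_gain_counts.get(strain, 0) / tot if tot else 0.0

    @property
    def mean_indel_size(self) -> float:
        return float(np.mean(self.indel_sizes)) if self.indel_sizes else 0.0

    def as_dict(self) -> dict:
        return {
            "n_substitutions": self.n_substitutions,
            "n_insertions": self.n_insertions,
            "n_deletions": self.n_deletions,
            "n_indels": self.n_insertions + self.n_deletions,
            "transitions": self.ti,
            "transversions": self.tv,
            "ti_percent": round(100 * self.ti_fraction, 1),
            "direction_counts": dict(self.direction_counts),
            "gc_at_percent": round(self.gc_at_percent, 1),
            "at_gain_percent_A": round(self.at_gain_percent("A"), 1),
            "at_gain_percent_B": round(self.at_gain_percent("B"), 1),
            "partition_counts": {k: dict(v) for k, v in self.partition_counts.items()},
            "mean_indel_size": round(self.mean_indel_size, 1),
        }


def classify_variants(variants: list[Variant],
                      partition_a: GenomePartition) -> VariantSummary:
    """Label every variant and aggregate the mutational-class summary.

    Substitutions get ti/tv and direction labels (direction read A -> B, the
    AT-receiving strain recorded); all variants get the partition class of
    their position on genome A.  Labels are written into each variant's
    ``labels`` dict in place and tallied.
    """
    dir_counts = {d: 0 for d in DIRECTION_CLASSES}
    part_counts: dict[str, dict[str, int]] = {
        "substitution": {}, "insertion": {}, "deletion": {}}
    at_gain = {"A": 0, "B": 0, "neither": 0}
    ti = tv = 0
    sizes = []
    n_sub = n_ins = n_del = 0
    glen = len(partition_a.classes)
    for v in variants:
        p = min(v.seg_start, glen - 1)
        pclass = partition_a.class_at(p)
        v.labels["partition"] = pclass
        part_counts[v.vtype][pclass] = part_counts[v.vtype].get(pclass, 0) + 1
        if v.vtype == "substitution":
            n_sub += 1
            if is_transition(v.ref, v.alt):
                ti += 1
                v.labels["titv"] = "ti"
            else:
                tv += 1
                v.labels["titv"] = "tv"
            d, gainer = _direction(v.ref, v.alt)
            v.labels["direction"] = d
            v.labels["at_gaining_strain"] = gainer
            dir_counts[d] += 1
            at_gain[gainer] += 1
        else:
            sizes.append(v.length)
            if v.vtype == "insertion":
                n_ins += 1
            else:
                n_del += 1
    return VariantSummary(
        n_substitutions=n_sub, n_insertions=n_ins, n_deletions=n_del,
        ti=ti, tv=tv, direction_counts=dir_counts,
        partition_counts=part_counts,
        at_gain_counts={"A": at_gain["A"], "B": at_gain["B"]},
        indel_sizes=sizes)
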