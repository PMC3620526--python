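"""Synonymous/non-synonymous divergence by the Nei-Gojobori (1986) method.

Sites: each codon position contributes a synonymous-site fraction equal to
the share of its possible single-base changes that are synonymous, with
changes creating stop codons excluded from both numerator and denominator;
site totals are averaged over the two sequences.  Differences: codon pairs
differing at d positions are scored by averaging synonymous/non-synonymous
step counts over all d! minimal mutational pathways that avoid stop codons.
Proportions are Jukes-Cantor corrected, d = -(3/4) ln(1 - 4p/3), and
omega = dN/dS.  Standard errors come from a seeded codon-column bootstrap.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from .genome_io import CDSRecord
from .genome_profile import GENETIC_CODE

__all__ = [
    "CodonAlignment", "SelectionSummary",
    "pair_orthologs", "count_sites_ng86", "count_differences_ng86",
    "estimate_dnds", "jukes_cantor",
]

_BASES = "ACGT"


@dataclass
class CodonAlignment:
    """Gap-free paired codon columns from one ortholog CDS pair."""
    gene: str
    codons_a: list[str]
    codons_b: list[str]
    n_dropped: int = 0          # columns removed (gaps or N)

    def __post_init__(self) -> None:
        if len(self.codons_a) != len(self.codons_b):
            raise ValueError(f"{self.gene}: unequal codon counts")


@dataclass
class SelectionSummary:
    Sd: float
    Nd: float
    S: float
    N: float
    pS: float
    pN: float
    dS: float
    dN: float
    dS_se: float | None
    dN_se: float | None
    omega: float | None          # None when dS == 0 (undefined)
    n_codons: int
    skipped_codons: int = 0      # pairs whose every pathway crossed a stop
    per_gene: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "Sd": round(self.Sd, 4), "Nd": round(self.Nd, 4),
            "S": round(self.S, 2), "N": round(self.N, 2),
            "pS": self.pS, "pN": self.pN,
            "dS": round(self.dS, 4), "dN": round(self.dN, 4),
            "dS_se": None if self.dS_se is None else round(self.dS_se, 4),
            "dN_se": None if self.dN_se is None else round(self.dN_se, 4),
            "omega": None if self.omega is None else round(self.omega, 2),
            "n_codons": self.n_codons,
        }


class JukesCantorError(ValueError):
    """p >= 3/4: the Jukes-Cantor correction is undefined."""


def jukes_cantor(p: float) -> float:
    if p >= 0.75:
        raise JukesCantorError(
            f"proportion {p:.4f} >= 0.75; Jukes-Cantor distance undefined")
    return -0.75 * np.log(1.0 - 4.0 * p / 3.0)


@lru_cache(maxsize=None)
def count_sites_ng86(codon: str) -> tuple[float, float]:
    """(synonymous, non-synonymous) site counts of one codon.

    Per position, the synonymous fraction is (synonymous non-stop changes) /
    (non-stop changes); mutations to stop codons do not count as sites.
    s + n = 3 exactly.
    """
    aa = GENETIC_CODE.get(codon)
    if aa is None:
        raise ValueError(f"invalid codon {codon!r}")
    if aa == "*":
        raise ValueError(f"stop codon {codon!r} has no NG86 sites")
    s = 0.0
    for i in range(3):
        syn = 0
        valid = 0
        for b in _BASES:
            if b == codon[i]:
                continue
            alt = codon[:i] + b + codon[i + 1:]
            alt_aa = GENETIC_CODE[alt]
            if alt_aa == "*":
                continue
            valid += 1
            if alt_aa == aa:
                syn += 1
        if valid:
            s += syn / valid
    return s, 3.0 - s


@lru_cache(maxsize=None)
def count_differences_ng86(codon_a: str, codon_b: str) -> tuple[float, float] | None:
    """(synonymous, non-synonymous) difference counts between two codons.

    Averages over all minimal mutational pathways that avoid stop codons at
    every intermediate (and terminal) step.  Returns None when every pathway
    passes through a stop codon — callers should skip and report the pair.
    """
    if GENETIC_CODE[codon_a] == "*" or GENETIC_CODE[codon_b] == "*":
        raise ValueError("stop codons cannot be compared")
    diff_pos = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff_pos:
        return 0.0, 0.0
    paths = []
    for order in itertools.permutations(diff_pos):
        cur = codon_a
        sd = nd = 0
        ok = True
        for i in order:
            nxt = cur[:i] + codon_b[i] + cur[i + 1:]
            if GENETIC_CODE[nxt] == "*":
                ok = False
                break
            if GENETIC_CODE[nxt] == GENETIC_CODE[cur]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        if ok:
            paths.append((sd, nd))
    if not paths:
        return None
    sd = sum(p[0] for p in paths) / len(paths)
    nd = sum(p[1] for p in paths) / len(paths)
    return sd, nd


# ---------------------------------------------------------------------------
# Ortholog pairing


def pair_orthologs(cds_a: list[CDSRecord], cds_b: list[CDSRecord],
                   ) -> tuple[list[CodonAlignment], list[str]]:
    """Match CDS sets by gene name and codon-align each retained pair.

    Length-mismatched pairs are aligned allowing only frame-preserving
    (multiple-of-3) end/indel gaps via a simple anchored codon alignment;
    codon columns containing a gap or N are dropped and counted.  Returns
    (alignments, unmatched gene names).  Duplicate names raise ValueError.
    """
    def index(cds_set, label):
        idx = {}
        dups = []
        for c in cds_set:
            if c.name in idx:
                dups.append(c.name)
            idx[c.name] = c
        if dups:
            raise ValueError(f"duplicate gene names in {label}: {sorted(set(dups))}")
        return idx

    ia, ib = index(cds_a, "set A"), index(cds_b, "set B")
    unmatched = sorted(set(ia) ^ set(ib))
    alignments = []
    for name in sorted(set(ia) & set(ib)):
        a, b = ia[name], ib[name]
        if not (a.in_frame and b.in_frame):
            continue
        ca = [a.sequence[i:i + 3] for i in range(0, len(a.sequence), 3)]
        cb = [b.sequence[i:i + 3] for i in range(0, len(b.sequence), 3)]
        if len(ca) == len(cb):
            pairs = list(zip(ca, cb))
        else:
            pairs = _codon_align(ca, cb)
        clean_a, clean_b, dropped = [], [], 0
        for x, y in pairs:
            if x is None or y is None or "N" in x or "N" in y \
                    or GENETIC_CODE[x] == "*" or GENETIC_CODE[y] == "*":
                dropped += 1
                continue
            clean_a.append(x)
            clean_b.append(y)
        if clean_a:
            alignments.append(CodonAlignment(
                gene=name, codons_a=clean_a, codons_b=clean_b,
                n_dropped=dropped))
    return alignments, unmatched


def _codon_align(ca: list[str], cb: list[str]) -> list[tuple[str | None, str | None]]:
    """Anchor-based codon alignment for length-mismatched ortholog pairs.

    Greedy longest-common-prefix/suffix with a middle gap: adequate for
    strain pairs whose indels are few and frame-preserving; columns inside
    the unanchored middle are gapped out rather than force-paired.
    """
    pre = 0
    while pre < min(len(ca), len(cb)) and ca[pre] == cb[pre]:
        pre += 1
    suf = 0
    while (suf < min(len(ca), len(cb)) - pre
           and ca[len(ca) - 1 - suf] == cb[len(cb) - 1 - suf]):
        suf += 1
    pairs: list[tuple[str | None, str | None]] = []
    pairs.extend(zip(ca[:pre], cb[:pre]))
    mid_a = ca[pre:len(ca) - suf]
    mid_b = cb[pre:len(cb) - suf]
    # pair the overlap of the middle only when lengths agree; otherwise gap
    if len(mid_a) == len(mid_b):
        pairs.extend(zip(mid_a, mid_b))
    else:
        pairs.extend((x, None) for x in mid_a)
        pairs.extend((None, y) for y in mid_b)
    pairs.extend(zip(ca[len(ca) - suf:], cb[len(cb) - suf:]))
    return pairs


# ---------------------------------------------------------------------------
# dN/dS estimation


def _tally(codons_a: list[str], codons_b: list[str]) -> tuple[float, float, float, float, int]:
    S = N = Sd = Nd = 0.0
    skipped = 0
    for x, y in zip(codons_a, codons_b):
        d = count_differences_ng86(x, y)
        if d is None:
            skipped += 1
            continue
        sx, nx = count_sites_ng86(x)
        sy, ny = count_sites_ng86(y)
        S += (sx + sy) / 2
        N += (nx + ny) / 2
        Sd += d[0]
        Nd += d[1]
    return S, N, Sd, Nd, skipped


def estimate_dnds(alignments: list[CodonAlignment],
                  bootstrap_reps: int = 1000,
                  seed: int = 0,
                  per_gene: bool = False) -> SelectionSummary:
    """NG86 dS/dN/omega over concatenated ortholog codon alignments.

    Codon columns are pooled across genes (concatenation); standard errors by
    bootstrap resampling of codon columns with a fixed seed.  omega is None
    (undefined) when dS = 0.
    """
    all_a = [c for al in alignments for c in al.codons_a]
    all_b = [c for al in alignments for c in al.codons_b]
    if not all_a:
        raise ValueError("no codon columns to analyse")
    S, N, Sd, Nd, skipped = _tally(all_a, all_b)
    pS = Sd / S if S else 0.0
    pN = Nd / N if N else 0.0
    dS = jukes_cantor(pS)
    dN = jukes_cantor(pN)
    omega = (dN / dS) if dS > 0 else None

    dS_se = dN_se = None
    if bootstrap_reps > 0:
        rng = np.random.default_rng(seed)
        n = len(all_a)
        # per-column site/difference contributions, resampled as units
        contrib = np.empty((n, 4))
        for i, (x, y) in enumerate(zip(all_a, all_b)):
            d = count_differences_ng86(x, y)
            sx, nx = count_sites_ng86(x)
            sy, ny = count_sites_ng86(y)
            if d is None:
                contrib[i] = (0.0, 0.0, 0.0, 0.0)
            else:
                contrib[i] = ((sx + sy) / 2, (nx + ny) / 2, d[0], d[1])
        ds_samples, dn_samples = [], []
        for _ in range(bootstrap_reps):
            idx = rng.integers(0, n, size=n)
            bS, bN, bSd, bNd = contrib[idx].sum(axis=0)
            bpS = bSd / bS if bS else 0.0
            bpN = bNd / bN if bN else 0.0
            if bpS < 0.75 and bpN < 0.75:
                ds_samples.append(jukes_cantor(bpS))
                dn_samples.append(jukes_cantor(bpN))
        dS_se = float(np.std(ds_samples, ddof=1)) if len(ds_samples) > 1 else 0.0
        dN_se = float(np.std(dn_samples, ddof=1)) if len(dn_samples) > 1 else 0.0

    gene_results = {}
    if per_gene:
        for al in alignments:
            gS, gN, gSd, gNd, gsk = _tally(al.codons_a, al.codons_b)
            gene_results[al.gene] = {"S": gS, "N": gN, "Sd": gSd, "Nd": gNd,
                                     "skipped": gsk}

    return SelectionSummary(
        Sd=Sd, Nd=Nd, S=S, N=N, pS=pS, pN=pN, dS=float(dS), dN=float(dN),
        dS_se=dS_se, dN_se=dN_se, omega=omega,
        n_codons=len(all_a), skipped_codons=skipped, per_gene=gene_results)
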