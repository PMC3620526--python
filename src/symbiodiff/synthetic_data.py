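"""Synthetic annotated genomes and derived strains with planted mutations.

The generator builds a circular annotated ancestor (configurable length, GC
content, CDS/pseudogene/RNA/IGR architecture, optional duplicated rRNA-like
block, optional inverted-repeat-flanked region, homopolymer enrichment) and
derives a second strain carrying planted substitutions and indels with fully
parameterized class fractions.  Every planted event is recorded in a truth
table as a left-normalized, labelled Variant, so the whole pipeline
(alignment, calling, classification, context, selection) can be scored
against ground truth without any external data.

All randomness flows through one numpy Generator per operation, seeded from
the spec/model, so outputs are byte-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genome_io import Feature, GenomeRecord, build_partition, reverse_complement
from .genome_profile import GENETIC_CODE, STOP_CODONS
from .indel_context import classify_indel_context, scan_homopolymers, scan_microsatellites
from .strain_compare import Variant, apply_variants, left_normalize
from .trna_demand import CodonDemand, TRNAInventory

__all__ = [
    "GenomeSpec", "MutationModel", "TruthTable",
    "generate_genome", "derive_strain", "generate_panel",
    "InfeasibleSpecError",
]


class InfeasibleSpecError(ValueError):
    """The requested architecture or mutation load cannot be placed."""


# one anticodon per amino acid (a plausible minimal decoding set)
DEFAULT_ANTICODONS = (
    "TGC", "ACG", "GTT", "GTC", "GCA", "TTG", "TTC", "GCC", "GTG", "GAT",
    "TAG", "CTT", "CAT", "GAA", "TGG", "GCT", "TGT", "CCA", "GTA", "TAC")

AA_OF_ANTICODON = {ac: GENETIC_CODE[reverse_complement(ac)]
                   for ac in DEFAULT_ANTICODONS}

AA3 = {"A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp", "C": "Cys",
       "Q": "Gln", "E": "Glu", "G": "Gly", "H": "His", "I": "Ile",
       "L": "Leu", "K": "Lys", "M": "Met", "F": "Phe", "P": "Pro",
       "S": "Ser", "T": "Thr", "W": "Trp", "Y": "Tyr", "V": "Val"}


@dataclass
class GenomeSpec:
    length: int
    gc_content: float = 0.50
    n_cds: int = 100
    n_trna: int = 10
    n_pseudogenes: int = 5
    cds_length_mean: float = 900.0       # bp, incl. start and stop
    cds_length_sd: float = 300.0
    cds_min_length: int = 150
    homopolymer_runs_per_kb: float = 0.0  # planted A/T runs >= 6 nt, in IGRs
    run_length_geom_p: float = 0.5        # planted run length = 6 + Geom(p) - 1
    duplicated_block: tuple[int, int] | None = None   # (length, copies)
    ir_flanked: tuple[int, int] | None = None         # (arm length, region length)
    stop_weights: tuple[float, float, float] = (0.6, 0.2, 0.2)  # TAA, TAG, TGA
    trna_anticodons: tuple[str, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.gc_content < 1.0:
            raise InfeasibleSpecError("gc_content must be in (0, 1)")
        if self.length < 1:
            raise InfeasibleSpecError("length must be positive")


@dataclass
class MutationModel:
    n_substitutions: int = 0
    transition_fraction: float = 0.5
    gc_to_at_fraction: float = 0.85       # P(event is a GC<->AT change)
    neutral_split_at: float = 0.5         # P(A<->T | neutral GC-content change)
    n_indels: int = 0
    indel_size_mean: float = 2.0          # geometric mean; sizes capped below
    indel_size_max: int = 75
    indel_events: list[tuple[int, str]] | None = None  # explicit (size, ins|del)
    homopolymer_targeting_prob: float = 0.0
    coding_synonymous_fraction: float | None = None
    substitution_partition_weights: dict[str, float] | None = None
    indel_partition_weights: dict[str, float] | None = None
    min_spacing: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("transition_fraction", "gc_to_at_fraction",
                     "neutral_split_at", "homopolymer_targeting_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InfeasibleSpecError(f"{name} must be in [0, 1]")
        if self.transition_fraction > self.gc_to_at_fraction + 1e-12:
            raise InfeasibleSpecError(
                "transitions are GC<->AT changes by definition, so "
                "transition_fraction cannot exceed gc_to_at_fraction")


@dataclass
class TruthTable:
    """Planted-mutation ledger: left-normalized labelled Variants on the
    ancestor's coordinates, in position order."""
    events: list[Variant]
    ancestor_id: str
    derived_id: str
    seed: int

    @property
    def substitutions(self) -> list[Variant]:
        return [v for v in self.events if v.vtype == "substitution"]

    @property
    def indels(self) -> list[Variant]:
        return [v for v in self.events if v.vtype != "substitution"]

    def to_tsv(self) -> str:
        rows = ["pos_1based\ttype\tref\talt\tlength\tlabels"]
        for v in self.events:
            lab = ";".join(f"{k}={val}" for k, val in sorted(v.labels.items()))
            rows.append(f"{v.pos + 1}\t{v.vtype}\t{v.ref}\t{v.alt}\t{v.length}\t{lab}")
        return "\n".join(rows) + "\n"


# ---------------------------------------------------------------------------
# Genome generation


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> str:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=n, p=probs)])


def _random_cds(rng: np.random.Generator, n_codons: int, gc: float,
                stop_weights: tuple[float, float, float]) -> str:
    """ATG + stop-free body + weighted stop codon."""
    body = []
    while len(body) < n_codons - 2:
        chunk = _random_bases(rng, 3 * (n_codons - 2 - len(body)), gc)
        for i in range(0, len(chunk), 3):
            cod = chunk[i:i + 3]
            if GENETIC_CODE[cod] != "*":
                body.append(cod)
    w = np.asarray(stop_weights, dtype=float)
    stop = STOP_CODONS[rng.choice(3, p=w / w.sum())]
    return "ATG" + "".join(body) + stop


def generate_genome(spec: GenomeSpec) -> GenomeRecord:
    """Build a deterministic annotated ancestor genome from a spec.

    Features are laid out non-overlapping, separated by IGRs whose lengths
    are drawn from a multinomial split of the residual length; CDS start with
    ATG, end with a stop and contain no internal stop.  Optional extras: a
    duplicated rRNA-like block (identical copies), an inverted-repeat-flanked
    region, and homopolymer enrichment of the IGRs.
    """
    rng = np.random.default_rng(spec.seed)

    items: list[tuple[str, str, dict]] = []   # (kind, payload sequence, meta)
    cds_lens = np.maximum(
        spec.cds_min_length,
        rng.normal(spec.cds_length_mean, spec.cds_length_sd, spec.n_cds))
    cds_lens = (np.round(cds_lens / 3).astype(int) * 3)
    for i, ln in enumerate(cds_lens):
        n_codons = max(int(ln) // 3, 4)
        seq = _random_cds(rng, n_codons, spec.gc_content, spec.stop_weights)
        strand = "+" if rng.random() < 0.5 else "-"
        items.append(("CDS", seq, {"name": f"g{i + 1:04d}", "strand": strand}))

    anticodons = spec.trna_anticodons or DEFAULT_ANTICODONS
    for i in range(spec.n_trna):
        ac = anticodons[i % len(anticodons)]
        aa = AA_OF_ANTICODON.get(ac, GENETIC_CODE.get(reverse_complement(ac), "X"))
        items.append(("tRNA", _random_bases(rng, 76, spec.gc_content),
                      {"name": f"trna{i + 1:02d}", "strand": "+",
                       "anticodon": ac, "product": f"tRNA-{AA3.get(aa, aa)}({ac})"}))

    for i in range(spec.n_pseudogenes):
        ln = int(max(90, rng.normal(spec.cds_length_mean * 0.6,
                                    spec.cds_length_sd * 0.5)))
        items.append(("pseudogene", _random_bases(rng, ln, spec.gc_content),
                      {"name": f"ps{i + 1:03d}", "strand": "+",
                       "original_key": "CDS"}))

    if spec.duplicated_block is not None:
        blen, copies = spec.duplicated_block
        block = _random_bases(rng, blen, spec.gc_content)
        for i in range(copies):
            items.append(("rRNA", block,
                          {"name": f"rrn{i + 1}", "strand": "+"}))

    if spec.ir_flanked is not None:
        arm_len, region_len = spec.ir_flanked
        arm = _random_bases(rng, arm_len, spec.gc_content)
        interior = _random_bases(rng, region_len, spec.gc_content)
        items.append(("igr_block", arm + interior + reverse_complement(arm), {}))

    order = rng.permutation(len(items))
    items = [items[i] for i in order]

    total_feature = sum(len(p) for _, p, _ in items)
    n_igr = len(items) + 1
    min_igr = 20
    residual = spec.length - total_feature - n_igr * min_igr
    if residual < 0:
        raise InfeasibleSpecError(
            f"features need {total_feature + n_igr * min_igr} bp but genome "
            f"length is {spec.length}")
    extra = rng.multinomial(residual, np.full(n_igr, 1.0 / n_igr))
    igr_lens = extra + min_igr

    parts: list[str] = []
    features: list[Feature] = []
    pos = 0
    for idx, (kind, payload, meta) in enumerate(items):
        igr = _random_bases(rng, int(igr_lens[idx]), spec.gc_content)
        parts.append(igr)
        pos += len(igr)
        s, e = pos, pos + len(payload)
        if kind == "igr_block":
            parts.append(payload)
        elif kind == "CDS":
            strand = meta["strand"]
            genomic = payload if strand == "+" else reverse_complement(payload)
            parts.append(genomic)
            features.append(Feature(kind="CDS", strand=strand,
                                    intervals=[(s, e)], name=meta["name"],
                                    qualifiers={"locus_tag": meta["name"]}))
        elif kind == "tRNA":
            parts.append(payload)
            features.append(Feature(
                kind="tRNA", strand="+", intervals=[(s, e)],
                name=meta["name"],
                qualifiers={"anticodon": meta["anticodon"],
                            "product": meta["product"]}))
        elif kind == "rRNA":
            parts.append(payload)
            features.append(Feature(kind="rRNA", strand="+",
                                    intervals=[(s, e)], name=meta["name"],
                                    qualifiers={}))
        else:
            parts.append(payload)
            features.append(Feature(kind="pseudogene", strand="+",
                                    intervals=[(s, e)], name=meta["name"],
                                    qualifiers={"original_key":
                                                meta["original_key"]}))
        pos += len(payload)
    parts.append(_random_bases(rng, int(igr_lens[-1]), spec.gc_content))
    seq = list("".join(parts))
    assert len(seq) == spec.length

    # homopolymer enrichment: overwrite stretches inside IGRs with A/T runs
    if spec.homopolymer_runs_per_kb > 0:
        n_runs = rng.poisson(spec.homopolymer_runs_per_kb * spec.length / 1000)
        igr_spans = _igr_spans(spec.length, features)
        weights = np.array([e - s for s, e in igr_spans], dtype=float)
        weights /= weights.sum()
        placed: list[tuple[int, int]] = []
        for _ in range(int(n_runs)):
            run_len = 6 + rng.geometric(spec.run_length_geom_p) - 1
            base = "A" if rng.random() < 0.5 else "T"
            for _try in range(50):
                si = rng.choice(len(igr_spans), p=weights)
                s, e = igr_spans[si]
                if e - s < run_len + 4:
                    continue
                start = int(rng.integers(s + 2, e - run_len - 1))
                span = (start - 1, start + run_len + 1)
                if any(not (span[1] <= a or b <= span[0]) for a, b in placed):
                    continue
                # avoid accidental merge with identical neighbours
                if seq[start - 1] == base or seq[start + run_len] == base:
                    continue
                seq[start:start + run_len] = base * run_len
                placed.append(span)
                break

    record = GenomeRecord(id=f"synthetic_{spec.seed}", sequence="".join(seq),
                          circular=True, features=features)
    return record


def _igr_spans(length: int, features: list[Feature]) -> list[tuple[int, int]]:
    occupied = sorted((f.start, f.end) for f in features)
    spans = []
    prev = 0
    for s, e in occupied:
        if s > prev:
            spans.append((prev, s))
        prev = max(prev, e)
    if prev < length:
        spans.append((prev, length))
    return spans


# ---------------------------------------------------------------------------
# Strain derivation

_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_GC_TO_AT_TV = {"G": "T", "C": "A"}
_AT_TO_GC_TV = {"A": "C", "T": "G"}
_AT_SWAP = {"A": "T", "T": "A"}
_GC_SWAP = {"G": "C", "C": "G"}
_COMP = {"A": "T", "T": "A", "G": "C", "C": "G"}


class _EventPlacer:
    """Tracks occupied intervals (sorted, bisect lookups) with a minimum
    spacing margin, so tens of thousands of events place quickly."""

    def __init__(self, spacing: int):
        self.spacing = spacing
        self.starts: list[int] = []
        self.ends: list[int] = []

    def free(self, start: int, end: int) -> bool:
        import bisect
        m = self.spacing
        i = bisect.bisect_left(self.starts, start)
        if i > 0 and self.ends[i - 1] + m > start:
            return False
        if i < len(self.starts) and end + m > self.starts[i]:
            return False
        return True

    def claim(self, start: int, end: int) -> None:
        import bisect
        i = bisect.bisect_left(self.starts, start)
        self.starts.insert(i, start)
        self.ends.insert(i, end)


def _cds_maps(record: GenomeRecord):
    """Per-CDS codon lists plus a position -> (cds index) lookup."""
    cds_feats = record.features_of_kind("CDS")
    pos_cds = np.full(len(record), -1, dtype=np.int32)
    codons = []
    for ci, f in enumerate(cds_feats):
        s, e = f.intervals[0]
        pos_cds[s:e] = ci
        seq = record.sequence[s:e]
        if f.strand == "-":
            seq = reverse_complement(seq)
        codons.append([seq[i:i + 3] for i in range(0, len(seq), 3)])
    return cds_feats, pos_cds, codons


def _coding_change(record, cds_feats, pos_cds, codons, pos: int, alt: str):
    """(codon_index, old_codon, new_codon, synonymous, creates_stop, at_edge)
    of a genome-strand substitution inside a CDS."""
    ci = int(pos_cds[pos])
    f = cds_feats[ci]
    s, e = f.intervals[0]
    if f.strand == "+":
        q = pos - s
        coding_alt = alt
    else:
        q = (e - 1) - pos
        coding_alt = _COMP[alt]
    codon_idx, off = q // 3, q % 3
    old = codons[ci][codon_idx]
    new = old[:off] + coding_alt + old[off + 1:]
    syn = GENETIC_CODE[new] == GENETIC_CODE[old]
    at_edge = codon_idx == 0 or codon_idx == len(codons[ci]) - 1
    return codon_idx, old, new, syn, GENETIC_CODE[new] == "*", at_edge


def _apportion(weights: dict[str, float] | None, n: int) -> list[str] | None:
    """Largest-remainder apportionment of n events over weighted classes."""
    if weights is None or n == 0:
        return None if weights is None else []
    names = sorted(weights)
    w = np.array([weights[k] for k in names], dtype=float)
    w = w / w.sum()
    exact = w * n
    counts = np.floor(exact).astype(int)
    short = n - counts.sum()
    for i in np.argsort(-(exact - counts))[:short]:
        counts[i] += 1
    plan: list[str] = []
    for name, c in zip(names, counts):
        plan.extend([name] * int(c))
    return plan


def derive_strain(ancestor: GenomeRecord, model: MutationModel,
                  ) -> tuple[GenomeRecord, TruthTable]:
    """Plant substitutions and indels on the ancestor; return the derived
    strain (with shifted annotation) and the truth table.

    Substitution classes follow the model's transition / GC->AT knobs
    exactly per event; indels target homopolymer runs with the stated
    probability.  Events respect min_spacing, avoid feature boundaries and
    CDS start/stop codons, and never create internal stop codons, so every
    planted label is recoverable by the downstream classifiers.
    """
    rng = np.random.default_rng(model.seed)
    seq = ancestor.sequence
    n = len(seq)
    partition = build_partition(ancestor)
    cls = partition.classes
    cds_feats, pos_cds, codons = _cds_maps(ancestor)

    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    is_gc = (arr == ord("G")) | (arr == ord("C"))
    class_codes = {"igr": 0, "pseudogene": 1, "rna": 2, "coding": 3}
    pools: dict[tuple[str, str], np.ndarray] = {}
    for cname, code in class_codes.items():
        in_class = cls == code
        pools[(cname, "GC")] = np.flatnonzero(in_class & is_gc)
        pools[(cname, "AT")] = np.flatnonzero(in_class & ~is_gc)
        pools[(cname, "ANY")] = np.flatnonzero(in_class)
    global_pools = {"GC": np.flatnonzero(is_gc), "AT": np.flatnonzero(~is_gc)}

    # feature-boundary margin: indels keep clear of starts/ends of features
    boundary = np.zeros(n, dtype=bool)
    for f in ancestor.features:
        for s, e in f.intervals:
            boundary[max(0, s - 3):min(n, s + 3)] = True
            boundary[max(0, e - 3):min(n, e + 3)] = True

    runs = scan_homopolymers(seq, min_len=6)
    tracts = scan_microsatellites(seq)
    run_near = np.zeros(n, dtype=bool)
    for r in runs:
        run_near[max(0, r.start - 2):min(n, r.end + 2)] = True

    placer = _EventPlacer(model.min_spacing)
    events: list[Variant] = []
    genes_hit_by_indel: set[int] = set()
    genes_hit_by_sub: set[int] = set()

    max_tries = 4000

    # ---------------- substitutions
    # The class fractions are study conditions, so they are realized as exact
    # quotas (largest-remainder apportionment) rather than per-event coin
    # flips; the rng only shuffles assignments and picks positions.
    n_sub = model.n_substitutions
    n_ti = int(round(n_sub * model.transition_fraction))
    n_gcat = min(max(int(round(n_sub * model.gc_to_at_fraction)), n_ti), n_sub)
    n_neutral = n_sub - n_gcat
    n_at_swap = min(int(round(n_neutral * model.neutral_split_at)), n_neutral)
    mut_plan = (["ti"] * n_ti + ["gcat_tv"] * (n_gcat - n_ti)
                + ["at_swap"] * n_at_swap
                + ["gc_swap"] * (n_neutral - n_at_swap))
    # orientation of GC<->AT events: which strain holds the A/T base (even split)
    orient_plan = (["GC"] * (n_gcat - n_gcat // 2) + ["AT"] * (n_gcat // 2))
    orient_plan = [orient_plan[i] for i in rng.permutation(n_gcat)]
    part_plan = _apportion(model.substitution_partition_weights, n_sub)
    if part_plan is not None:
        part_plan = [part_plan[i] for i in rng.permutation(n_sub)]
    mut_plan = [mut_plan[i] for i in rng.permutation(n_sub)]
    syn_plan: list[bool | None] = [None] * n_sub
    if model.coding_synonymous_fraction is not None and part_plan is not None:
        coding_idx = [i for i, c in enumerate(part_plan) if c == "coding"]
        n_syn = int(round(len(coding_idx) * model.coding_synonymous_fraction))
        flags = [True] * n_syn + [False] * (len(coding_idx) - n_syn)
        flags = [flags[i] for i in rng.permutation(len(flags))]
        for i, fl in zip(coding_idx, flags):
            syn_plan[i] = fl

    orient_iter = iter(orient_plan)
    for ev_i in range(n_sub):
        mclass = mut_plan[ev_i]
        target_class = part_plan[ev_i] if part_plan is not None else None
        want_syn = syn_plan[ev_i]
        if mclass in ("ti", "gcat_tv"):
            group = next(orient_iter)
            if mclass == "ti":
                alt_of = _TRANSITION
            else:
                alt_of = _GC_TO_AT_TV if group == "GC" else _AT_TO_GC_TV
        elif mclass == "at_swap":
            group, alt_of = "AT", _AT_SWAP
        else:
            group, alt_of = "GC", _GC_SWAP
        placed = False
        for _try in range(max_tries):
            if target_class is None:
                pool = global_pools[group]
            else:
                pool = pools[(target_class, group)]
            if len(pool) == 0:
                continue
            pos = int(pool[rng.integers(0, len(pool))])
            if not placer.free(pos, pos + 1):
                continue
            base = seq[pos]
            alt = alt_of.get(base)
            if alt is None:
                continue
            in_coding = cls[pos] == class_codes["coding"]
            if in_coding:
                ci = int(pos_cds[pos])
                if ci in genes_hit_by_indel:
                    continue
                _, _, _, syn, makes_stop, at_edge = _coding_change(
                    ancestor, cds_feats, pos_cds, codons, pos, alt)
                if makes_stop or at_edge:
                    continue
                if want_syn is not None and syn != want_syn:
                    continue
                genes_hit_by_sub.add(ci)
                syn_label = "synonymous" if syn else "nonsynonymous"
            else:
                syn_label = None
            v = Variant(vtype="substitution", pos=pos, ref=base, alt=alt,
                        length=1)
            if syn_label:
                v.labels["synonymy"] = syn_label
            events.append(v)
            placer.claim(pos, pos + 1)
            placed = True
            break
        if not placed:
            raise InfeasibleSpecError(
                "could not place all substitutions under the spacing and "
                "class constraints")

    # ---------------- indels
    if model.indel_events is not None:
        indel_plan = list(model.indel_events)
    else:
        indel_plan = []
        for _ in range(model.n_indels):
            size = min(int(rng.geometric(1.0 / model.indel_size_mean)),
                       model.indel_size_max)
            indel_plan.append((size, "deletion" if rng.random() < 0.5
                               else "insertion"))

    n_ind = len(indel_plan)
    n_hp = int(round(n_ind * model.homopolymer_targeting_prob))
    # slippage events in mononucleotide runs are short: the homopolymer
    # quota goes to the smallest drawn sizes (a deletion cannot exceed the
    # run it sits in)
    size_order = np.argsort([s for s, _ in indel_plan], kind="stable")
    hp_set = {int(i) for i in size_order[:n_hp]}
    hp_flags = [i in hp_set for i in range(n_ind)]
    ind_part_plan = _apportion(model.indel_partition_weights, n_ind - n_hp)
    if ind_part_plan:
        ind_part_plan = [ind_part_plan[i]
                         for i in rng.permutation(len(ind_part_plan))]
    nonhp_i = 0

    for (size, vtype), target_hp in zip(indel_plan, hp_flags):
        if target_hp:
            target_class = None   # homopolymer runs live where they live
        else:
            target_class = (ind_part_plan[nonhp_i]
                            if ind_part_plan else None)
            nonhp_i += 1
        placed = False
        for _try in range(max_tries):
            if target_hp:
                cand = [r for r in runs
                        if (target_class is None
                            or partition.class_at(r.start) == target_class
                            and partition.class_at(r.end - 1) == target_class)
                        and not boundary[r.start:r.end].any()
                        and (vtype == "insertion" or r.length >= size)
                        and placer.free(r.start - 1, r.end + 1)]
                if not cand:
                    continue
                r = cand[int(rng.integers(0, len(cand)))]
                p, allele = r.start, r.base * size
            else:
                pool = pools[(target_class, "ANY")] if target_class else None
                if pool is not None and len(pool) == 0:
                    continue
                pos0 = int(pool[rng.integers(0, len(pool))]) if pool is not None \
                    else int(rng.integers(1, n - size - 2))
                if vtype == "deletion":
                    span = (pos0, pos0 + size)
                    if span[1] >= n:
                        continue
                    allele = seq[span[0]:span[1]]
                else:
                    span = (pos0, pos0)
                    allele = _random_bases(rng, size, 0.5)
                p, allele = left_normalize(seq, pos0, allele)
                end = p + (size if vtype == "deletion" else 0)
                if boundary[max(0, p - 2):min(n, end + 2)].any():
                    continue
                if run_near[max(0, p - 1):min(n, end + 1)].any():
                    continue
                if target_class is not None and (
                        partition.class_at(p) != target_class
                        or partition.class_at(max(p, end - 1)) != target_class):
                    continue
            end = p + (size if vtype == "deletion" else 0)
            if not placer.free(p - 1, end + 1):
                continue
            ci = int(pos_cds[p]) if cls[p] == class_codes["coding"] else -1
            if ci >= 0 and (ci in genes_hit_by_sub or ci in genes_hit_by_indel):
                continue
            v = _make_indel(seq, vtype, p, allele)
            call = classify_indel_context(v, runs, tracts)
            if target_hp and call.context != "homopolymer":
                continue
            if not target_hp and call.context == "homopolymer":
                continue
            if ci >= 0:
                genes_hit_by_indel.add(ci)
            events.append(v)
            placer.claim(p - 1, end + 1)
            placed = True
            break
        if not placed:
            raise InfeasibleSpecError(
                f"could not place a {size} bp {vtype} under the constraints")

    events.sort(key=lambda v: v.seg_start)

    # label substitutions with ti/tv, direction and partition (truth labels
    # use the same definitions the classifier applies)
    from .strain_compare import _direction, is_transition
    for v in events:
        v.labels["partition"] = partition.class_at(min(v.seg_start, n - 1))
        if v.vtype == "substitution":
            v.labels["titv"] = "ti" if is_transition(v.ref, v.alt) else "tv"
            d, gainer = _direction(v.ref, v.alt)
            v.labels["direction"] = d
            v.labels["at_gaining_strain"] = gainer

    derived_seq = apply_variants(seq, events)
    derived_features = _shift_features(ancestor.features, events)
    derived = GenomeRecord(id=f"{ancestor.id}_derived", sequence=derived_seq,
                           circular=ancestor.circular,
                           features=derived_features)
    truth = TruthTable(events=events, ancestor_id=ancestor.id,
                       derived_id=derived.id, seed=model.seed)
    return derived, truth


def _make_indel(seq: str, vtype: str, p: int, allele: str) -> Variant:
    if p > 0:
        anchor = seq[p - 1]
        ref = anchor + allele if vtype == "deletion" else anchor
        alt = anchor if vtype == "deletion" else anchor + allele
        pos = p - 1
    else:
        nxt = seq[len(allele)] if vtype == "deletion" else seq[0]
        ref = allele + nxt if vtype == "deletion" else nxt
        alt = nxt if vtype == "deletion" else allele + nxt
        pos = 0
    return Variant(vtype=vtype, pos=pos, ref=ref, alt=alt, length=len(allele))


def _shift_features(features: list[Feature], events: list[Variant],
                    ) -> list[Feature]:
    """Map feature intervals through the planted indels (which never touch
    feature boundaries, so intervals shift rigidly at their ends)."""
    indels = [(v.seg_start, v.length if v.vtype == "insertion" else -v.length)
              for v in events if v.vtype != "substitution"]
    indels.sort()

    def delta(p: int) -> int:
        d = 0
        for s, ln in indels:
            if ln > 0 and s <= p:
                d += ln
            elif ln < 0 and s + (-ln) <= p:
                d += ln
        return d

    out = []
    for f in features:
        new_ivs = [(s + delta(s), e + delta(e)) for s, e in f.intervals]
        out.append(Feature(kind=f.kind, strand=f.strand, intervals=new_ivs,
                           name=f.name, qualifiers=dict(f.qualifiers)))
    return out


# ---------------------------------------------------------------------------
# tRNA-demand panels


def generate_panel(n_genomes: int,
                   demand_range: tuple[int, int] = (50_000, 1_300_000),
                   noise_sd: float = 3.0,
                   slope: float = 4.5e-5,
                   intercept: float = 25.0,
                   overload_factor: float | None = None,
                   overload_index: int = 0,
                   seed: int = 0,
                   ) -> list[tuple[TRNAInventory, CodonDemand]]:
    """Synthetic cross-genome panel: tRNA counts linear in codon demand plus
    Gaussian noise; optionally one genome's count multiplied by
    overload_factor to emulate a tRNA-overloaded outlier."""
    if n_genomes < 4:
        raise ValueError("panels need at least 4 genomes")
    rng = np.random.default_rng(seed)
    sense = sorted(c for c, aa in GENETIC_CODE.items() if aa != "*")
    panel = []
    demands = np.sort(rng.integers(demand_range[0], demand_range[1],
                                   size=n_genomes))
    for i, total in enumerate(demands):
        gid = f"panel{i + 1:02d}"
        props = rng.dirichlet(np.full(len(sense), 2.0))
        per_codon = rng.multinomial(int(total), props)
        demand = CodonDemand(genome_id=gid,
                             codon_counts={c: int(k) for c, k
                                           in zip(sense, per_codon) if k})
        count = intercept + slope * float(total) + rng.normal(0.0, noise_sd)
        if overload_factor is not None and i == overload_index:
            count *= overload_factor
        count = max(1, int(round(count)))
        acs = list(DEFAULT_ANTICODONS)
        alloc = rng.multinomial(count, np.full(len(acs), 1.0 / len(acs)))
        inv = TRNAInventory(genome_id=gid,
                            anticodon_counts={a: int(k) for a, k
                                              in zip(acs, alloc) if k})
        panel.append((inv, demand))
    return panel
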