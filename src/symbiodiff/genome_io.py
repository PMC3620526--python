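"""Annotated genome records, GenBank/FASTA I/O, positional partitions and CDS extraction.

The unit of data for the whole pipeline is the :class:`GenomeRecord`: a single
(usually circular) bacterial replicon plus a flat list of typed features.
Coordinates are 0-based half-open everywhere inside the package; report writers
convert to 1-based inclusive (GenBank convention) at the boundary.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

__all__ = [
    "Feature",
    "GenomeRecord",
    "GenomePartition",
    "GenomeIOError",
    "parse_genbank",
    "write_genbank",
    "read_fasta",
    "write_fasta",
    "build_partition",
    "extract_cds",
    "reverse_complement",
]

FEATURE_KINDS = ("CDS", "rRNA", "tRNA", "smallRNA", "pseudogene")

# partition precedence: coding > rna > pseudogene > igr
CLASS_IGR = 0
CLASS_PSEUDO = 1
CLASS_RNA = 2
CLASS_CODING = 3
CLASS_NAMES = {CLASS_CODING: "coding", CLASS_RNA: "rna",
               CLASS_PSEUDO: "pseudogene", CLASS_IGR: "igr"}

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class GenomeIOError(ValueError):
    """Raised for malformed or unsupported genome input."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class Feature:
    """One annotated element.

    ``kind`` is one of CDS / rRNA / tRNA / smallRNA / pseudogene; anything
    flagged ``/pseudo`` in the source annotation is classed pseudogene
    regardless of its original key (the original key is kept in
    ``qualifiers['original_key']``).  ``intervals`` holds one or more 0-based
    half-open [start, end) pairs, in translation order for joined CDS.
    """

    kind: str
    strand: str
    intervals: list[tuple[int, int]]
    name: str
    qualifiers: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in FEATURE_KINDS:
            raise GenomeIOError(f"unknown feature kind {self.kind!r}")
        if self.strand not in "+-":
            raise GenomeIOError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.intervals:
            raise GenomeIOError("feature has no intervals")
        for s, e in self.intervals:
            if not (0 <= s < e):
                raise GenomeIOError(f"bad interval [{s},{e}) in feature {self.name!r}")

    @property
    def length(self) -> int:
        return sum(e - s for s, e in self.intervals)

    @property
    def start(self) -> int:
        return min(s for s, _ in self.intervals)

    @property
    def end(self) -> int:
        return max(e for _, e in self.intervals)

    def is_pseudo(self) -> bool:
        return self.kind == "pseudogene"


@dataclass
class GenomeRecord:
    id: str
    sequence: str
    circular: bool = False
    features: list[Feature] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        bad = set(self.sequence) - set("ACGTN")
        if bad:
            raise GenomeIOError(
                f"sequence of {self.id!r} contains unsupported characters {sorted(bad)}; "
                "only A/C/G/T/N are accepted")
        if len(self.sequence) < 1:
            raise GenomeIOError("empty sequence")
        for f in self.features:
            if f.end > len(self.sequence):
                raise GenomeIOError(
                    f"feature {f.name!r} interval ends at {f.end} beyond "
                    f"sequence length {len(self.sequence)}")

    def __len__(self) -> int:
        return len(self.sequence)

    def features_of_kind(self, kind: str) -> list[Feature]:
        return [f for f in self.features if f.kind == kind]


@dataclass
class GenomePartition:
    """Exclusive per-position class assignment (coding / rna / pseudogene / igr).

    ``classes`` is an int8 array of length ``genome length`` holding the CLASS_*
    codes; ``class_lengths`` maps class name -> bp.
    """

    classes: np.ndarray
    class_lengths: dict[str, int]

    def class_at(self, pos: int) -> str:
        return CLASS_NAMES[int(self.classes[pos])]

    @property
    def gene_density(self) -> float:
        """Percent of positions covered by functional genes (coding + rna)."""
        n = len(self.classes)
        return 100.0 * (self.class_lengths["coding"] + self.class_lengths["rna"]) / n

    def igr_intervals(self) -> list[tuple[int, int]]:
        """Maximal intervals of contiguous igr positions."""
        return _runs_of_value(self.classes, CLASS_IGR)


def _runs_of_value(arr: np.ndarray, value: int) -> list[tuple[int, int]]:
    mask = np.asarray(arr) == value
    if not mask.any():
        return []
    padded = np.concatenate(([False], mask, [False]))
    diff = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)
    return list(zip(starts.tolist(), ends.tolist()))


# ---------------------------------------------------------------------------
# GenBank parsing

_RNA_KEYS = {"rRNA": "rRNA", "tRNA": "tRNA", "ncRNA": "smallRNA",
             "misc_RNA": "smallRNA", "tmRNA": "smallRNA"}


def _feature_from_biopython(bf: SeqFeature, genome_len: int) -> Feature | None:
    key = bf.type
    pseudo = "pseudo" in bf.qualifiers or "pseudogene" in bf.qualifiers
    if key == "CDS":
        kind = "CDS"
    elif key in _RNA_KEYS:
        kind = _RNA_KEYS[key]
    elif key == "pseudogene":
        kind = "pseudogene"
        pseudo = True
    else:
        return None
    if pseudo:
        kind = "pseudogene"

    strand = "-" if bf.location.strand == -1 else "+"
    parts = list(bf.location.parts)
    # keep translation order for minus-strand joins
    if strand == "-":
        parts = sorted(parts, key=lambda p: int(p.start), reverse=True)
    else:
        parts = sorted(parts, key=lambda p: int(p.start))
    intervals = [(int(p.start), int(p.end)) for p in parts]
    for s, e in intervals:
        if e > genome_len:
            raise GenomeIOError(
                f"feature at {s}..{e} extends beyond sequence of length {genome_len}")

    quals: dict[str, str] = {}
    for k, v in bf.qualifiers.items():
        quals[k] = v[0] if isinstance(v, list) and v else str(v)
    if kind == "pseudogene":
        quals.setdefault("original_key", key)
    name = quals.get("gene") or quals.get("locus_tag") or quals.get("product") or "?"
    return Feature(kind=kind, strand=strand, intervals=intervals,
                   name=name, qualifiers=quals)


def parse_genbank(text: str) -> GenomeRecord:
    """Parse GenBank flat-file text into a :class:`GenomeRecord`.

    One Feature is produced per CDS/rRNA/tRNA/ncRNA feature; anything flagged
    ``/pseudo`` becomes kind=pseudogene.  Gene/source/misc features carrying no
    sequence class of their own are ignored.  Ambiguity codes other than N are
    rejected.
    """
    try:
        rec = SeqIO.read(io.StringIO(text), "genbank")
    except Exception as exc:  # Biopython raises bare ValueError with line info
        raise GenomeIOError(f"malformed GenBank record: {exc}") from exc
    seq = str(rec.seq).upper()
    if not seq or set(seq) == {"N"} and len(seq) == 0:
        raise GenomeIOError("GenBank record has no ORIGIN sequence")
    circular = rec.annotations.get("topology", "linear") == "circular"
    features = []
    for bf in rec.features:
        feat = _feature_from_biopython(bf, len(seq))
        if feat is not None:
            features.append(feat)
    return GenomeRecord(id=rec.id or rec.name, sequence=seq,
                        circular=circular, features=features)


def write_genbank(record: GenomeRecord) -> str:
    """Serialize a GenomeRecord back to GenBank flat-file text."""
    srec = SeqRecord(Seq(record.sequence), id=record.id, name=record.id[:16],
                     description="")
    srec.annotations["molecule_type"] = "DNA"
    srec.annotations["topology"] = "circular" if record.circular else "linear"
    for f in record.features:
        strand = -1 if f.strand == "-" else 1
        locs = [FeatureLocation(s, e, strand) for s, e in f.intervals]
        if strand == -1:
            locs = sorted(locs, key=lambda l: int(l.start))
        loc = locs[0] if len(locs) == 1 else CompoundLocation(locs)
        if f.kind == "pseudogene":
            key = f.qualifiers.get("original_key", "CDS")
            quals = {k: [v] for k, v in f.qualifiers.items() if k != "original_key"}
            quals["pseudo"] = [""]
        else:
            key = {"smallRNA": "ncRNA"}.get(f.kind, f.kind)
            quals = {k: [v] for k, v in f.qualifiers.items()}
        quals.setdefault("gene", [f.name])
        srec.features.append(SeqFeature(loc, type=key, qualifiers=quals))
    out = io.StringIO()
    SeqIO.write(srec, out, "genbank")
    return out.getvalue()


def read_fasta(text: str) -> list[tuple[str, str]]:
    recs = list(SeqIO.parse(io.StringIO(text), "fasta"))
    return [(r.id, str(r.seq).upper()) for r in recs]


def write_fasta(entries: list[tuple[str, str]], width: int = 70) -> str:
    out = []
    for name, seq in entries:
        out.append(f">{name}")
        out.extend(seq[i:i + width] for i in range(0, len(seq), width))
    return "\n".join(out) + "\n"


# ---------------------------------------------------------------------------
# Partition and CDS extraction

_KIND_TO_CLASS = {"CDS": CLASS_CODING, "rRNA": CLASS_RNA, "tRNA": CLASS_RNA,
                  "smallRNA": CLASS_RNA, "pseudogene": CLASS_PSEUDO}


def build_partition(record: GenomeRecord) -> GenomePartition:
    """Assign every position to exactly one of coding/rna/pseudogene/igr.

    Overlaps are resolved by precedence coding > rna > pseudogene; positions
    covered by nothing are igr.  The result is independent of feature order.
    """
    classes = np.zeros(len(record), dtype=np.int8)  # CLASS_IGR
    for f in record.features:
        code = _KIND_TO_CLASS[f.kind]
        for s, e in f.intervals:
            np.maximum(classes[s:e], code, out=classes[s:e])
    lengths = {name: int((classes == code).sum())
               for code, name in CLASS_NAMES.items()}
    return GenomePartition(classes=classes, class_lengths=lengths)


@dataclass
class CDSRecord:
    name: str
    sequence: str
    strand: str
    start: int
    end: int
    in_frame: bool            # length divisible by 3
    n_positions: list[int]    # indices of N within the extracted sequence


def extract_cds(record: GenomeRecord) -> list[CDSRecord]:
    """Extract in-frame nucleotide sequences of all functional CDS.

    Minus-strand CDS are reverse-complemented; joined intervals concatenated in
    translation order.  Sequences whose length is not a multiple of 3, or that
    contain N, are flagged rather than dropped or truncated.
    """
    out = []
    for f in record.features_of_kind("CDS"):
        if f.strand == "+":
            seq = "".join(record.sequence[s:e] for s, e in f.intervals)
        else:
            seq = "".join(reverse_complement(record.sequence[s:e])
                          for s, e in f.intervals)
        out.append(CDSRecord(
            name=f.name, sequence=seq, strand=f.strand,
            start=f.start, end=f.end,
            in_frame=len(seq) % 3 == 0,
            n_positions=[i for i, b in enumerate(seq) if b == "N"]))
    return out
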