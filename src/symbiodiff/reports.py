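"""Report writers: TSV / JSON / BED / minimal VCF-style variant tables.

All genomic coordinates are converted to 1-based inclusive here (GenBank
convention); BED output stays 0-based half-open as the format requires.
"""

from __future__ import annotations

import json
from typing import Iterable

from .genome_profile import CODONS, CodonUsageTable, GenomeSummary
from .indel_context import HomopolymerRun, MicrosatelliteTract
from .repeats import FlankedRegion, RepeatPair
from .strain_compare import Variant, VariantSummary

SCHEMA_VERSION = "1"


def summary_tsv(summary: GenomeSummary) -> str:
    rows = ["statistic\tvalue"]
    d = summary.as_dict()
    for key in ("genome_id", "size", "n_cds", "n_rrna", "n_trna",
                "n_small_rna", "n_pseudogenes"):
        rows.append(f"{key}\t{d[key]}")
    for key in ("gene_density", "mean_orf_length", "mean_igr_length",
                "gc_overall", "gc_genes", "gc_pseudogenes", "gc_igr"):
        rows.append(f"{key}\t{d[key]:.1f}")
    return "\n".join(rows) + "\n"


def codon_usage_tsv(table: CodonUsageTable) -> str:
    from .genome_profile import GENETIC_CODE
    rows = ["codon\tamino_acid\tcount"]
    for codon in CODONS:
        aa = GENETIC_CODE[codon]
        count = (table.stop_counts[codon] if aa == "*"
                 else table.codon_counts[codon])
        rows.append(f"{codon}\t{aa}\t{count}")
    return "\n".join(rows) + "\n"


def variants_tsv(chrom: str, variants: Iterable[Variant]) -> str:
    """Minimal VCF-body-style table: CHROM, POS (1-based), REF, ALT, INFO."""
    rows = ["CHROM\tPOS\tREF\tALT\tINFO"]
    for v in variants:
        info = ";".join([f"TYPE={v.vtype}", f"LEN={v.length}"]
                        + [f"{k.upper()}={val}"
                           for k, val in sorted(v.labels.items())])
        rows.append(f"{chrom}\t{v.pos + 1}\t{v.ref}\t{v.alt}\t{info}")
    return "\n".join(rows) + "\n"


def variant_summary_json(summary: VariantSummary, params: dict | None = None) -> str:
    payload = {"schema_version": SCHEMA_VERSION, **summary.as_dict()}
    if params:
        payload["parameters"] = params
    return json.dumps(payload, indent=2, sort_keys=True) + "\n"


def runs_bed(chrom: str, runs: Iterable[HomopolymerRun]) -> str:
    lines = [f"{chrom}\t{r.start}\t{r.end}\t{r.base}x{r.length}"
             for r in runs]
    return "\n".join(lines) + ("\n" if lines else "")


def tracts_bed(chrom: str, tracts: Iterable[MicrosatelliteTract]) -> str:
    lines = [f"{chrom}\t{t.start}\t{t.end}\t{t.motif}x{t.copies}"
             for t in tracts]
    return "\n".join(lines) + ("\n" if lines else "")


def repeats_tsv(pairs: Iterable[RepeatPair]) -> str:
    """BED-like but 1-based inclusive, with an orientation column."""
    rows = ["startA\tendA\tstartB\tendB\tlength\torientation"]
    for p in pairs:
        rows.append(f"{p.startA + 1}\t{p.startA + p.length}\t"
                    f"{p.startB + 1}\t{p.startB + p.length}\t"
                    f"{p.length}\t{p.orientation}")
    return "\n".join(rows) + "\n"


def ir_regions_tsv(regions: Iterable[FlankedRegion]) -> str:
    rows = ["region_start\tregion_end\tregion_length\tarm_length\t"
            "left_arm_start\tright_arm_start"]
    for r in regions:
        rows.append(f"{r.start + 1}\t{r.end}\t{r.region_length}\t"
                    f"{r.arm_length}\t{r.arm_start_left + 1}\t"
                    f"{r.arm_start_right + 1}")
    return "\n".join(rows) + "\n"


def json_report(payload: dict, params: dict | None = None) -> str:
    out = {"schema_version": SCHEMA_VERSION, **payload}
    if params:
        out["parameters"] = params
    return json.dumps(out, indent=2, sort_keys=True, default=float) + "\n"
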