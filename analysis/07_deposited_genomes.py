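#!/usr/bin/env python
"""Reproduce the published per-genome statistics from the deposited records.

Requires the four GenBank flat files under data/genomes/ (CP002918.gb,
CP002244.gb, CP003881.gb, CP002243.gb — the two sequenced strains of each
consortium partner).  They cannot be redistributed here; fetch them from
NCBI nuccore, e.g.:

    efetch -db nuccore -id CP003881 -format gb > data/genomes/CP003881.gb

With the files in place this script recomputes genome sizes, stratified GC,
feature counts, the tiny-genome strain-pair variant spectrum (23
substitutions / 5 indels / 138,903 identical bp), the A/T homopolymer
census, stop-codon usage, lysine-AAG demand and the dS/dN/omega estimate,
and writes everything to results/deposited_genomes.json.
"""

import json
import sys
from pathlib import Path

ROOT = Path(__file__).resolve().parent.parent
sys.path.insert(0, str(ROOT / "src"))

from symbiodiff.genome_io import build_partition, extract_cds, parse_genbank
from symbiodiff.genome_profile import aa_profile, codon_usage, summarize_genome
from symbiodiff.indel_context import scan_homopolymers
from symbiodiff.scenarios import run_strain_pair
from symbiodiff.trna_demand import codon_demand, trna_inventory

DATA = ROOT / "data" / "genomes"
RESULTS = ROOT / "results"
ACCESSIONS = {
    "CP002918": "tremblaya_PCVAL", "CP002244": "tremblaya_PCIT",
    "CP003881": "moranella_PCVAL", "CP002243": "moranella_PCIT",
}


def main() -> None:
    missing = [a for a in ACCESSIONS if not (DATA / f"{a}.gb").exists()]
    if missing:
        print("Missing GenBank files under data/genomes/: "
              + ", ".join(missing))
        print("Fetch them from NCBI nuccore (see this script's docstring) "
              "and re-run; no network access is assumed here.")
        return

    recs = {name: parse_genbank((DATA / f"{acc}.gb").read_text())
            for acc, name in ACCESSIONS.items()}
    payload = {}
    for name, rec in recs.items():
        part = build_partition(rec)
        summ = summarize_genome(rec, part)
        payload[name] = {
            "size_bp": summ.size, "gc_percent": round(summ.gc_overall, 1),
            "gc_genes": round(summ.gc_genes, 1),
            "gc_pseudogenes": round(summ.gc_pseudogenes, 1),
            "gc_igr": round(summ.gc_igr, 1),
            "gene_density_percent": round(summ.gene_density, 1),
            "cds": summ.n_cds, "trna": summ.n_trna, "rrna": summ.n_rrna,
            "pseudogenes": summ.n_pseudogenes,
        }

    tp = run_strain_pair(recs["tremblaya_PCVAL"], recs["tremblaya_PCIT"],
                         with_selection=False)
    payload["tremblaya_pair"] = {
        "substitutions": tp.summary.n_substitutions,
        "transition_percent": round(100 * tp.summary.ti_fraction, 1),
        "indels": tp.summary.n_insertions + tp.summary.n_deletions,
        "identical_bp": tp.amap.identical_positions,
        "identity_percent": round(tp.amap.identity_percent, 2),
        "length_difference_bp": tp.length_difference,
    }

    me = run_strain_pair(recs["moranella_PCVAL"], recs["moranella_PCIT"],
                         bootstrap_reps=1000, seed=1)
    s = me.summary
    payload["moranella_pair"] = {
        "substitutions": s.n_substitutions,
        "gc_at_change_percent": round(s.gc_at_percent, 1),
        "indels": s.n_insertions + s.n_deletions,
        "mean_indel_size": round(s.mean_indel_size, 1),
        "homopolymer_context_percent":
            me.context_summary["homopolymer_percent"],
        "selection": me.selection.as_dict() if me.selection else None,
        "length_difference_bp": me.length_difference,
    }

    mp = recs["moranella_PCVAL"]
    runs = [r for r in scan_homopolymers(mp.sequence, 6) if r.base in "AT"]
    usage = codon_usage(extract_cds(mp))
    payload["moranella_PCVAL"].update({
        "at_homopolymers_ge6": len(runs),
        "taa_stop_percent": round(usage.stop_fraction("TAA"), 2),
        "aag_demand": codon_demand(mp).codon_counts.get("AAG", 0),
        "trna_genes_functional": trna_inventory(mp).total,
    })
    prof = aa_profile(extract_cds(recs["tremblaya_PCVAL"]))
    payload["tremblaya_PCVAL"]["gc_rich_aa_percent"] = round(
        100 * sum(prof.frequencies[a] for a in "ARLGVS"), 2)

    RESULTS.mkdir(exist_ok=True)
    (RESULTS / "deposited_genomes.json").write_text(
        json.dumps(payload, indent=2, sort_keys=True) + "\n")
    print(json.dumps(payload, indent=2, sort_keys=True))


if __name__ == "__main__":
    main()
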