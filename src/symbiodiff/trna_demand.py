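"""tRNA gene inventory versus proteome codon demand.

A genome's translational requirement is the total count of sense codons over
all its functional CDS; its tRNA supply is the count of functional tRNA
genes.  Across genomes the two are strongly linearly related; a genome whose
tRNA count is out of proportion (overloaded or depleted) is flagged by the
drop in R-squared when it is added to the panel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from scipy import stats

from .genome_io import GenomeRecord, extract_cds, reverse_complement
from .genome_profile import GENETIC_CODE

__all__ = [
    "TRNAInventory", "CodonDemand", "DemandRegression",
    "trna_inventory", "codon_demand", "fit_demand_regression",
    "overload_score", "codon_coverage_gaps", "anticodon_to_codon",
]


def anticodon_to_codon(anticodon: str) -> str:
    """Codon read 5'->3' that pairs a given anticodon by exact Watson-Crick
    base pairing (anticodon also written 5'->3')."""
    return reverse_complement(anticodon.upper().replace("U", "T"))


@dataclass
class TRNAInventory:
    genome_id: str
    anticodon_counts: dict[str, int] = field(default_factory=dict)
    n_unknown_anticodon: int = 0
    n_pseudo: int = 0

    @property
    def total(self) -> int:
        """Functional tRNA genes (pseudogenes never counted)."""
        return sum(self.anticodon_counts.values()) + self.n_unknown_anticodon

    def decoded_codons(self) -> set[str]:
        return {anticodon_to_codon(ac) for ac in self.anticodon_counts}


@dataclass
class CodonDemand:
    genome_id: str
    codon_counts: dict[str, int]

    @property
    def total_codons(self) -> int:
        """Total sense-codon demand (stops excluded)."""
        return sum(self.codon_counts.values())


@dataclass
class DemandRegression:
    points: list[tuple[str, int, int]]   # (genome id, total_codons, tRNA count)
    slope: float
    intercept: float
    r_squared: float


def _anticodon_of(qualifiers: dict[str, str]) -> str | None:
    ac = qualifiers.get("anticodon")
    if ac:
        # accept bare "cuu" or GenBank "(pos:..,aa:Lys,seq:cuu)" styles
        if "seq:" in ac:
            ac = ac.split("seq:")[1].rstrip(") ")
        ac = ac.strip().upper().replace("U", "T")
        if len(ac) == 3 and set(ac) <= set("ACGT"):
            return ac
    product = qualifiers.get("product", "")
    if "-" in product and "(" in product:   # e.g. "tRNA-Lys(CTT)"
        inner = product.split("(")[1].rstrip(")")
        inner = inner.upper().replace("U", "T")
        if len(inner) == 3 and set(inner) <= set("ACGT"):
            return inner
    return None


def trna_inventory(record: GenomeRecord) -> TRNAInventory:
    """Count functional tRNA genes per anticodon.

    Pseudo-tRNAs (already classed pseudogene at parse time) are counted
    separately and excluded from totals; features with an unresolvable
    anticodon stay in the total but are flagged.
    """
    inv = TRNAInventory(genome_id=record.id)
    for f in record.features_of_kind("tRNA"):
        ac = _anticodon_of(f.qualifiers)
        if ac is None:
            inv.n_unknown_anticodon += 1
        else:
            inv.anticodon_counts[ac] = inv.anticodon_counts.get(ac, 0) + 1
    for f in record.features_of_kind("pseudogene"):
        if f.qualifiers.get("original_key") == "tRNA":
            inv.n_pseudo += 1
    return inv


def codon_demand(record: GenomeRecord) -> CodonDemand:
    """Per-codon counts over all functional CDS; stop codons excluded."""
    counts: dict[str, int] = {}
    for cds in extract_cds(record):
        if not cds.in_frame or cds.n_positions:
            continue
        for i in range(0, len(cds.sequence), 3):
            c = cds.sequence[i:i + 3]
            if GENETIC_CODE.get(c, "*") != "*":
                counts[c] = counts.get(c, 0) + 1
    return CodonDemand(genome_id=record.id, codon_counts=counts)


def fit_demand_regression(panel: list[tuple[TRNAInventory, CodonDemand]],
                          ) -> DemandRegression:
    """OLS of tRNA gene count on total codon demand across >= 3 genomes."""
    if len(panel) < 3:
        raise ValueError("need at least 3 genomes for the regression")
    xs = [d.total_codons for _, d in panel]
    ys = [inv.total for inv, _ in panel]
    if len(set(xs)) == 1 or len(set(ys)) == 1:
        raise ValueError("zero variance in demand or tRNA counts")
    fit = stats.linregress(xs, ys)
    return DemandRegression(
        points=[(inv.genome_id, d.total_codons, inv.total)
                for inv, d in panel],
        slope=float(fit.slope), intercept=float(fit.intercept),
        r_squared=float(fit.rvalue) ** 2)


def overload_score(panel: list[tuple[TRNAInventory, CodonDemand]],
                   focal_id: str) -> tuple[float, float, float]:
    """(R2 with focal, R2 without focal, delta = without - with).

    A clearly positive delta marks the focal genome as an outlier in tRNA
    supply relative to its translational demand.
    """
    if len(panel) < 4:
        raise ValueError("need at least 4 genomes to score one against the rest")
    ids = [inv.genome_id for inv, _ in panel]
    if focal_id not in ids:
        raise ValueError(f"focal genome {focal_id!r} not in panel")
    with_focal = fit_demand_regression(panel).r_squared
    rest = [(inv, d) for inv, d in panel if inv.genome_id != focal_id]
    without_focal = fit_demand_regression(rest).r_squared
    return with_focal, without_focal, without_focal - with_focal


def codon_coverage_gaps(inventory: TRNAInventory, demand: CodonDemand,
                        wobble: dict[str, list[str]] | None = None,
                        ) -> list[tuple[str, int]]:
    """Sense codons in demand with no cognate tRNA, by decreasing demand.

    Cognate means exact Watson-Crick anticodon match; an optional wobble
    table (anticodon -> extra codons decoded) extends coverage.  Decoding
    rules vary by lineage, so wobble is data, not code.
    """
    covered = inventory.decoded_codons()
    if wobble:
        for ac, extra in wobble.items():
            if ac.upper().replace("U", "T") in inventory.anticodon_counts:
                covered.update(c.upper() for c in extra)
    gaps = [(codon, n) for codon, n in demand.codon_counts.items()
            if n > 0 and codon not in covered]
    gaps.sort(key=lambda t: (-t[1], t[0]))
    return gaps
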