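#!/usr/bin/env python
"""Intragenomic duplications and inverted-repeat-flanked regions.

Scans both simulated ancestors for maximal exact repeats (direct and
inverted) and for regions bracketed by inverted-repeat arms, mirroring the
duplicated rRNA-like block and the invertible region planted by the
generator.  Writes coordinate tables (1-based inclusive) to results/.
"""

import sys
from pathlib import Path

ROOT = Path(__file__).resolve().parent.parent
sys.path.insert(0, str(ROOT / "src"))

from symbiodiff.repeats import find_exact_repeats, find_ir_flanked_regions
from symbiodiff.reports import ir_regions_tsv, repeats_tsv
from symbiodiff.scenarios import moranella_like, tremblaya_like
from symbiodiff.synthetic_data import generate_genome

SEED = 1
RESULTS = ROOT / "results"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    for name, scenario, min_len in [("tremblaya_like", tremblaya_like, 1000),
                                    ("moranella_like", moranella_like, 1000)]:
        spec, _ = scenario(SEED)
        rec = generate_genome(spec)
        pairs = find_exact_repeats(rec.sequence, min_len=min_len)
        regions = find_ir_flanked_regions(rec.sequence, min_arm=30,
                                          max_region=10_000)
        (RESULTS / f"{name}_repeats.tsv").write_text(repeats_tsv(pairs))
        (RESULTS / f"{name}_ir_regions.tsv").write_text(
            ir_regions_tsv(regions))
        desc = ", ".join(
            f"{p.orientation} {p.length:,} bp at {p.startA + 1:,}/"
            f"{p.startB + 1:,}" for p in pairs) or "none"
        ir_desc = ", ".join(
            f"{r.region_length:,} bp region with {r.arm_length} bp arms"
            for r in regions) or "none"
        print(f"{name}: repeats >= {min_len} bp: {desc}; "
              f"IR-flanked regions: {ir_desc}")


if __name__ == "__main__":
    main()
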