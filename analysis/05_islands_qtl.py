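#!/usr/bin/env python
"""ROH islands, sweep/island overlap, and QTL annotation on the demo cohort.

Builds a small deterministic QTL track (intervals around and away from the
planted sweeps, labelled with trait categories), intersects it with the
detected sweep regions at both tails, and tallies hits per category.
"""

from pathlib import Path

import pandas as pd

from sweeproh import GenomicInterval, intersect, qtl_overlap
from sweeproh.vcfio import read_intervals, write_intervals

ROOT = Path(__file__).resolve().parents[1]
DEMO = ROOT / "results" / "demo"


def toy_qtl_track() -> list[GenomicInterval]:
    qtls = []
    # clusters near the planted sweeps plus scattered background QTLs
    for i in range(4):
        qtls.append(
            GenomicInterval(
                "chr1", 1_000_000 + i * 120_000, 1_150_000 + i * 120_000,
                name=f"qtl_tn_{i}", category="teat_number",
            )
        )
    for i in range(3):
        qtls.append(
            GenomicInterval(
                "chr2", 2_950_000 + i * 200_000, 3_100_000 + i * 200_000,
                name=f"qtl_bw_{i}", category="body_weight",
            )
        )
    for i in range(5):
        qtls.append(
            GenomicInterval(
                "chr3", 500_000 + i * 900_000, 700_000 + i * 900_000,
                name=f"qtl_mchc_{i}", category="mchc",
            )
        )
    return qtls


def main() -> None:
    regions_5 = DEMO / "sweep_regions_5pct.tsv"
    if not regions_5.exists():
        raise SystemExit("run analysis/03_sweep_scan.py first")

    qtls = toy_qtl_track()
    write_intervals(qtls, DEMO / "toy_qtl_track.bed")

    islands = pd.read_csv(DEMO / "roh_islands.tsv", sep="\t")
    print(f"{len(islands)} ROH islands detected across populations")

    for tag in ("1pct", "5pct"):
        df = pd.read_csv(DEMO / f"sweep_regions_{tag}.tsv", sep="\t")
        sweeps = [
            GenomicInterval(r.chrom, int(r.start), int(r.end))
            for r in df.itertuples()
        ]
        both = read_intervals(DEMO / f"sweep_island_overlap_{tag}.bed") if (
            DEMO / f"sweep_island_overlap_{tag}.bed"
        ).exists() else []
        report = qtl_overlap(sweeps, qtls)
        print(f"\n== tail {tag}: {len(sweeps)} sweep regions ==")
        print(f"sweep x island overlaps: {len(both)}")
        print(f"QTLs hit: {report.n_qtls_hit}")
        for cat, count in sorted(report.category_counts.items()):
            print(f"  {cat}: {count} ({report.category_percent[cat]:.2f}%)")
        pd.DataFrame(
            sorted(report.category_counts.items()), columns=["category", "n_qtls"]
        ).to_csv(DEMO / f"toy_qtl_tally_{tag}.tsv", sep="\t", index=False)


if __name__ == "__main__":
    main()
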