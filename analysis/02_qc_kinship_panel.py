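#!/usr/bin/env python
"""Quality control, kinship pruning and neutral-panel selection.

Reads the simulated cohort from results/cohort/, applies the site hard
filters (QUAL/FS/QD/MQ/RankSums, call rate, MAF), the individual filters
(mean depth >= 4x, missingness <= 30%), KING-robust kinship pruning at
phi > 0.177, and the panel rules (complete genotyping, MAF >= 0.05,
HWE P >= 0.001, one SNP per 10 kb), then checks every removal against the
generator's truth labels and writes the filtered dataset and reports
under results/qc/.
"""

import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent.parent / "src"))

import pandas as pd

from stepstone.qc import (
    design_panel,
    filter_individuals,
    filter_sites,
    king_kinship,
    prune_first_degree,
)
from stepstone.vcfio import read_popmap, read_vcf, write_popmap, write_vcf

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    truth = pd.read_csv(ROOT / "cohort" / "individuals_truth.tsv", sep="\t")
    gm = read_vcf(ROOT / "cohort" / "cohort.vcf", individuals=truth)
    out = ROOT / "qc"
    out.mkdir(parents=True, exist_ok=True)

    gm, site_rep = filter_sites(gm)
    print(site_rep)
    gm, ind_rep = filter_individuals(gm)
    print(ind_rep)
    planted_bad = set(truth.loc[truth.truth_low_depth | truth.truth_high_missing, "id"])
    removed = planted_bad - set(gm.ids)
    print(f"  planted low-quality individuals removed: {len(removed)}/{len(planted_bad)}")

    kin = king_kinship(gm)
    flagged = kin.pairs_above(0.177)
    kept = prune_first_degree(kin, missingness=gm.missing_fraction().to_dict())
    pruned = sorted(set(gm.ids) - set(kept))
    gm = gm.subset(ids=kept)
    planted_children = set(truth.loc[truth.truth_parent.notna(), "id"]) & set(
        kept + pruned
    )
    print(f"kinship: {len(flagged)} first-degree pair(s) flagged, "
          f"{len(pruned)} individual(s) pruned ({', '.join(pruned) or 'none'}); "
          f"{len(planted_children)} planted offspring were present")

    keep_idx, panel_rep = design_panel(gm)
    gm = gm.subset(site_idx=keep_idx)
    print(panel_rep)

    write_vcf(gm, out / "panel.vcf")
    write_popmap(gm.individuals, out / "panel.popmap.tsv")
    reports = {
        "site_filters": site_rep.to_dict(),
        "individual_filters": ind_rep.to_dict(),
        "kinship": {"flagged_pairs": [[a, b, round(p, 4)] for a, b, p in flagged],
                    "pruned": pruned},
        "panel": panel_rep.to_dict(),
    }
    (out / "qc_reports.json").write_text(json.dumps(reports, indent=1, sort_keys=True))
    print(f"final: {len(gm.individuals)} individuals x {len(gm.sites)} panel SNPs -> {out}")


if __name__ == "__main__":
    main()
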