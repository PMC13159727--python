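#!/usr/bin/env python
"""Simulate the synthetic study cohort.

Generates a cohort of 20 sampling groups nested in the five genetic
clusters (SW, SE, C, NC, N) under the best-fit admixed stepping-stone
demography, with planted QC failures (bad sites, low-depth and
high-missingness individuals, first-degree relatives), and writes it as
VCF + popmap under results/cohort/.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent.parent / "src"))

from stepstone.pipeline import RunConfig, load_or_simulate_cohort
from stepstone.vcfio import write_popmap, write_vcf

OUT = Path(__file__).resolve().parent.parent / "results" / "cohort"


def main() -> None:
    cfg = RunConfig(seed=1, n_sites=5000, relative_pairs=2, n_low_depth=3,
                    n_high_missing=3, site_fail_rate=0.01)
    gm = load_or_simulate_cohort(cfg)
    OUT.mkdir(parents=True, exist_ok=True)
    write_vcf(gm, OUT / "cohort.vcf")
    write_popmap(gm.individuals, OUT / "cohort.popmap.tsv")
    gm.individuals.to_csv(OUT / "individuals_truth.tsv", sep="\t", index=False)

    n_rel = gm.individuals["truth_parent"].notna().sum()
    n_bad_site = gm.sites["truth_fail_rule"].notna().sum()
    print(f"cohort: {len(gm.individuals)} individuals x {len(gm.sites)} SNPs")
    print(f"planted: {n_rel} offspring of sampled parents, "
          f"{int(gm.individuals.truth_low_depth.sum())} low-depth and "
          f"{int(gm.individuals.truth_high_missing.sum())} high-missingness "
          f"individuals, {n_bad_site} annotation-failing sites")
    print(f"written to {OUT}")


if __name__ == "__main__":
    main()
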