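#!/usr/bin/env python
"""Genetic diversity, differentiation and isolation by distance.

From the QC'd panel: per-individual observed heterozygosity, pairwise
Weir-Cockerham F_ST between the five clusters, and a Mantel test of
linearized F_ST against great-circle distance between cluster centroids.
Writes tables under results/stats/.
"""

import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent.parent / "src"))

import numpy as np

from stepstone.pipeline import _DEFAULT_COORDS
from stepstone.stats import (
    geographic_distances,
    linearize_fst_matrix,
    mantel_test,
    observed_heterozygosity,
    pairwise_fst,
)
from stepstone.vcfio import read_popmap, read_vcf

ROOT = Path(__file__).resolve().parent.parent / "results"
CLUSTERS = ["SW", "SE", "C", "NC", "N"]


def main() -> None:
    pm = read_popmap(ROOT / "qc" / "panel.popmap.tsv")
    gm = read_vcf(ROOT / "qc" / "panel.vcf", individuals=pm.assign(mean_depth=np.nan))
    out = ROOT / "stats"
    out.mkdir(parents=True, exist_ok=True)

    ho = observed_heterozygosity(gm.genotypes, gm.ids)
    by_cluster = ho.groupby(gm.individuals["cluster"].to_numpy()).mean()
    print("observed heterozygosity per cluster:")
    for c in CLUSTERS:
        print(f"  {c:3s} {by_cluster[c]:.3f}")
    ho.rename_axis("id").reset_index().to_csv(out / "heterozygosity.tsv", sep="\t",
                                              index=False, float_format="%.6g")

    fst = pairwise_fst(gm.genotypes, list(gm.individuals["cluster"]), CLUSTERS)
    fst.to_tsv(out / "fst_clusters.tsv")
    up = fst.upper()
    print(f"pairwise F_ST between clusters: {up.min():.3f} to {up.max():.3f}")

    geo = geographic_distances({c: _DEFAULT_COORDS[c] for c in CLUSTERS})
    res = mantel_test(linearize_fst_matrix(fst), geo.reorder(CLUSTERS),
                      n_perm=9999, seed=1)
    print(f"Mantel IBD: r={res['r']:.3f} R2={res['R2']:.3f} p={res['p']:.4f}")
    (out / "ibd.json").write_text(json.dumps(res, indent=1, sort_keys=True))


if __name__ == "__main__":
    main()
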