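"""Synthetic diploid genotype cohorts with QC truth labels.

This is the synthetic stand-in for a capture-sequencing SNP dataset: a
cohort of sampling groups nested in genetic clusters, genotyped at
independent biallelic SNPs drawn from a coalescent demography.  Each site
is one segregating site of its own genealogy; haploid sample lineages are
paired into diploid individuals within demes, which yields Hardy-Weinberg
genotypes within each simulated frequency automatically.

The generator also plants the failure modes the QC stage must detect, with
truth labels carried in the metadata tables:

* per-site variant-calling annotations (QUAL, FS, QD, MQ, MQRankSum,
  ReadPosRankSum) drawn from pass/fail mixtures, with the failing rule
  recorded per site;
* low-depth and high-missingness individuals;
* first-degree relatives built by Mendelian transmission from a sampled
  parent and a synthetic unsampled mate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .coalescent import locus_rng, simulate_branches, _prepare
from .demography import Demography

__all__ = ["GenotypeMatrix", "simulate_genotype_matrix"]

ANNOTATIONS = ("QUAL", "FS", "QD", "MQ", "MQRankSum", "ReadPosRankSum")

# pass/fail sampling ranges per annotation (low, high); failures land
# strictly on the removal side of the corresponding hard threshold
_PASS_RANGES = {
    "QUAL": (60.0, 3000.0),
    "FS": (0.0, 30.0),
    "QD": (2.0, 35.0),
    "MQ": (40.0, 60.0),
    "MQRankSum": (-5.0, 5.0),
    "ReadPosRankSum": (-4.0, 4.0),
}
_FAIL_RANGES = {
    "QUAL": (5.0, 59.5),
    "FS": (60.5, 200.0),
    "QD": (0.1, 1.95),
    "MQ": (10.0, 39.5),
    "MQRankSum": (-40.0, -20.5),
    "ReadPosRankSum": (-15.0, -8.5),
}


@dataclass
class GenotypeMatrix:
    """Diploid genotypes plus per-site and per-individual metadata.

    ``genotypes``: individuals x sites, values 0/1/2 alt-allele dosage,
    -1 for missing.  ``sites`` carries chrom/pos/alleles and the filter
    annotations; ``individuals`` carries group, cluster, mean depth and
    (for synthetic cohorts) truth columns.
    """

    genotypes: np.ndarray
    sites: pd.DataFrame
    individuals: pd.DataFrame

    def __post_init__(self) -> None:
        n_ind, n_sites = self.genotypes.shape
        if len(self.individuals) != n_ind:
            raise ValueError("individuals table does not match genotype rows")
        if len(self.sites) != n_sites:
            raise ValueError("sites table does not match genotype columns")

    @property
    def ids(self) -> list[str]:
        return list(self.individuals["id"])

    def missing_fraction(self) -> pd.Series:
        frac = (self.genotypes < 0).mean(axis=1)
        return pd.Series(frac, index=self.individuals["id"], name="missing_fraction")

    def subset(self, ids: Sequence[str] | None = None, site_idx=None) -> "GenotypeMatrix":
        G = self.genotypes
        ind = self.individuals
        sites = self.sites
        if ids is not None:
            keep = ind["id"].isin(list(ids)).to_numpy()
            G = G[keep]
            ind = ind.loc[keep].reset_index(drop=True)
        if site_idx is not None:
            G = G[:, site_idx]
            sites = sites.iloc[site_idx].reset_index(drop=True)
        return GenotypeMatrix(G.copy(), sites, ind)


def simulate_genotype_matrix(
    demog: Demography,
    group_sizes: Mapping[str, int],
    n_sites: int,
    seed: int,
    group_to_deme: Mapping[str, str] | None = None,
    missing_rate: float = 0.0,
    relative_pairs: int = 0,
    n_low_depth: int = 0,
    n_high_missing: int = 0,
    site_fail_rate: float = 0.0,
    n_chromosomes: int = 20,
    mean_site_spacing_bp: int = 4000,
    max_steps: int = 1_000_000,
) -> GenotypeMatrix:
    """Simulate a cohort of diploid individuals at independent SNPs.

    ``group_sizes`` maps sampling-group labels to diploid counts;
    ``group_to_deme`` maps each group to a deme of ``demog`` (identity by
    default).  ``site_fail_rate`` is the per-annotation-rule probability
    that a site is generated as failing that rule (truth in
    ``sites["truth_fail_rule"]``).  ``relative_pairs`` individuals are
    regenerated as Mendelian offspring of a sampled parent (truth in
    ``individuals["truth_parent"]``).  Low-depth individuals get mean
    depth below 4; high-missingness individuals exceed 30% missing calls.
    """
    group_to_deme = dict(group_to_deme or {g: g for g in group_sizes})
    idx = demog.index
    for g, d in group_to_deme.items():
        if d not in idx:
            raise KeyError(f"group {g!r} maps to unknown deme {d!r}")
    for g in group_sizes:
        if g not in group_to_deme:
            raise KeyError(f"group {g!r} has no deme mapping")

    # diploids per deme, and the individual layout (deme-major, group-major)
    groups = list(group_sizes)
    deme_diploids: dict[str, int] = {}
    for g in groups:
        deme_diploids[group_to_deme[g]] = deme_diploids.get(group_to_deme[g], 0) + int(
            group_sizes[g]
        )
    demog = demog.with_samples(deme_diploids)
    deme_order = [d.label for d in demog.demes if d.n_samples > 0]

    ind_rows = []
    for deme in deme_order:
        for g in groups:
            if group_to_deme[g] != deme:
                continue
            for k in range(int(group_sizes[g])):
                ind_rows.append({"id": f"{g}_{k + 1:02d}", "group": g, "cluster": deme})
    individuals = pd.DataFrame(ind_rows)
    n_ind = len(individuals)
    n_hap = 2 * n_ind

    # haplotypes: one genealogy per site, one segregating mutation placed
    # proportionally to branch length
    prep = _prepare(demog)
    nbytes = (n_hap + 7) // 8
    H = np.zeros((n_sites, n_hap), dtype=np.uint8)
    for s in range(n_sites):
        rng = locus_rng(seed, s)
        branches = simulate_branches(
            demog, rng, max_steps=max_steps, track_leaves=True, _prep=prep
        )
        total = sum(b[1] for b in branches)
        u = rng.random() * total
        acc = 0.0
        mask = branches[-1][0]
        for cfg, length in branches:
            acc += length
            if u < acc:
                mask = cfg
                break
        bits = np.unpackbits(
            np.frombuffer(mask.to_bytes(nbytes, "little"), dtype=np.uint8),
            bitorder="little",
        )
        H[s] = bits[:n_hap]
    G = (H[:, 0::2] + H[:, 1::2]).T.astype(np.int8)  # individuals x sites

    root = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(2**30 + 7,)))

    # planted parent-offspring pairs: replace one individual per pair with a
    # Mendelian child of a sampled parent and an unsampled mate drawn from
    # the group's allele frequencies
    individuals["truth_parent"] = None
    by_group = individuals.groupby("group", sort=False).indices
    slots: list[tuple[int, int]] = []
    for g in groups:
        members = list(by_group.get(g, []))
        for a, b in zip(members[0::2], members[1::2]):
            slots.append((int(a), int(b)))
    if relative_pairs > len(slots):
        raise ValueError(
            f"cannot plant {relative_pairs} parent-offspring pairs: "
            f"only {len(slots)} disjoint within-group pairs available"
        )
    for parent, child in slots[:relative_pairs]:
        cluster = individuals.loc[child, "cluster"]
        in_cluster = (individuals["cluster"] == cluster).to_numpy()
        freq = G[in_cluster].mean(axis=0) / 2.0
        from_parent = np.where(
            G[parent] == 1, root.integers(0, 2, n_sites).astype(np.int8), (G[parent] // 2)
        )
        from_mate = (root.random(n_sites) < freq).astype(np.int8)
        G[child] = from_parent + from_mate
        individuals.loc[child, "truth_parent"] = individuals.loc[parent, "id"]

    # per-individual depth, with planted low-depth failures
    depth = root.gamma(shape=8.0, scale=2.8, size=n_ind)  # mean ~22x
    depth = np.maximum(depth, 4.2)
    individuals["truth_low_depth"] = False
    individuals["truth_high_missing"] = False
    # keep the planted failure sets disjoint: each QC stage gets its own signal
    in_pairs = {i for pair in slots[:relative_pairs] for i in pair}
    candidates = np.array([i for i in range(n_ind) if i not in in_pairs])
    if n_low_depth + n_high_missing > len(candidates):
        raise ValueError("too many planted low-quality individuals for cohort size")
    fail_ids = root.choice(candidates, size=n_low_depth + n_high_missing, replace=False)
    low_depth_ids = fail_ids[:n_low_depth]
    high_missing_ids = fail_ids[n_low_depth:]
    depth[low_depth_ids] = root.uniform(1.0, 3.9, size=n_low_depth)
    individuals.loc[low_depth_ids, "truth_low_depth"] = True
    individuals.loc[high_missing_ids, "truth_high_missing"] = True
    individuals["mean_depth"] = np.round(depth, 2)

    # missingness: baseline rate everywhere, elevated for planted individuals
    miss = root.random((n_ind, n_sites)) < missing_rate
    if len(high_missing_ids):
        extra = root.random((len(high_missing_ids), n_sites)) < 0.45
        miss[high_missing_ids] |= extra
    G[miss] = -1

    sites = _make_sites(
        G, n_sites, root, site_fail_rate, n_chromosomes, mean_site_spacing_bp
    )
    return GenotypeMatrix(G, sites, individuals)


def _make_sites(G, n_sites, root, site_fail_rate, n_chromosomes, spacing):
    per_chrom = int(np.ceil(n_sites / n_chromosomes))
    chroms, positions = [], []
    for c in range(1, n_chromosomes + 1):
        k = min(per_chrom, n_sites - len(chroms))
        if k <= 0:
            break
        gaps = root.integers(200, 2 * spacing, size=k)
        pos = np.cumsum(gaps)
        chroms += [f"chr{c}"] * k
        positions += list(pos)
    bases = np.array(list("ACGT"))
    ref_i = root.integers(0, 4, n_sites)
    alt_i = (ref_i + root.integers(1, 4, n_sites)) % 4

    cols: dict[str, np.ndarray] = {}
    truth = np.array([None] * n_sites, dtype=object)
    for ann in ANNOTATIONS:
        lo, hi = _PASS_RANGES[ann]
        cols[ann] = np.round(root.uniform(lo, hi, n_sites), 3)
    if site_fail_rate > 0:
        for ann in ANNOTATIONS:
            fail = (root.random(n_sites) < site_fail_rate) & (truth == None)  # noqa: E711
            lo, hi = _FAIL_RANGES[ann]
            cols[ann][fail] = np.round(root.uniform(lo, hi, int(fail.sum())), 3)
            truth[fail] = ann
    # GATK emits RankSum annotations only for sites carrying a heterozygote
    has_het = (G == 1).any(axis=0)
    for ann in ("MQRankSum", "ReadPosRankSum"):
        cols[ann] = np.where(has_het, cols[ann], np.nan)
        truth[(~has_het) & (truth == ann)] = None
    return pd.DataFrame(
        {
            "chrom": chroms,
            "pos": np.asarray(positions, dtype=np.int64),
            "ref": bases[ref_i],
            "alt": bases[alt_i],
            **cols,
            "truth_fail_rule": truth,
        }
    )
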