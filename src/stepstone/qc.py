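"""Site and individual hard filters, kinship pruning, and panel design.

Filtering conventions: the removal conditions are strict inequalities
(QUAL < 60 removes, QUAL = 60 passes), matching how variant-calling hard
filters are customarily stated; a site failing several rules is attributed
to the first failing rule in the documented order.  Annotations missing on
a record (RankSum statistics exist only for sites carrying a heterozygote)
cause that rule to be skipped for that record.

Kinship uses the KING-robust between-family estimator over pairwise-
complete sites:

    phi = (N_het,het - 2 * N_opposing-hom) / (N_het(i) + N_het(j))

First-degree pairs (phi > 0.177) are broken by greedy maximum-degree
removal, ties by higher missingness then label order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix

__all__ = [
    "SiteFilterThresholds",
    "FilterReport",
    "KinshipMatrix",
    "filter_sites",
    "filter_individuals",
    "hwe_exact_test",
    "king_kinship",
    "prune_first_degree",
    "design_panel",
    "merge_intervals",
]

FIRST_DEGREE_KINSHIP = 0.177


@dataclass(frozen=True)
class SiteFilterThresholds:
    """Hard-filter thresholds; values exactly at a threshold pass."""

    qual_min: float = 60.0
    fs_max: float = 60.0
    qd_min: float = 2.0
    mq_min: float = 40.0
    mq_rank_sum_min: float = -20.0
    read_pos_rank_sum_min: float = -8.0
    maf_min: float = 0.05
    max_site_missing: float = 0.20


@dataclass
class FilterReport:
    """Per-rule removal counts, in order of attribution."""

    stage: str
    n_input: int
    n_output: int
    removed: dict[str, int] = field(default_factory=dict)
    skipped_annotations: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if sum(self.removed.values()) != self.n_input - self.n_output:
            raise ValueError("removal counts must sum to n_input - n_output")

    def to_dict(self) -> dict:
        return {
            "stage": self.stage,
            "n_input": self.n_input,
            "n_output": self.n_output,
            "removed": dict(self.removed),
            "skipped_annotations": dict(self.skipped_annotations),
        }

    def __str__(self) -> str:
        lines = [f"[{self.stage}] {self.n_input} -> {self.n_output}"]
        for rule, n in self.removed.items():
            lines.append(f"  {rule:<22s} -{n}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# Site filters


def _site_fail_matrix(sites: pd.DataFrame, G: np.ndarray, thr: SiteFilterThresholds):
    """Ordered (rule, fail-vector) pairs plus skipped-annotation counts."""
    n = len(sites)

    def col(name):
        return sites[name].to_numpy(dtype=float) if name in sites else np.full(n, np.nan)

    checks = [
        ("QUAL", col("QUAL") < thr.qual_min),
        ("FS", col("FS") > thr.fs_max),
        ("QD", col("QD") < thr.qd_min),
        ("MQ", col("MQ") < thr.mq_min),
        ("MQRankSum", col("MQRankSum") < thr.mq_rank_sum_min),
        ("ReadPosRankSum", col("ReadPosRankSum") < thr.read_pos_rank_sum_min),
    ]
    skipped = {}
    rules = []
    for name, fail in checks:
        nan = np.isnan(col(name))
        if nan.any():
            skipped[name] = int(nan.sum())
        rules.append((name, np.where(nan, False, fail)))

    miss = (G < 0).mean(axis=0)
    rules.append(("site_missing", miss > thr.max_site_missing))

    maf = site_maf(G)
    rules.append(("MAF", np.where(np.isnan(maf), True, maf < thr.maf_min)))
    return rules, skipped


def site_maf(G: np.ndarray) -> np.ndarray:
    """Minor-allele frequency per site over non-missing genotypes (NaN if
    no calls)."""
    called = (G >= 0).sum(axis=0)
    alt = np.where(G > 0, G, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = alt / (2.0 * called)
    p = np.where(called > 0, p, np.nan)
    return np.minimum(p, 1.0 - p)


def filter_sites(
    gm: GenotypeMatrix, thresholds: SiteFilterThresholds | None = None
) -> tuple[GenotypeMatrix, FilterReport]:
    """Apply the site-level hard filters; remove a site if it fails ANY
    rule, attributing it to the first failing rule in documented order."""
    thr = thresholds or SiteFilterThresholds()
    rules, skipped = _site_fail_matrix(gm.sites, gm.genotypes, thr)
    fail = np.stack([f for _, f in rules])
    any_fail = fail.any(axis=0)
    first = fail.argmax(axis=0)
    removed = {}
    for r, (name, _) in enumerate(rules):
        removed[name] = int((any_fail & (first == r)).sum())
    keep = np.flatnonzero(~any_fail)
    report = FilterReport(
        stage="site_filters",
        n_input=len(gm.sites),
        n_output=len(keep),
        removed=removed,
        skipped_annotations=skipped,
    )
    return gm.subset(site_idx=keep), report


def filter_individuals(
    gm: GenotypeMatrix, min_mean_depth: float = 4.0, max_missing: float = 0.30
) -> tuple[GenotypeMatrix, FilterReport]:
    """Remove individuals with mean depth < 4 or missing fraction > 0.30."""
    depth = gm.individuals["mean_depth"].to_numpy(dtype=float)
    miss = (gm.genotypes < 0).mean(axis=1)
    low_depth = depth < min_mean_depth
    high_miss = miss > max_missing
    drop = low_depth | high_miss
    removed = {
        "low_depth": int(low_depth.sum()),
        "high_missing": int((high_miss & ~low_depth).sum()),
    }
    keep_ids = [i for i, d in zip(gm.individuals["id"], drop) if not d]
    report = FilterReport(
        stage="individual_filters",
        n_input=len(gm.individuals),
        n_output=len(keep_ids),
        removed=removed,
    )
    return gm.subset(ids=keep_ids), report


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test


@lru_cache(maxsize=100_000)
def _het_distribution(n: int, n_a: int) -> tuple[np.ndarray, np.ndarray]:
    """Probabilities of each heterozygote count given n diploids and n_a
    copies of the rarer allele, under the exact conditional (Levene)
    distribution.  Returns (het_counts, probabilities)."""
    parity = n_a % 2
    hets = np.arange(parity, min(n_a, 2 * n - n_a) + 1, 2)
    # recurrence on P(h+2)/P(h) avoids factorial overflow
    probs = np.zeros(len(hets))
    mid = len(hets) // 2
    probs[mid] = 1.0
    for k in range(mid, len(hets) - 1):
        h = hets[k]
        n_aa = (n_a - h) // 2
        n_bb = n - n_aa - h
        probs[k + 1] = probs[k] * 4.0 * n_aa * n_bb / ((h + 2.0) * (h + 1.0))
    for k in range(mid, 0, -1):
        h = hets[k]
        n_aa = (n_a - h) // 2
        n_bb = n - n_aa - h
        probs[k - 1] = probs[k] * h * (h - 1.0) / (4.0 * (n_aa + 1.0) * (n_bb + 1.0))
    probs /= probs.sum()
    return hets, probs


def hwe_exact_test(n_aa_hom: int, n_het: int, n_bb_hom: int) -> float:
    """Two-sided exact Hardy-Weinberg p-value.

    Sums the probabilities of all heterozygote counts (conditional on the
    allele counts) whose probability does not exceed that of the observed
    count.  Monomorphic sites have a single attainable configuration and
    return 1.0.
    """
    if min(n_aa_hom, n_het, n_bb_hom) < 0:
        raise ValueError("genotype counts must be >= 0")
    n = n_aa_hom + n_het + n_bb_hom
    if n < 1:
        raise ValueError("need at least one genotyped individual")
    n_a = 2 * n_aa_hom + n_het
    n_b = 2 * n_bb_hom + n_het
    rare = min(n_a, n_b)
    if rare == 0:
        return 1.0
    hets, probs = _het_distribution(n, rare)
    p_obs = probs[np.searchsorted(hets, n_het)]
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))


def hwe_pvalues(G: np.ndarray) -> np.ndarray:
    """Exact HWE p-value per site of a genotype matrix (missing ignored)."""
    out = np.ones(G.shape[1])
    for s in range(G.shape[1]):
        g = G[:, s]
        g = g[g >= 0]
        if g.size:
            out[s] = hwe_exact_test(
                int((g == 0).sum()), int((g == 1).sum()), int((g == 2).sum())
            )
    return out


# ---------------------------------------------------------------------------
# Kinship


@dataclass
class KinshipMatrix:
    """Symmetric pairwise KING-robust kinship; NaN where a pair shares no
    complete sites (diagonal holds self-kinship, 0.5 by convention)."""

    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.ids), len(self.ids)):
            raise ValueError("kinship matrix shape must match ids")
        if not np.allclose(v, v.T, equal_nan=True):
            raise ValueError("kinship matrix must be symmetric")
        self.values = v

    def pairs_above(self, threshold: float) -> list[tuple[str, str, float]]:
        out = []
        n = len(self.ids)
        for i in range(n):
            for j in range(i + 1, n):
                phi = self.values[i, j]
                if np.isfinite(phi) and phi > threshold:
                    out.append((self.ids[i], self.ids[j], float(phi)))
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)


def king_kinship(gm: GenotypeMatrix | np.ndarray, ids: Sequence[str] | None = None) -> KinshipMatrix:
    """KING-robust between-family kinship for all pairs.

    phi = (N_double-het - 2 * N_opposing-hom) / (N_het_i + N_het_j), with
    all counts taken over sites non-missing in both individuals.
    """
    if isinstance(gm, GenotypeMatrix):
        G = gm.genotypes
        ids = list(gm.ids)
    else:
        G = np.asarray(gm)
        ids = list(ids) if ids is not None else [f"ind{i}" for i in range(G.shape[0])]
    called = (G >= 0)
    H = ((G == 1) & called).astype(np.int64)
    A0 = (G == 0).astype(np.int64)
    A2 = (G == 2).astype(np.int64)
    Cm = called.astype(np.int64)

    n_hh = H @ H.T
    n_opp = A0 @ A2.T
    n_opp = n_opp + n_opp.T
    het_in_pair = H @ Cm.T  # het calls of i over sites also called in j
    denom = het_in_pair + het_in_pair.T
    overlap = Cm @ Cm.T
    with np.errstate(invalid="ignore", divide="ignore"):
        phi = (n_hh - 2.0 * n_opp) / denom
    phi = np.where((overlap > 0) & (denom > 0), phi, np.nan)
    np.fill_diagonal(phi, 0.5)
    return KinshipMatrix(ids=ids, values=phi)


def prune_first_degree(
    kinship: KinshipMatrix,
    threshold: float = FIRST_DEGREE_KINSHIP,
    missingness: Mapping[str, float] | None = None,
) -> list[str]:
    """Greedy minimal pruning of individuals until no pair exceeds the
    first-degree kinship threshold.

    Repeatedly removes the individual incident to the most flagged pairs;
    ties go to the individual with higher missingness, then later label in
    sort order.  Returns the kept ids in input order.
    """
    miss = dict(missingness or {})
    flagged = {
        frozenset((a, b)) for a, b, _ in kinship.pairs_above(threshold)
    }
    removed: set[str] = set()
    while True:
        live = {p for p in flagged if not (p & removed)}
        if not live:
            break
        degree: dict[str, int] = {}
        for pair in live:
            for x in pair:
                degree[x] = degree.get(x, 0) + 1
        worst = max(
            degree, key=lambda x: (degree[x], miss.get(x, 0.0), x)
        )
        removed.add(worst)
    return [i for i in kinship.ids if i not in removed]


# ---------------------------------------------------------------------------
# Panel design


def merge_intervals(intervals: Sequence[tuple[str, int, int]]):
    """Normalize 0-based half-open intervals: sort and merge overlaps.
    Returns (merged dict chrom -> (starts, ends) arrays, n_merged)."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, start, end in intervals:
        if end < start:
            raise ValueError(f"malformed interval {chrom}:{start}-{end}")
        by_chrom.setdefault(chrom, []).append((int(start), int(end)))
    merged: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    n_merged = 0
    for chrom, ivs in by_chrom.items():
        ivs.sort()
        out = [list(ivs[0])]
        for s, e in ivs[1:]:
            if s <= out[-1][1]:
                out[-1][1] = max(out[-1][1], e)
                n_merged += 1
            else:
                out.append([s, e])
        starts = np.array([s for s, _ in out])
        ends = np.array([e for _, e in out])
        merged[chrom] = (starts, ends)
    return merged, n_merged


def _in_mask(chrom: np.ndarray, pos: np.ndarray, merged) -> np.ndarray:
    """Membership of 1-based positions in merged 0-based half-open mask."""
    hit = np.zeros(len(pos), dtype=bool)
    for c in np.unique(chrom):
        if c not in merged:
            continue
        starts, ends = merged[c]
        sel = chrom == c
        p0 = pos[sel] - 1  # to 0-based
        k = np.searchsorted(starts, p0, side="right") - 1
        ok = (k >= 0) & (p0 < ends[np.clip(k, 0, len(ends) - 1)])
        hit[sel] = ok
    return hit


_NON_AUTOSOMAL = {"x", "y", "chrx", "chry", "mt", "chrm", "chrmt", "m"}


def design_panel(
    gm: GenotypeMatrix,
    gene_mask: Sequence[tuple[str, int, int]] = (),
    cpg_mask: Sequence[tuple[str, int, int]] = (),
    maf_min: float = 0.05,
    hwe_alpha: float = 0.001,
    thin_bp: int = 10_000,
) -> tuple[np.ndarray, FilterReport]:
    """Neutral SNP-panel selection.

    Applies, in order: autosomal-biallelic restriction, gene-mask
    exclusion, CpG-mask exclusion, complete-genotyping requirement,
    MAF >= maf_min, HWE p >= hwe_alpha, then per-chromosome thinning to
    one SNP per ``thin_bp`` window (windows anchored at position 1, first
    site per window kept).  Returns (kept site indices, report).
    """
    sites = gm.sites
    G = gm.genotypes
    chrom = sites["chrom"].to_numpy(dtype=object)
    pos = sites["pos"].to_numpy(dtype=np.int64)
    n = len(sites)
    alive = np.ones(n, dtype=bool)
    removed: dict[str, int] = {}

    def apply(rule: str, bad: np.ndarray) -> None:
        kill = alive & bad
        removed[rule] = int(kill.sum())
        alive[kill] = False

    chrom_l = np.array([str(c).lower() for c in chrom])
    apply("non_autosomal", np.isin(chrom_l, sorted(_NON_AUTOSOMAL)))
    if "ref" in sites and "alt" in sites:
        apply("non_biallelic", np.array([("," in str(a)) for a in sites["alt"]]))
    else:
        removed["non_biallelic"] = 0
    gm_merged, _ = merge_intervals(gene_mask)
    apply("gene_mask", _in_mask(chrom, pos, gm_merged))
    cpg_merged, _ = merge_intervals(cpg_mask)
    apply("cpg_mask", _in_mask(chrom, pos, cpg_merged))
    apply("incomplete_genotyping", (G < 0).any(axis=0))
    maf = site_maf(G)
    apply("MAF", np.where(np.isnan(maf), True, maf < maf_min))
    pvals = np.ones(n)
    idx_alive = np.flatnonzero(alive)
    pvals[idx_alive] = hwe_pvalues(G[:, idx_alive])
    apply("HWE", pvals < hwe_alpha)

    # thinning: first surviving SNP per (chrom, window)
    thin_kill = np.zeros(n, dtype=bool)
    seen: set[tuple[str, int]] = set()
    order = np.lexsort((pos, chrom_l))
    for i in order[alive[order]]:
        key = (chrom[i], int((pos[i] - 1) // thin_bp))
        if key in seen:
            thin_kill[i] = True
        else:
            seen.add(key)
    apply("thinning", thin_kill)

    keep = np.flatnonzero(alive)
    report = FilterReport(
        stage="panel_design", n_input=n, n_output=len(keep), removed=removed
    )
    return keep, report
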