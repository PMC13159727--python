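"""Heterozygosity, Weir-Cockerham F_ST, geographic distance and Mantel IBD.

F_ST uses the Weir & Cockerham (1984) estimator with multilocus
ratio-of-averages aggregation (sum of a-components over sum of a+b+c),
computed from genotype counts so within-individual heterozygosity enters
the variance decomposition.  Estimates can be slightly negative; they are
reported as-is and clamped to zero only when linearized to the genetic
distance F_ST / (1 - F_ST).

Isolation by distance is tested with a one-sided Mantel permutation test
(positive association) between linearized F_ST and great-circle
geographic distance.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DistanceMatrix",
    "observed_heterozygosity",
    "pairwise_fst",
    "wc_fst",
    "linearize_fst",
    "geographic_distances",
    "mantel_test",
]

EARTH_RADIUS_KM = 6371.0088


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distances with a kind tag."""

    labels: list[str]
    values: np.ndarray
    kind: str = "generic"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if v.shape != (n, n):
            raise ValueError("distance matrix shape must match labels")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0):
            raise ValueError("distance matrix diagonal must be zero")
        self.values = v

    def upper(self) -> np.ndarray:
        iu = np.triu_indices(len(self.labels), k=1)
        return self.values[iu]

    def reorder(self, labels: Sequence[str]) -> "DistanceMatrix":
        idx = [self.labels.index(l) for l in labels]
        return DistanceMatrix(list(labels), self.values[np.ix_(idx, idx)], self.kind)

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(self.values, index=self.labels, columns=self.labels).to_csv(
            path, sep="\t", float_format="%.10g"
        )

    @classmethod
    def from_tsv(cls, path: str | Path, kind: str = "generic") -> "DistanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(list(df.index.astype(str)), df.to_numpy(dtype=float), kind)


def observed_heterozygosity(genotypes: np.ndarray, ids: Sequence[str] | None = None) -> pd.Series:
    """Per-individual observed heterozygosity: heterozygous calls over
    non-missing calls.  Raises if any individual has no calls at all."""
    G = np.asarray(genotypes)
    called = (G >= 0).sum(axis=1)
    if (called == 0).any():
        bad = np.flatnonzero(called == 0)
        raise ValueError(f"individual(s) with no non-missing genotypes: {bad.tolist()}")
    het = (G == 1).sum(axis=1)
    idx = list(ids) if ids is not None else list(range(G.shape[0]))
    return pd.Series(het / called, index=idx, name="Ho")


def _wc_components(g1: np.ndarray, g2: np.ndarray):
    """Per-locus Weir-Cockerham (1984) a, b, c variance components for two
    populations of diploid genotypes (rows: individuals; -1 missing)."""
    r = 2.0
    n1 = (g1 >= 0).sum(axis=0).astype(float)
    n2 = (g2 >= 0).sum(axis=0).astype(float)
    usable = (n1 >= 1) & (n2 >= 1) & (n1 + n2 >= 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        p1 = np.where(g1 > 0, g1, 0).sum(axis=0) / (2 * n1)
        p2 = np.where(g2 > 0, g2, 0).sum(axis=0) / (2 * n2)
        h1 = (g1 == 1).sum(axis=0) / n1
        h2 = (g2 == 1).sum(axis=0) / n2
        n_bar = (n1 + n2) / r
        n_c = (r * n_bar - (n1**2 + n2**2) / (r * n_bar)) / (r - 1.0)
        p_bar = (n1 * p1 + n2 * p2) / (r * n_bar)
        s2 = (n1 * (p1 - p_bar) ** 2 + n2 * (p2 - p_bar) ** 2) / ((r - 1.0) * n_bar)
        h_bar = (n1 * h1 + n2 * h2) / (r * n_bar)
        inner = p_bar * (1 - p_bar) - (r - 1.0) / r * s2
        a = n_bar / n_c * (s2 - (inner - h_bar / 4.0) / (n_bar - 1.0))
        b = n_bar / (n_bar - 1.0) * (inner - (2.0 * n_bar - 1.0) / (4.0 * n_bar) * h_bar)
        c = h_bar / 2.0
    # loci with n_bar == 1 or no usable data are dropped
    ok = usable & (n1 + n2 > 2) & np.isfinite(a) & np.isfinite(b) & np.isfinite(c)
    return a, b, c, ok


def wc_fst(g1: np.ndarray, g2: np.ndarray) -> float:
    """Multilocus Weir-Cockerham F_ST between two populations
    (ratio of averages: sum(a) / sum(a+b+c) over usable loci)."""
    g1 = np.atleast_2d(np.asarray(g1))
    g2 = np.atleast_2d(np.asarray(g2))
    if g1.shape[0] < 2 or g2.shape[0] < 2:
        raise ValueError("each population needs at least two individuals")
    a, b, c, ok = _wc_components(g1, g2)
    denom = (a + b + c)[ok].sum()
    if denom == 0:
        return 0.0
    return float(a[ok].sum() / denom)


def pairwise_fst(
    genotypes: np.ndarray,
    individual_pops: Sequence[str],
    populations: Sequence[str] | None = None,
) -> DistanceMatrix:
    """Pairwise multilocus Weir-Cockerham F_ST between all populations."""
    pops = list(populations) if populations is not None else sorted(set(individual_pops))
    G = np.asarray(genotypes)
    rows = {p: G[np.array([q == p for q in individual_pops])] for p in pops}
    for p, g in rows.items():
        if g.shape[0] < 2:
            raise ValueError(f"population {p!r} has fewer than two individuals")
    n = len(pops)
    out = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        f = wc_fst(rows[pops[i]], rows[pops[j]])
        out[i, j] = out[j, i] = f
    return DistanceMatrix(pops, out, kind="fst")


def linearize_fst(f: float | np.ndarray):
    """Genetic distance F_ST / (1 - F_ST); negative inputs clamp to 0.

    Accepts scalars or arrays; F_ST = 1 raises (infinite distance)."""
    arr = np.asarray(f, dtype=float)
    if (arr >= 1.0).any():
        raise ValueError("F_ST = 1 gives infinite genetic distance")
    clamped = np.maximum(arr, 0.0)
    out = clamped / (1.0 - clamped)
    return float(out) if np.isscalar(f) or arr.ndim == 0 else out


def linearize_fst_matrix(d: DistanceMatrix) -> DistanceMatrix:
    return DistanceMatrix(d.labels, linearize_fst(d.values), kind="fst_linearized")


def geographic_distances(coords: Mapping[str, tuple[float, float]] | pd.DataFrame) -> DistanceMatrix:
    """Great-circle (haversine) distances in km from (lat, lon) degrees."""
    if isinstance(coords, pd.DataFrame):
        coords = {
            str(row["label"]): (float(row["lat"]), float(row["lon"]))
            for _, row in coords.iterrows()
        }
    labels = list(coords)
    for lab, (lat, lon) in coords.items():
        if not (-90.0 <= lat <= 90.0 and -180.0 <= lon <= 360.0):
            raise ValueError(f"{lab}: coordinates out of range: lat={lat}, lon={lon}")
    n = len(labels)
    out = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        out[i, j] = out[j, i] = _haversine_km(coords[labels[i]], coords[labels[j]])
    return DistanceMatrix(labels, out, kind="geographic_km")


def _haversine_km(a: tuple[float, float], b: tuple[float, float]) -> float:
    lat1, lon1 = map(math.radians, a)
    lat2, lon2 = map(math.radians, b)
    s = (
        math.sin((lat2 - lat1) / 2.0) ** 2
        + math.cos(lat1) * math.cos(lat2) * math.sin((lon2 - lon1) / 2.0) ** 2
    )
    return 2.0 * EARTH_RADIUS_KM * math.asin(min(1.0, math.sqrt(s)))


def mantel_test(
    d_gen: DistanceMatrix,
    d_geo: DistanceMatrix,
    n_perm: int = 999,
    seed: int = 0,
    method: str = "permutation",
) -> dict:
    """One-sided Mantel test for positive matrix association.

    r is the Pearson correlation of the off-diagonal upper triangles; the
    p-value permutes the row/column labels of the second matrix jointly:
    p = (1 + #{r_perm >= r_obs}) / (n_perm + 1).  ``method="exact"``
    enumerates all label permutations instead (p = #{r_perm >= r_obs} /
    n!, identity included; feasible for few labels).
    """
    if set(d_gen.labels) != set(d_geo.labels):
        raise ValueError("matrices must share the same labels")
    d_geo = d_geo.reorder(d_gen.labels)
    n = len(d_gen.labels)
    if n < 3:
        raise ValueError("Mantel test needs at least three labels")
    x = d_gen.upper()
    B = d_geo.values
    y = d_geo.upper()
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("constant distance matrix: correlation undefined")
    iu = np.triu_indices(n, k=1)
    r_obs = _pearson(x, y)

    if method == "exact":
        if n > 8:
            raise ValueError("exact enumeration is limited to <= 8 labels")
        count = 0
        total = 0
        for perm in itertools.permutations(range(n)):
            yp = B[np.ix_(perm, perm)][iu]
            total += 1
            if _pearson(x, yp) >= r_obs - 1e-12:
                count += 1
        p = count / total
    elif method == "permutation":
        if n_perm < 99:
            raise ValueError("use at least 99 permutations")
        rng = np.random.default_rng(np.random.SeedSequence(seed))
        count = 0
        for _ in range(n_perm):
            perm = rng.permutation(n)
            yp = B[np.ix_(perm, perm)][iu]
            if _pearson(x, yp) >= r_obs - 1e-12:
                count += 1
        p = (1.0 + count) / (n_perm + 1.0)
    else:
        raise ValueError(f"unknown method {method!r}")
    return {"r": float(r_obs), "R2": float(r_obs**2), "p": float(p), "n_perm": n_perm}


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    return float((xc @ yc) / np.sqrt((xc @ xc) * (yc @ yc)))
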