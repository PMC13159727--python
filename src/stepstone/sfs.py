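"""Joint site-frequency spectra: construction, folding, projection, I/O.

An :class:`SFS` is a dense array over per-population allele counts: axis
``k`` has length ``n_k + 1`` where ``n_k`` is the haploid sample size of
population ``k``.  Entries are non-negative reals (hypergeometric
projection produces fractional expectations).  A folded spectrum is
indexed by minor-allele counts: every cell whose total derived count
exceeds half the total sample is folded onto its complement and zeroed.

Two on-disk dialects are supported: a JSON dialect carrying labels,
shape, fold flag and counts, and (for 1D/2D spectra) the fastsimcoal-style
whitespace text with a "1 observations" header line.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import hypergeom

__all__ = ["SFS", "joint_sfs", "polymorphic_mask"]


def polymorphic_mask(shape: Sequence[int]) -> np.ndarray:
    """Boolean mask that is False only at the two monomorphic corner cells
    (derived count zero everywhere / maximal everywhere)."""
    mask = np.ones(tuple(shape), dtype=bool)
    mask[tuple(0 for _ in shape)] = False
    mask[tuple(s - 1 for s in shape)] = False
    return mask


@dataclass
class SFS:
    """A joint site-frequency spectrum over one or more populations."""

    labels: tuple[str, ...]
    counts: np.ndarray
    folded: bool = False

    def __post_init__(self) -> None:
        self.labels = tuple(self.labels)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != len(self.labels):
            raise ValueError(
                f"{len(self.labels)} labels but counts has {self.counts.ndim} axes"
            )
        if (self.counts < 0).any():
            raise ValueError("SFS counts must be non-negative")

    # -- basic queries ------------------------------------------------------

    @property
    def n_haploid(self) -> tuple[int, ...]:
        return tuple(s - 1 for s in self.counts.shape)

    def total(self) -> float:
        return float(self.counts.sum())

    def monomorphic_mass(self) -> float:
        return float(self.counts[~polymorphic_mask(self.counts.shape)].sum())

    def polymorphic_mass(self) -> float:
        return float(self.counts[polymorphic_mask(self.counts.shape)].sum())

    def axis(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"population {label!r} not in SFS {self.labels}") from None

    # -- transforms ---------------------------------------------------------

    def fold(self) -> "SFS":
        """Fold onto minor-allele counts (no-op on an already folded SFS)."""
        if self.folded:
            return SFS(self.labels, self.counts.copy(), folded=True)
        rev = self.counts[tuple(slice(None, None, -1) for _ in self.counts.shape)]
        folded = self.counts + rev
        tot = _total_count_grid(self.counts.shape)
        half = sum(self.n_haploid) / 2.0
        folded[tot > half] = 0.0
        folded[tot == half] *= 0.5
        return SFS(self.labels, folded, folded=True)

    def marginalize(self, keep: Sequence[str]) -> "SFS":
        """Sum over all populations not in ``keep`` (mass conserved)."""
        if not keep:
            raise ValueError("must keep at least one population")
        axes_keep = [self.axis(lab) for lab in keep]
        if len(set(axes_keep)) != len(axes_keep):
            raise ValueError("duplicate labels in keep")
        drop = tuple(a for a in range(self.counts.ndim) if a not in axes_keep)
        counts = self.counts.sum(axis=drop) if drop else self.counts.copy()
        current = [lab for a, lab in enumerate(self.labels) if a in axes_keep]
        perm = [current.index(lab) for lab in keep]
        counts = np.transpose(counts, perm)
        return SFS(tuple(keep), counts, folded=self.folded)

    def project(self, target_sizes: Mapping[str, int]) -> "SFS":
        """Project to smaller haploid sample sizes by hypergeometric
        expectation (mass conserved; identity when sizes are unchanged)."""
        if self.folded:
            raise ValueError("project an unfolded SFS, then fold")
        counts = self.counts
        for lab, n_to in target_sizes.items():
            ax = self.axis(lab)
            n_from = self.counts.shape[ax] - 1
            if n_to > n_from:
                raise ValueError(
                    f"cannot project {lab} from {n_from} up to {n_to} haploids"
                )
            if n_to == n_from:
                continue
            # W[j, d] = P(j of n_to | d of n_from)
            d = np.arange(n_from + 1)
            j = np.arange(n_to + 1)
            W = hypergeom.pmf(j[:, None], n_from, d[None, :], n_to)
            counts = np.moveaxis(
                np.tensordot(W, np.moveaxis(counts, ax, 0), axes=(1, 0)), 0, ax
            )
        return SFS(self.labels, counts, folded=False)

    # -- I/O ----------------------------------------------------------------

    def to_json(self, path: str | Path | None = None) -> str:
        doc = {
            "labels": list(self.labels),
            "shape": list(self.counts.shape),
            "folded": self.folded,
            "counts": self.counts.ravel().tolist(),
        }
        text = json.dumps(doc, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "SFS":
        if isinstance(source, Path) or not str(source).lstrip().startswith("{"):
            text = Path(source).read_text()
        else:
            text = str(source)
        doc = json.loads(text)
        counts = np.asarray(doc["counts"], dtype=float).reshape(doc["shape"])
        return cls(tuple(doc["labels"]), counts, folded=bool(doc["folded"]))

    def to_fsc(self, path: str | Path) -> None:
        """fastsimcoal-style observed-SFS text (1D and 2D spectra only)."""
        tag = "M" if self.folded else "D"
        if self.counts.ndim == 1:
            header = "\t".join(f"d0_{i}" for i in range(self.counts.shape[0]))
            body = header + "\n" + "\t".join(_fmt(x) for x in self.counts) + "\n"
        elif self.counts.ndim == 2:
            header = "\t" + "\t".join(f"d0_{j}" for j in range(self.counts.shape[1]))
            rows = [
                f"d1_{i}\t" + "\t".join(_fmt(x) for x in self.counts[i])
                for i in range(self.counts.shape[0])
            ]
            body = header + "\n" + "\n".join(rows) + "\n"
        else:
            raise ValueError("fastsimcoal text supports 1D/2D only; use JSON")
        head = f"1 observations. Populations: {' '.join(self.labels)} [{tag}AF]\n"
        Path(path).write_text(head + body)

    @classmethod
    def from_fsc(cls, path: str | Path) -> "SFS":
        lines = [ln.rstrip("\n") for ln in Path(path).read_text().splitlines() if ln.strip()]
        if not lines[0].startswith("1 observations"):
            raise ValueError("not a fastsimcoal observed-SFS file")
        folded = "[MAF]" in lines[0]
        labels: tuple[str, ...]
        if "Populations:" in lines[0]:
            rest = lines[0].split("Populations:", 1)[1]
            labels = tuple(tok for tok in rest.replace("[MAF]", "").replace("[DAF]", "").split())
        else:
            labels = ()
        if lines[1].lstrip().startswith("d") and not lines[1].startswith("\t") and len(lines) == 3:
            counts = np.array([float(x) for x in lines[2].split()])
            labels = labels or ("pop0",)
            return cls(labels[:1], counts, folded=folded)
        rows = []
        for ln in lines[2:]:
            toks = ln.split()
            rows.append([float(x) for x in toks[1:]])
        counts = np.array(rows)
        labels = labels or ("pop1", "pop0")
        return cls(labels[:2], counts, folded=folded)

    def marginals_tsv(self, path: str | Path) -> None:
        """TSV of the 1D marginal spectrum of each population."""
        lines = ["population\tallele_count\tsites"]
        for lab in self.labels:
            marg = self.marginalize([lab]).counts
            for i, x in enumerate(marg):
                lines.append(f"{lab}\t{i}\t{_fmt(x)}")
        Path(path).write_text("\n".join(lines) + "\n")


def _fmt(x: float) -> str:
    return f"{int(x)}" if float(x).is_integer() else f"{x:.10g}"


def _total_count_grid(shape: Sequence[int]) -> np.ndarray:
    grids = np.indices(tuple(shape))
    return grids.sum(axis=0)


def joint_sfs(
    genotypes: np.ndarray,
    individual_pops: Sequence[str],
    populations: Sequence[str],
    folded: bool = False,
) -> SFS:
    """Joint SFS from a diploid genotype matrix (complete-case per site).

    ``genotypes`` is individuals x sites with values {0, 1, 2} and -1 for
    missing; ``individual_pops`` assigns each row to a population.  Only
    individuals whose population is in ``populations`` are used, and any
    site with a missing genotype among them is dropped.  Sites monomorphic
    in the retained sample land in the corner cells.
    """
    G = np.asarray(genotypes)
    pops = list(populations)
    ind_pops = list(individual_pops)
    if len(ind_pops) != G.shape[0]:
        raise ValueError("individual_pops length must match genotype rows")
    sel = np.array([p in pops for p in ind_pops])
    if not sel.any():
        raise ValueError("no individuals in the requested populations")
    Gs = G[sel]
    pop_of = np.array([pops.index(p) for p, s in zip(ind_pops, sel) if s])
    complete = ~(Gs < 0).any(axis=0)
    Gc = Gs[:, complete]
    shape = tuple(2 * int((pop_of == k).sum()) + 1 for k in range(len(pops)))
    for k, s in enumerate(shape):
        if s < 2:
            raise ValueError(f"population {pops[k]!r} has no genotyped individuals")
    counts = np.zeros(shape)
    if Gc.shape[1]:
        indicator = np.stack([(pop_of == k) for k in range(len(pops))]).astype(np.int64)
        alt = indicator @ Gc  # pops x sites
        flat = np.ravel_multi_index(tuple(alt), shape)
        np.add.at(counts.ravel(), flat, 1)
    out = SFS(tuple(pops), counts, folded=False)
    return out.fold() if folded else out
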