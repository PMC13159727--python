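"""End-to-end driver: cohort -> QC -> kinship -> panel -> SFS -> fit -> stats.

The pipeline consumes a :class:`RunConfig` (YAML-friendly, strict about
unknown keys), runs the enabled stages in order, and writes every result
as deterministic JSON/TSV under the output directory, together with a
manifest recording seeds, thresholds and per-stage counts.  Identical
configurations produce byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .genotypes import GenotypeMatrix, simulate_genotype_matrix
from .inference import compare_models, fit_with_restarts
from .models import build_named_model
from .qc import (
    SiteFilterThresholds,
    design_panel,
    filter_individuals,
    filter_sites,
    king_kinship,
    prune_first_degree,
)
from .sfs import joint_sfs
from .stats import (
    geographic_distances,
    linearize_fst_matrix,
    mantel_test,
    observed_heterozygosity,
    pairwise_fst,
)
from .vcfio import read_bed, read_coords, read_popmap, read_vcf, write_popmap, write_vcf

log = logging.getLogger("stepstone")

_DEFAULT_GROUPS: dict[str, dict[str, int]] = {
    # 20 sampling groups nested in the five genetic clusters
    "SW": {"SW1": 5, "SW2": 5, "SW3": 4},
    "SE": {"SE1": 5, "SE2": 4},
    "C": {"C1": 6, "C2": 5, "C3": 5, "C4": 4, "C5": 4, "C6": 4},
    "NC": {"NC1": 5, "NC2": 4, "NC3": 4, "NC4": 4},
    "N": {"N1": 5, "N2": 4, "N3": 4, "N4": 4, "N5": 4},
}

# cluster centroids (lat, lon) roughly along a south-to-north montane arc
_DEFAULT_COORDS: dict[str, tuple[float, float]] = {
    "SW": (26.2, 99.3),
    "SE": (26.6, 99.8),
    "C": (27.4, 99.5),
    "NC": (28.2, 99.2),
    "N": (28.9, 98.9),
}


@dataclass
class RunConfig:
    """Pipeline configuration; unknown keys are rejected on load."""

    seed: int = 1
    out_dir: str = "results/run"
    # input files; leave empty to simulate a synthetic cohort
    vcf: str | None = None
    popmap: str | None = None
    gene_mask_bed: str | None = None
    cpg_mask_bed: str | None = None
    coords_tsv: str | None = None
    # synthetic cohort scenario
    model: str = "model4_SE_NC_admix"
    model_params: dict[str, float] = field(default_factory=dict)
    groups: dict[str, dict[str, int]] = field(default_factory=lambda: _DEFAULT_GROUPS)
    n_sites: int = 5000
    missing_rate: float = 0.02
    relative_pairs: int = 2
    n_low_depth: int = 2
    n_high_missing: int = 2
    site_fail_rate: float = 0.01
    # stage toggles
    run_site_filters: bool = True
    run_individual_filters: bool = True
    run_kinship: bool = True
    run_panel: bool = True
    run_sfs: bool = True
    run_fit: bool = False
    run_stats: bool = True
    # thresholds
    site_thresholds: dict[str, float] = field(default_factory=dict)
    min_mean_depth: float = 4.0
    max_individual_missing: float = 0.30
    kinship_threshold: float = 0.177
    panel_maf_min: float = 0.05
    panel_hwe_alpha: float = 0.001
    panel_thin_bp: int = 10_000
    # SFS / fitting
    sfs_folded: bool = False
    fit_models: list[str] = field(default_factory=lambda: ["model1_stepping", "model4_SE_NC_admix"])
    fit_fixed: dict[str, dict[str, float]] = field(default_factory=dict)
    fit_n_sims: int = 1000
    fit_cycles: int = 2
    fit_restarts: int = 1
    mantel_permutations: int = 999

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(doc)

    @classmethod
    def from_dict(cls, doc: Mapping[str, Any]) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {', '.join(sorted(unknown))}")
        return cls(**doc)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _json_dump(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, sort_keys=True, indent=1) + "\n")


def _spawn_seed(root: int, key: int) -> int:
    return int(np.random.SeedSequence(root, spawn_key=(key,)).generate_state(1)[0] >> 1)


def load_or_simulate_cohort(cfg: RunConfig) -> GenotypeMatrix:
    if cfg.vcf:
        individuals = None
        if cfg.popmap:
            pm = read_popmap(cfg.popmap)
            individuals = pm.assign(mean_depth=np.nan)
        gm = read_vcf(cfg.vcf, individuals=individuals)
        if "mean_depth" not in gm.individuals or gm.individuals["mean_depth"].isna().all():
            # no depth metadata: synthesize a passing value so the depth
            # rule is a no-op rather than removing everyone
            gm.individuals["mean_depth"] = 99.0
        return gm
    from .models import BEST_FIT_SE_NC_ADMIX

    params = {**BEST_FIT_SE_NC_ADMIX, **cfg.model_params}
    demog = build_named_model(cfg.model, params)
    group_sizes = {g: n for cl in cfg.groups.values() for g, n in cl.items()}
    group_to_deme = {g: cl for cl, d in cfg.groups.items() for g in d}
    return simulate_genotype_matrix(
        demog,
        group_sizes=group_sizes,
        n_sites=cfg.n_sites,
        seed=_spawn_seed(cfg.seed, 1),
        group_to_deme=group_to_deme,
        missing_rate=cfg.missing_rate,
        relative_pairs=cfg.relative_pairs,
        n_low_depth=cfg.n_low_depth,
        n_high_missing=cfg.n_high_missing,
        site_fail_rate=cfg.site_fail_rate,
    )


def run_pipeline(cfg: RunConfig) -> dict:
    """Run the enabled stages; return the manifest (also written to disk)."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "version": __version__,
        "seed": cfg.seed,
        "config": cfg.to_dict(),
        "stages": {},
    }

    gm = load_or_simulate_cohort(cfg)
    write_vcf(gm, out / "cohort.vcf")
    write_popmap(gm.individuals, out / "cohort.popmap.tsv")
    manifest["stages"]["cohort"] = {
        "n_individuals": int(len(gm.individuals)),
        "n_sites": int(len(gm.sites)),
    }

    if cfg.run_site_filters:
        thr = SiteFilterThresholds(**cfg.site_thresholds)
        gm, rep = filter_sites(gm, thr)
        _json_dump(rep.to_dict(), out / "report_site_filters.json")
        log.info("%s", rep)
        manifest["stages"]["site_filters"] = rep.to_dict()

    if cfg.run_individual_filters:
        gm, rep = filter_individuals(
            gm, min_mean_depth=cfg.min_mean_depth, max_missing=cfg.max_individual_missing
        )
        _json_dump(rep.to_dict(), out / "report_individual_filters.json")
        log.info("%s", rep)
        manifest["stages"]["individual_filters"] = rep.to_dict()

    if cfg.run_kinship:
        kin = king_kinship(gm)
        miss = gm.missing_fraction().to_dict()
        kept = prune_first_degree(kin, threshold=cfg.kinship_threshold, missingness=miss)
        removed = sorted(set(gm.ids) - set(kept))
        gm = gm.subset(ids=kept)
        _json_dump(
            {
                "threshold": cfg.kinship_threshold,
                "n_removed": len(removed),
                "removed": removed,
            },
            out / "report_kinship.json",
        )
        manifest["stages"]["kinship"] = {"n_removed": len(removed), "removed": removed}

    if cfg.run_panel:
        gene_mask = read_bed(cfg.gene_mask_bed) if cfg.gene_mask_bed else []
        cpg_mask = read_bed(cfg.cpg_mask_bed) if cfg.cpg_mask_bed else []
        keep_idx, rep = design_panel(
            gm,
            gene_mask=gene_mask,
            cpg_mask=cpg_mask,
            maf_min=cfg.panel_maf_min,
            hwe_alpha=cfg.panel_hwe_alpha,
            thin_bp=cfg.panel_thin_bp,
        )
        gm = gm.subset(site_idx=keep_idx)
        _json_dump(rep.to_dict(), out / "report_panel.json")
        log.info("%s", rep)
        manifest["stages"]["panel"] = rep.to_dict()

    clusters = [c for c in gm.individuals["cluster"].unique() if c is not None]
    sfs_obj = None
    if cfg.run_sfs:
        sfs_obj = joint_sfs(
            gm.genotypes,
            list(gm.individuals["cluster"]),
            clusters,
            folded=cfg.sfs_folded,
        )
        sfs_obj.to_json(out / "sfs_joint.json")
        sfs_obj.marginals_tsv(out / "sfs_marginals.tsv")
        manifest["stages"]["sfs"] = {
            "populations": list(sfs_obj.labels),
            "segregating": sfs_obj.polymorphic_mass(),
            "monomorphic_in_sample": sfs_obj.monomorphic_mass(),
        }

    if cfg.run_fit:
        if sfs_obj is None:
            raise RuntimeError("fit stage requires the sfs stage")
        fits = []
        for name in cfg.fit_models:
            fits += fit_with_restarts(
                name,
                sfs_obj,
                n_restarts=cfg.fit_restarts,
                seed=_spawn_seed(cfg.seed, 2),
                n_sims=cfg.fit_n_sims,
                cycles=cfg.fit_cycles,
                fixed=cfg.fit_fixed.get(name, {}),
            )
        _json_dump([f.to_dict() for f in fits], out / "fits.json")
        ranking = compare_models(fits)
        _json_dump(ranking, out / "model_ranking.json")
        manifest["stages"]["fit"] = {
            "ranking": [(r["model"], r["delta_AIC"]) for r in ranking]
        }

    if cfg.run_stats:
        ho = observed_heterozygosity(gm.genotypes, gm.ids)
        ho.rename_axis("id").reset_index().to_csv(
            out / "heterozygosity.tsv", sep="\t", index=False, float_format="%.6g"
        )
        # F_ST needs >= 2 genotyped individuals per population
        sizes = gm.individuals["cluster"].value_counts()
        clusters = [c for c in clusters if sizes.get(c, 0) >= 2]
        fst = pairwise_fst(gm.genotypes, list(gm.individuals["cluster"]), clusters)
        fst.to_tsv(out / "fst_clusters.tsv")
        stats_summary: dict[str, Any] = {
            "Ho_mean": float(ho.mean()),
            "fst_range": [
                float(np.min(fst.upper())) if len(fst.labels) > 1 else None,
                float(np.max(fst.upper())) if len(fst.labels) > 1 else None,
            ],
        }
        coords = None
        if cfg.coords_tsv:
            cdf = read_coords(cfg.coords_tsv)
            coords = {r["label"]: (r["lat"], r["lon"]) for _, r in cdf.iterrows()}
        elif set(clusters) <= set(_DEFAULT_COORDS):
            coords = {c: _DEFAULT_COORDS[c] for c in clusters}
        if coords and len(clusters) >= 3:
            geo = geographic_distances(coords).reorder(fst.labels)
            gen = linearize_fst_matrix(fst)
            ibd = mantel_test(
                gen, geo, n_perm=cfg.mantel_permutations, seed=_spawn_seed(cfg.seed, 3)
            )
            stats_summary["mantel"] = ibd
            geo.to_tsv(out / "geographic_km.tsv")
            gen.to_tsv(out / "fst_linearized.tsv")
        _json_dump(stats_summary, out / "stats.json")
        manifest["stages"]["stats"] = stats_summary

    _json_dump(manifest, out / "manifest.json")
    return manifest
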