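"""File-format adapters: VCF 4.2 (subset), BED masks, popmap and
coordinate TSVs.

Coordinate conventions: VCF positions are 1-based inclusive and stay
1-based internally; BED intervals are 0-based half-open and stay 0-based
as mask inputs (the QC stage converts at the boundary).
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .genotypes import ANNOTATIONS, GenotypeMatrix

__all__ = [
    "read_vcf",
    "write_vcf",
    "read_popmap",
    "write_popmap",
    "read_coords",
    "read_bed",
    "write_bed",
]

log = logging.getLogger("stepstone")

_VCF_HEADER = """##fileformat=VCFv4.2
##source=stepstone
##INFO=<ID=FS,Number=1,Type=Float,Description="Fisher strand bias">
##INFO=<ID=QD,Number=1,Type=Float,Description="Quality by depth">
##INFO=<ID=MQ,Number=1,Type=Float,Description="RMS mapping quality">
##INFO=<ID=MQRankSum,Number=1,Type=Float,Description="Mapping quality rank sum">
##INFO=<ID=ReadPosRankSum,Number=1,Type=Float,Description="Read position rank sum">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
"""

_GT_STR = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}


def read_vcf(path: str | Path, individuals: pd.DataFrame | None = None) -> GenotypeMatrix:
    """Read biallelic SNP records from a VCF into a GenotypeMatrix.

    Multiallelic records are dropped (count logged).  INFO keys FS, QD,
    MQ, MQRankSum, ReadPosRankSum populate the site annotations; absent
    keys become NaN.  ``individuals`` optionally supplies group/cluster/
    depth metadata (by ``id``); otherwise a bare table is built.
    """
    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    if not samples:
        raise ValueError(f"{path}: VCF has no genotype columns")
    rows = []
    gts = []
    n_multi = 0
    for rec in vcf:
        if len(rec.ALT) != 1 or len(rec.REF) != 1 or len(rec.ALT[0]) != 1:
            n_multi += 1
            continue
        row = {
            "chrom": rec.CHROM,
            "pos": rec.POS,
            "ref": rec.REF,
            "alt": rec.ALT[0],
            "QUAL": rec.QUAL if rec.QUAL is not None else np.nan,
        }
        for key in ANNOTATIONS[1:]:
            val = rec.INFO.get(key)
            row[key] = float(val) if val is not None else np.nan
        rows.append(row)
        g = np.asarray(rec.gt_types, dtype=np.int8)  # gts012: 3 == unknown
        g[g == 3] = -1
        gts.append(g)
    vcf.close()
    if n_multi:
        log.info("read_vcf: dropped %d non-biallelic record(s)", n_multi)
    if not rows:
        raise ValueError(f"{path}: no biallelic SNP records")
    sites = pd.DataFrame(rows)
    G = np.stack(gts, axis=1)  # individuals x sites
    if individuals is None:
        individuals = pd.DataFrame(
            {"id": samples, "group": None, "cluster": None, "mean_depth": np.nan}
        )
    else:
        individuals = individuals.set_index("id").loc[samples].reset_index()
    return GenotypeMatrix(G, sites, individuals)


def write_vcf(gm: GenotypeMatrix, path: str | Path) -> None:
    """Write a GenotypeMatrix as uncompressed VCF 4.2 (GT only)."""
    ids = gm.ids
    lines = [_VCF_HEADER.rstrip("\n")]
    for c in pd.unique(gm.sites["chrom"]):
        lines.append(f"##contig=<ID={c}>")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(ids))
    s = gm.sites
    for j in range(len(s)):
        info = []
        for key in ANNOTATIONS[1:]:
            v = s[key].iloc[j] if key in s else np.nan
            if pd.notna(v):
                info.append(f"{key}={float(v):g}")
        qual = s["QUAL"].iloc[j] if "QUAL" in s else np.nan
        lines.append(
            "\t".join(
                [
                    str(s["chrom"].iloc[j]),
                    str(int(s["pos"].iloc[j])),
                    ".",
                    str(s["ref"].iloc[j]),
                    str(s["alt"].iloc[j]),
                    f"{float(qual):g}" if pd.notna(qual) else ".",
                    "PASS",
                    ";".join(info) if info else ".",
                    "GT",
                ]
                + [_GT_STR[int(g)] for g in gm.genotypes[:, j]]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_popmap(path: str | Path) -> pd.DataFrame:
    """TSV with columns: individual id, group, cluster (no header)."""
    df = pd.read_csv(
        path, sep="\t", header=None, names=["id", "group", "cluster"], dtype=str
    )
    if df["id"].isna().any() or df["group"].isna().any():
        raise ValueError(f"{path}: popmap requires id and group columns")
    return df


def write_popmap(individuals: pd.DataFrame, path: str | Path) -> None:
    individuals[["id", "group", "cluster"]].to_csv(
        path, sep="\t", header=False, index=False
    )


def read_coords(path: str | Path) -> pd.DataFrame:
    """TSV with header columns: label, lat, lon."""
    df = pd.read_csv(path, sep="\t")
    need = {"label", "lat", "lon"}
    if not need.issubset(df.columns):
        raise ValueError(f"{path}: coordinates TSV needs columns {sorted(need)}")
    return df


def read_bed(path: str | Path) -> list[tuple[str, int, int]]:
    """BED3: 0-based half-open intervals."""
    out = []
    for ln in Path(path).read_text().splitlines():
        ln = ln.strip()
        if not ln or ln.startswith(("#", "track", "browser")):
            continue
        toks = ln.split("\t")
        out.append((toks[0], int(toks[1]), int(toks[2])))
    return out


def write_bed(intervals: Sequence[tuple[str, int, int]], path: str | Path) -> None:
    Path(path).write_text(
        "".join(f"{c}\t{s}\t{e}\n" for c, s, e in intervals)
    )
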