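"""File I/O: genotype VCF, plasma VCF/TSV, report JSON.

Internal coordinates are 0-based half-open; VCF, TSV and report files
use 1-based positions.  VCFs are read with cyvcf2; writing uses a
minimal VCF 4.2 text emitter (three-sample GT, or single-sample AD for
plasma), which is all this assay needs.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .families import MISSING, GenotypeSet, Pedigree
from .panel import Panel
from .plasma import DEFAULT_EPSILON, PlasmaCounts

__all__ = [
    "write_genotypes_vcf",
    "read_genotypes_vcf",
    "write_plasma_vcf",
    "read_plasma_vcf",
    "write_report",
]

_GT_STRING = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def _vcf_header(samples: list[str], chroms: list[str]) -> str:
    lines = ["##fileformat=VCFv4.2", "##source=niptsr"]
    lines += [f"##contig=<ID={c}>" for c in chroms]
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append(
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">'
    )
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples)
    )
    return "\n".join(lines) + "\n"


def write_genotypes_vcf(
    path: str | Path, panel: Panel, genotypes: GenotypeSet, pedigree: Pedigree
) -> None:
    """Write mother/father/reference GTs as a plain-text multi-sample VCF."""
    samples = [pedigree.mother, pedigree.father, pedigree.reference]
    with open(path, "w") as fh:
        fh.write(_vcf_header(samples, panel.chromosomes))
        gdf = genotypes.df
        for row, g in zip(panel.df.itertuples(index=False), gdf.itertuples(index=False)):
            gts = "\t".join(_GT_STRING[int(v)] for v in (g.mother, g.father, g.reference))
            fh.write(
                f"{row.chrom}\t{row.pos + 1}\t.\t{row.ref}\t{row.alt}\t.\tPASS\t.\tGT\t{gts}\n"
            )


def read_genotypes_vcf(path: str | Path, panel: Panel, pedigree: Pedigree) -> GenotypeSet:
    """Read mother/father/reference genotypes from a multi-sample VCF.

    Sites are matched to the panel by (chrom, pos); panel SNPs absent
    from the VCF get missing genotypes.
    """
    vcf = VCF(str(path), gts012=True)
    sample_idx = {}
    for role, name in (
        ("mother", pedigree.mother),
        ("father", pedigree.father),
        ("reference", pedigree.reference),
    ):
        if name not in vcf.samples:
            raise ValueError(f"sample {name!r} ({role}) not in VCF {path}")
        sample_idx[role] = vcf.samples.index(name)

    lookup = {
        (c, int(p)): i
        for i, (c, p) in enumerate(zip(panel.df["chrom"], panel.df["pos"]))
    }
    gt = {role: np.full(len(panel), MISSING, dtype=np.int64) for role in sample_idx}
    for var in vcf:
        key = (var.CHROM, var.POS - 1)
        i = lookup.get(key)
        if i is None:
            continue
        types = var.gt_types  # 0 hom-ref, 1 het, 2 hom-alt, 3 unknown (gts012)
        for role, si in sample_idx.items():
            t = int(types[si])
            gt[role][i] = t if t in (0, 1, 2) else MISSING
    df = panel.df[["chrom", "pos"]].copy()
    for role, arr in gt.items():
        df[role] = arr
    return GenotypeSet(df)


def write_plasma_vcf(
    path: str | Path, panel: Panel, plasma: PlasmaCounts, sample: str = "plasma"
) -> None:
    """Write plasma allele depths as a single-sample VCF with AD."""
    with open(path, "w") as fh:
        fh.write(_vcf_header([sample], panel.chromosomes))
        for row, p in zip(panel.df.itertuples(index=False), plasma.df.itertuples(index=False)):
            ref_count = int(p.depth - p.alt_count)
            fh.write(
                f"{row.chrom}\t{row.pos + 1}\t.\t{row.ref}\t{row.alt}\t.\tPASS\t.\t"
                f"AD\t{ref_count},{int(p.alt_count)}\n"
            )


def read_plasma_vcf(
    path: str | Path, panel: Panel, epsilon: float = DEFAULT_EPSILON
) -> PlasmaCounts:
    """Read plasma allele depths (AD) from a single-sample VCF."""
    vcf = VCF(str(path))
    lookup = {
        (c, int(p)): i
        for i, (c, p) in enumerate(zip(panel.df["chrom"], panel.df["pos"]))
    }
    depth = np.zeros(len(panel), dtype=np.int64)
    alt = np.zeros(len(panel), dtype=np.int64)
    for var in vcf:
        i = lookup.get((var.CHROM, var.POS - 1))
        if i is None:
            continue
        ad = var.format("AD")
        if ad is None:
            continue
        ref_c, alt_c = int(ad[0][0]), int(ad[0][1])
        depth[i] = max(ref_c, 0) + max(alt_c, 0)
        alt[i] = max(alt_c, 0)
    df = panel.df[["chrom", "pos"]].copy()
    df["depth"] = depth
    df["alt_count"] = alt
    return PlasmaCounts(df=df, epsilon=epsilon)


def read_plasma(path: str | Path, panel: Panel, epsilon: float = DEFAULT_EPSILON) -> PlasmaCounts:
    """Read plasma counts from TSV or VCF, judged by file extension."""
    path = Path(path)
    if path.suffix.lower() == ".vcf":
        return read_plasma_vcf(path, panel, epsilon)
    counts = PlasmaCounts.from_tsv(path, epsilon)
    # align to the panel by (chrom, pos)
    merged = panel.df[["chrom", "pos"]].merge(counts.df, on=["chrom", "pos"], how="left")
    merged[["depth", "alt_count"]] = merged[["depth", "alt_count"]].fillna(0).astype(np.int64)
    return PlasmaCounts(df=merged, epsilon=epsilon)


def write_report(report: dict, path: str | Path) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON-serialisable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, default=_default)
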