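"""Readers and writers for the plain-text formats the pipeline touches.

Formats: BED3/BED6, BEDPE, bedGraph, HiC-Pro-style valid-pairs text,
matrix triplet text with a companion bin BED, a tab-separated gene table,
and a GT-only VCF v4.2 subset (reading of VCF lives in :mod:`muscle3d.sweep`
via cyvcf2; the simulator's writer is here).
"""

from __future__ import annotations

import os
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .genome import Gene, GenomeLayout, GenomicInterval

__all__ = [
    "read_bed",
    "write_bed",
    "read_bedpe",
    "write_bedpe",
    "write_bedgraph",
    "read_bedgraph",
    "read_valid_pairs",
    "write_valid_pairs",
    "read_gene_table",
    "write_gene_table",
    "write_vcf",
    "read_layout",
    "write_layout",
]

PAIRS_COLUMNS = ["read_id", "chrom1", "pos1", "strand1", "chrom2", "pos2", "strand2"]


def read_bed(path: str) -> List[GenomicInterval]:
    out: List[GenomicInterval] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            name = parts[3] if len(parts) > 3 else None
            score = float(parts[4]) if len(parts) > 4 and parts[4] != "." else None
            out.append(GenomicInterval(parts[0], int(parts[1]), int(parts[2]), name, score))
    return out


def write_bed(intervals: Iterable[GenomicInterval], path: str) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fields = [iv.chrom, str(iv.start), str(iv.end)]
            if iv.name is not None or iv.score is not None:
                fields.append(iv.name if iv.name is not None else ".")
            if iv.score is not None:
                fields.append(repr(iv.score))
            fh.write("\t".join(fields) + "\n")


def write_bedgraph(
    intervals: Iterable[GenomicInterval], values: Sequence[float], path: str
) -> None:
    with open(path, "w") as fh:
        for iv, v in zip(intervals, values):
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{v!r}\n")


def read_bedgraph(path: str) -> Tuple[List[GenomicInterval], np.ndarray]:
    ivs, vals = [], []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            c, s, e, v = line.rstrip("\n").split("\t")[:4]
            ivs.append(GenomicInterval(c, int(s), int(e)))
            vals.append(float(v))
    return ivs, np.array(vals)


def read_bedpe(path: str) -> pd.DataFrame:
    """BEDPE: chrom1,start1,end1,chrom2,start2,end2[,name,score,...extras]."""
    rows = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            p = line.rstrip("\n").split("\t")
            row = {
                "chrom1": p[0], "start1": int(p[1]), "end1": int(p[2]),
                "chrom2": p[3], "start2": int(p[4]), "end2": int(p[5]),
            }
            if len(p) > 6:
                row["name"] = p[6]
            if len(p) > 7:
                row["score"] = float(p[7]) if p[7] != "." else np.nan
            rows.append(row)
    return pd.DataFrame(rows)


def write_bedpe(df: pd.DataFrame, path: str) -> None:
    cols = ["chrom1", "start1", "end1", "chrom2", "start2", "end2"]
    extras = [c for c in df.columns if c not in cols]
    df[cols + extras].to_csv(path, sep="\t", header=False, index=False)


def read_valid_pairs(path: str) -> pd.DataFrame:
    """HiC-Pro allValidPairs dialect: readID chrom1 pos1 strand1 chrom2 pos2 strand2."""
    try:
        df = pd.read_csv(
            path, sep="\t", names=PAIRS_COLUMNS, header=None,
            dtype={"chrom1": str, "chrom2": str, "strand1": str, "strand2": str},
        )
    except ValueError as exc:  # pragma: no cover - malformed input path
        raise ValueError(f"malformed valid-pairs file {path}: {exc}") from exc
    if df[["pos1", "pos2"]].isna().any().any():
        bad = int(df[["pos1", "pos2"]].isna().any(axis=1).idxmax()) + 1
        raise ValueError(f"malformed valid-pairs line {bad} in {path}")
    return df


def write_valid_pairs(df: pd.DataFrame, path: str) -> None:
    df[PAIRS_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def read_gene_table(path: str) -> List[Gene]:
    """Tab-separated gene table: gene_id chrom start end strand [fpkm_<cond>...]."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    fpkm_cols = [c for c in df.columns if c.startswith("fpkm_")]
    genes = []
    for row in df.itertuples(index=False):
        expr = {c[len("fpkm_"):]: float(getattr(row, c)) for c in fpkm_cols}
        genes.append(
            Gene(
                gene_id=row.gene_id,
                interval=GenomicInterval(row.chrom, int(row.start), int(row.end)),
                strand=row.strand,
                expression=expr,
            )
        )
    return genes


def write_gene_table(genes: Sequence[Gene], path: str) -> None:
    conds: List[str] = []
    for g in genes:
        for c in g.expression:
            if c not in conds:
                conds.append(c)
    rows = []
    for g in genes:
        row = {
            "gene_id": g.gene_id, "chrom": g.chrom,
            "start": g.interval.start, "end": g.interval.end, "strand": g.strand,
        }
        for c in conds:
            row[f"fpkm_{c}"] = g.expression.get(c, 0.0)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_vcf(
    path: str,
    layout: GenomeLayout,
    chroms: Sequence[str],
    positions: Sequence[int],
    ref: Sequence[str],
    alt: Sequence[str],
    genotypes: np.ndarray,
    sample_names: Sequence[str],
) -> None:
    """Write a GT-only VCF v4.2. `positions` are 0-based; written 1-based.

    genotypes: (n_sites, n_samples) int array of alt-allele dosage 0/1/2,
    or -1 for a missing call.
    """
    gt_code = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in layout.chroms:
            fh.write(f"##contig=<ID={c},length={layout.length(c)}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(sample_names) + "\n"
        )
        for i in range(len(positions)):
            gts = "\t".join(gt_code[int(g)] for g in genotypes[i])
            fh.write(
                f"{chroms[i]}\t{positions[i] + 1}\t.\t{ref[i]}\t{alt[i]}\t.\tPASS\t.\tGT\t{gts}\n"
            )


def write_layout(layout: GenomeLayout, path: str) -> None:
    with open(path, "w") as fh:
        for c in layout.chroms:
            fh.write(f"{c}\t{layout.length(c)}\n")


def read_layout(path: str) -> GenomeLayout:
    lengths: Dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            c, ln = line.split("\t")[:2]
            lengths[c] = int(ln)
    return GenomeLayout(lengths)
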