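"""A/B compartment calling and cross-stage transition analysis.

Compartments are called per chromosome from the leading eigenvector (PC1)
of the Pearson correlation matrix of the distance-normalized (O/E)
balanced contact map at 1 Mb. The sign of an eigenvector is arbitrary, so
each chromosome's PC1 is oriented by an activity track (gene density or
mean ATAC signal per bin): the sign is flipped so that corr(PC1, track) is
positive, and A = PC1 > 0, B = PC1 < 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genome import Gene, GenomeLayout
from .hic import ContactMatrix, oe_matrix

__all__ = [
    "CompartmentTrack",
    "TransitionSet",
    "call_compartments",
    "compartment_transitions",
    "gene_density_track",
]

MIN_BINS = 4  # chromosomes with fewer usable bins are masked wholesale


@dataclass
class CompartmentTrack:
    """Per-bin PC1 values and A/B labels at one resolution."""

    layout: GenomeLayout
    resolution: int
    pc1: Dict[str, np.ndarray]  # NaN at masked bins
    labels: Dict[str, np.ndarray]  # "A", "B" or "." (masked)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for chrom in self.layout.chroms:
            L = self.layout.length(chrom)
            for b, (v, lab) in enumerate(zip(self.pc1[chrom], self.labels[chrom])):
                rows.append((chrom, b * self.resolution,
                             min((b + 1) * self.resolution, L), v, lab))
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "pc1", "label"])

    def fractions(self) -> Dict[str, float]:
        """A/B percentage of the non-masked genome; sums to 100."""
        labs = np.concatenate([self.labels[c] for c in self.layout.chroms])
        labs = labs[labs != "."]
        n = len(labs)
        if n == 0:
            return {"A": np.nan, "B": np.nan}
        return {"A": 100.0 * (labs == "A").mean(), "B": 100.0 * (labs == "B").mean()}


def gene_density_track(
    layout: GenomeLayout, genes: Sequence[Gene], resolution: int
) -> Dict[str, np.ndarray]:
    """Number of TSSs per bin — the default orientation track."""
    out = {c: np.zeros(layout.n_bins(c, resolution)) for c in layout.chroms}
    for g in genes:
        if g.chrom in out:
            out[g.chrom][min(g.tss // resolution, len(out[g.chrom]) - 1)] += 1
    return out


def call_compartments(
    m: ContactMatrix, orientation_track: Dict[str, np.ndarray]
) -> CompartmentTrack:
    """PC1 of the contact-correlation matrix, oriented and thresholded at 0.

    Requires an ICE-balanced matrix (1 Mb is the conventional resolution).
    Per chromosome: O/E by distance, Pearson correlation of its columns,
    leading eigenvector, sign chosen so correlation with the orientation
    track is positive. Bins masked in balancing stay masked.
    """
    pc1: Dict[str, np.ndarray] = {}
    labels: Dict[str, np.ndarray] = {}
    for chrom in m.chroms:
        n = m.n_bins(chrom)
        vec = np.full(n, np.nan)
        labs = np.full(n, ".", dtype="<U1")
        good = ~m.mask(chrom)
        if good.sum() >= MIN_BINS:
            oe = oe_matrix(m, chrom)[np.ix_(good, good)]
            oe = np.nan_to_num(oe, nan=1.0)
            with np.errstate(invalid="ignore"):
                corr = np.corrcoef(oe, rowvar=False)
            corr = np.nan_to_num(corr)
            evals, evecs = np.linalg.eigh(corr)
            v = evecs[:, -1]
            track = np.asarray(orientation_track[chrom], dtype=float)[good]
            if np.std(track) > 0 and np.std(v) > 0:
                r = np.corrcoef(v, track)[0, 1]
                if np.isfinite(r) and r < 0:
                    v = -v
            vec[good] = v
            labs[good] = np.where(v > 0, "A", np.where(v < 0, "B", "."))
        pc1[chrom] = vec
        labels[chrom] = labs
    return CompartmentTrack(m.layout, m.resolution, pc1, labels)


@dataclass
class TransitionSet:
    """A<->B transition classes between two stages, with expression tests."""

    table: pd.DataFrame  # chrom, start, end, class
    mb_per_class: Dict[str, float]
    genes_per_class: Dict[str, List[str]] = field(default_factory=dict)
    tests: pd.DataFrame = field(default_factory=pd.DataFrame)


def compartment_transitions(
    fetal: CompartmentTrack,
    adult: CompartmentTrack,
    genes: Optional[Sequence[Gene]] = None,
    conditions: tuple = ("fetal", "adult"),
) -> TransitionSet:
    """Classify bins A->A / A->B / B->A / B->B and test member-gene FPKM.

    Genes are assigned to the bin containing their TSS; per class, a
    two-sided Wilcoxon signed-rank test pairs each gene's FPKM across the
    two stages. Classes with no genes are skipped with a note.
    """
    if fetal.resolution != adult.resolution or fetal.layout != adult.layout:
        raise ValueError("tracks must share layout and resolution")
    res = fetal.resolution
    rows = []
    for chrom in fetal.layout.chroms:
        L = fetal.layout.length(chrom)
        for b, (lf, la) in enumerate(zip(fetal.labels[chrom], adult.labels[chrom])):
            if lf == "." or la == ".":
                continue
            rows.append((chrom, b * res, min((b + 1) * res, L), f"{lf}->{la}"))
    table = pd.DataFrame(rows, columns=["chrom", "start", "end", "class"])
    mb = {
        cls: float((grp["end"] - grp["start"]).sum() / 1e6)
        for cls, grp in table.groupby("class")
    }
    genes_per_class: Dict[str, List[str]] = {}
    tests_rows = []
    if genes:
        bin_class = {(r.chrom, r.start // res): r[3] for r in table.itertuples(index=False)}
        for g in genes:
            cls = bin_class.get((g.chrom, g.tss // res))
            if cls is not None:
                genes_per_class.setdefault(cls, []).append(g.gene_id)
        by_id = {g.gene_id: g for g in genes}
        for cls in sorted(mb):
            ids = genes_per_class.get(cls, [])
            x = np.array([by_id[i].expression.get(conditions[0], np.nan) for i in ids])
            y = np.array([by_id[i].expression.get(conditions[1], np.nan) for i in ids])
            ok = np.isfinite(x) & np.isfinite(y)
            x, y = x[ok], y[ok]
            if len(x) == 0:
                tests_rows.append({"class": cls, "n_genes": 0, "p_value": np.nan,
                                   "note": "no genes in class; test skipped"})
                continue
            diffs = x - y
            if np.allclose(diffs, 0):
                p = np.nan
                note = "identical expression; test degenerate"
            else:
                p = float(stats.wilcoxon(x, y, alternative="two-sided").pvalue)
                note = ""
            tests_rows.append({
                "class": cls, "n_genes": int(len(x)), "p_value": p,
                "median_delta": float(np.median(diffs)), "note": note,
            })
    return TransitionSet(table, mb, genes_per_class, pd.DataFrame(tests_rows))
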