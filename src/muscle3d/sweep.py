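"""Two-population windowed Fst scan and sweep-region enrichment.

Per-site Weir & Cockerham (1984) variance components a (among
populations), b (among individuals within populations) and c (within
individuals) are summed over sliding windows (10 kb window, 5 kb step by
convention); window Fst = sum(a) / sum(a+b+c), the weighted
ratio-of-sums estimator. ZFst standardizes the windowed values
genome-wide, and runs of windows with ZFst above a threshold are merged
into sweep regions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import false_discovery_control

from .genome import GenomeLayout, GenomicInterval, intersect_any

__all__ = [
    "read_vcf_table",
    "filter_variants",
    "wc_components",
    "windowed_zfst",
    "call_sweep_regions",
    "region_enrichment",
    "genotype_pca",
]


def read_vcf_table(path: str) -> pd.DataFrame:
    """Read a VCF into the genotype-table layout (alt dosage per sample,
    -1 for missing). Non-biallelic and non-SNP records are skipped."""
    from cyvcf2 import VCF

    vcf = VCF(path, gts012=True)
    rows = []
    genos = []
    n_skipped = 0
    for var in vcf:
        if len(var.ALT) != 1 or not var.is_snp:
            n_skipped += 1
            continue
        rows.append((var.CHROM, var.POS - 1, var.REF, var.ALT[0]))
        g = var.gt_types.astype(int)  # 0/1/2, 3 = unknown with gts012
        g[g == 3] = -1
        genos.append(g)
    df = pd.DataFrame(rows, columns=["chrom", "pos0", "ref", "alt"])
    if n_skipped:
        import logging

        logging.getLogger(__name__).info(
            "skipped %d non-biallelic/non-SNP records", n_skipped
        )
    geno = np.array(genos) if genos else np.empty((0, len(vcf.samples)), int)
    for k, s in enumerate(vcf.samples):
        df[s] = geno[:, k] if len(df) else np.array([], int)
    df.attrs["samples"] = list(vcf.samples)
    return df


def _sample_columns(table: pd.DataFrame) -> List[str]:
    return [c for c in table.columns if c not in ("chrom", "pos0", "ref", "alt")]


def filter_variants(
    table: pd.DataFrame, max_missing: float = 0.3, maf: float = 0.01
) -> pd.DataFrame:
    """Keep biallelic SNPs with missing rate < max_missing and minor
    allele frequency strictly > maf (computed over all called samples)."""
    samples = _sample_columns(table)
    geno = table[samples].to_numpy()
    called = geno >= 0
    miss_rate = 1.0 - called.mean(axis=1)
    with np.errstate(invalid="ignore"):
        p = np.where(called, geno, 0).sum(axis=1) / (2.0 * called.sum(axis=1))
    minor = np.minimum(p, 1 - p)
    keep = (miss_rate < max_missing) & (minor > maf)
    return table.loc[keep].reset_index(drop=True)


def wc_components(
    geno: np.ndarray, pop1: np.ndarray, pop2: np.ndarray
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Weir-Cockerham variance components (a, b, c) per site, two
    populations, diploid.

    geno: (n_sites, n_samples) alt dosages with -1 for missing. pop1/pop2
    are boolean sample masks. Sites where a population has < 2 called
    samples yield NaN components.
    """
    r = 2.0
    out_a = np.full(geno.shape[0], np.nan)
    out_b = np.full(geno.shape[0], np.nan)
    out_c = np.full(geno.shape[0], np.nan)
    parts = []
    for mask in (pop1, pop2):
        g = geno[:, mask]
        called = g >= 0
        n = called.sum(axis=1).astype(float)  # diploid individuals called
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(called, g, 0).sum(axis=1) / (2 * n)
            h = np.where(called, g == 1, False).sum(axis=1) / n
        parts.append((n, p, h))
    (n1, p1, h1), (n2, p2, h2) = parts
    ok = (n1 >= 2) & (n2 >= 2)
    n1, p1, h1, n2, p2, h2 = (x[ok] for x in (n1, p1, h1, n2, p2, h2))
    nbar = (n1 + n2) / r
    nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    a = (nbar / nc) * (
        s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
    )
    c = hbar / 2
    out_a[ok], out_b[ok], out_c[ok] = a, b, c
    return out_a, out_b, out_c


def windowed_zfst(
    table: pd.DataFrame,
    labels: Sequence[str],
    layout: GenomeLayout,
    window: int = 10_000,
    step: int = 5_000,
) -> pd.DataFrame:
    """Sliding-window weighted Fst and its genome-wide Z score.

    Negative per-site components are retained in the sums (standard
    estimator behavior); windows with no usable site carry NaN. ZFst is
    standardized over all windows with >= 1 usable site; a zero standard
    deviation raises (degenerate scan).
    """
    labels = np.asarray(labels)
    levels = pd.unique(labels)
    if len(levels) != 2:
        raise ValueError("exactly two population labels required")
    samples = _sample_columns(table)
    if len(samples) != len(labels):
        raise ValueError("labels must match sample columns")
    geno = table[samples].to_numpy()
    a, b, c = wc_components(geno, labels == levels[0], labels == levels[1])
    denom_site = a + b + c
    usable = np.isfinite(denom_site)

    rows = []
    for chrom in layout.chroms:
        L = layout.length(chrom)
        on_chrom = (table["chrom"] == chrom).to_numpy()
        pos = table["pos0"].to_numpy()
        for start in range(0, max(1, L - window + step), step):
            end = min(start + window, L)
            sel = on_chrom & usable & (pos >= start) & (pos < end)
            n = int(sel.sum())
            if n:
                denom = denom_site[sel].sum()
                fst = float(a[sel].sum() / denom) if denom != 0 else np.nan
            else:
                fst = np.nan
            rows.append((chrom, start, end, n, fst))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "n_variants", "fst"])
    vals = df["fst"].to_numpy()
    ok = np.isfinite(vals)
    if ok.sum() < 2:
        raise ValueError("too few windows with usable sites")
    mu, sd = vals[ok].mean(), vals[ok].std()
    if sd == 0:
        raise ValueError("degenerate scan: window Fst has zero variance")
    df["zfst"] = (vals - mu) / sd
    return df


@dataclass
class SweepRegion:
    interval: GenomicInterval
    max_zfst: float
    n_windows: int


def call_sweep_regions(
    windows: pd.DataFrame, z_threshold: float = 3.0
) -> List[SweepRegion]:
    """Merge overlapping/book-ended windows with ZFst > threshold."""
    hits = windows[windows["zfst"] > z_threshold].sort_values(["chrom", "start"])
    regions: List[SweepRegion] = []
    cur: Optional[List] = None  # [chrom, start, end, max_z, n]
    for row in hits.itertuples(index=False):
        if cur is not None and row.chrom == cur[0] and row.start <= cur[2]:
            cur[2] = max(cur[2], row.end)
            cur[3] = max(cur[3], row.zfst)
            cur[4] += 1
        else:
            if cur is not None:
                regions.append(SweepRegion(
                    GenomicInterval(cur[0], cur[1], cur[2]), cur[3], cur[4]))
            cur = [row.chrom, row.start, row.end, row.zfst, 1]
    if cur is not None:
        regions.append(SweepRegion(
            GenomicInterval(cur[0], cur[1], cur[2]), cur[3], cur[4]))
    return regions


def region_enrichment(
    query_elements: Mapping[str, Sequence[GenomicInterval]],
    sweeps: Sequence[SweepRegion],
    layout: GenomeLayout,
    bin_size: int = 10_000,
    alternative: str = "two-sided",
) -> pd.DataFrame:
    """Fisher's exact co-localization of element classes with sweeps.

    The universe is the genome tiled in `bin_size` bins; each bin is
    scored for overlap with the query class and with the sweep regions;
    the 2x2 table is tested per class with BH across classes. Odds ratios
    with an empty cell are reported as infinity.
    """
    universe = layout.bins(bin_size)
    if not universe:
        raise ValueError("empty universe")
    sweep_ivs = [s.interval for s in sweeps]
    in_sweep = intersect_any(universe, sweep_ivs) if sweep_ivs else np.zeros(
        len(universe), bool)
    rows = []
    for cls, elems in query_elements.items():
        in_q = intersect_any(universe, list(elems)) if len(elems) else np.zeros(
            len(universe), bool)
        both = int((in_q & in_sweep).sum())
        q_only = int((in_q & ~in_sweep).sum())
        s_only = int((~in_q & in_sweep).sum())
        neither = int((~in_q & ~in_sweep).sum())
        odds, p = stats.fisher_exact([[both, q_only], [s_only, neither]],
                                     alternative=alternative)
        rows.append({
            "class": cls, "both": both, "query_only": q_only,
            "sweep_only": s_only, "neither": neither,
            "odds_ratio": float(odds) if np.isfinite(odds) else np.inf,
            "p_value": float(p),
        })
    df = pd.DataFrame(rows)
    if len(df):
        df["q_value"] = false_discovery_control(df["p_value"].to_numpy(),
                                                method="bh")
    return df


def genotype_pca(
    table: pd.DataFrame, n_components: int = 2
) -> Tuple[np.ndarray, np.ndarray]:
    """Diagnostic projection of samples: eigen-decomposition of the
    covariance of centered genotype dosages (missing set to the site
    mean). Returns (coordinates, explained-variance fractions)."""
    samples = _sample_columns(table)
    g = table[samples].to_numpy().astype(float).T  # samples x sites
    g[g < 0] = np.nan
    mu = np.nanmean(g, axis=0)
    g = np.where(np.isnan(g), mu, g) - mu
    cov = g @ g.T / g.shape[1]
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1][:n_components]
    coords = evecs[:, order] * np.sqrt(np.maximum(evals[order], 0))
    frac = evals[order] / evals.sum() if evals.sum() > 0 else np.zeros(len(order))
    return coords, frac
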