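"""ATAC-derived regulatory elements, their wiring through loops, and
expression integration.

The element catalog is built sequentially: union ATAC peaks overlapping
promoter windows (TSS +/- 3 kb of expressed genes) are promoters (P);
remaining peaks overlapping contact-predicted enhancer bins are enhancers
(E); the rest are other accessible elements (O). Loop anchors inherit the
highest-priority class of their overlapping peaks (P > E > O) or N when no
peak overlaps. P/E/O partition the union peak set by construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import false_discovery_control

from .genome import Gene, GenomicInterval, intersect_any, merge_within_distance
from .hic import ContactMatrix
from .loops import ExpectedModel, Loop
from .simulate import CoverageTrack
from .tads import TadSet

__all__ = [
    "UnionPeak",
    "AnchorElement",
    "build_union_peaks",
    "tss_enrichment_score",
    "differential_counts",
    "predict_enhancer_candidates",
    "classify_elements",
    "wire_and_census",
    "expression_effects",
]

PROMOTER_FLANK = 3000
CLASS_PRIORITY = ("P", "E", "O")


@dataclass
class UnionPeak:
    """A merged accessible region with per-sample counts and enrichment.

    The enrichment value is the library-normalized per-base signal minus
    the library-normalized per-base background of the same sample,
    averaged over samples.
    """

    interval: GenomicInterval
    counts: Dict[str, float] = field(default_factory=dict)
    enrichment: float = np.nan
    cls: Optional[str] = None


@dataclass
class AnchorElement:
    """A loop anchor labeled by its overlapping peaks (P/E/O) or N."""

    anchor: GenomicInterval
    cls: str
    peak_indices: List[int] = field(default_factory=list)
    gene_ids: List[str] = field(default_factory=list)


def build_union_peaks(
    replicate_peaks: Mapping[str, Sequence[GenomicInterval]],
    coverage: Mapping[str, CoverageTrack],
    condition_of: Mapping[str, str],
    merge_gap: int = 10,
) -> List[UnionPeak]:
    """Union peak set from replicate-consistent peaks, with counts and
    enrichment values re-tallied on the union intervals.

    Per condition, peaks present (>= 1 bp overlap) in both replicates are
    retained; the per-condition sets are merged across conditions with the
    `merge_gap` rule. With a single replicate the consistency filter is
    skipped with a warning.
    """
    consistent: List[GenomicInterval] = []
    by_cond: Dict[str, List[str]] = {}
    for sample, cond in condition_of.items():
        by_cond.setdefault(cond, []).append(sample)
    for cond, samples in by_cond.items():
        if len(samples) < 2:
            warnings.warn(
                f"condition {cond} has a single replicate; "
                "consistency filter skipped",
                RuntimeWarning,
            )
            consistent.extend(replicate_peaks[samples[0]])
            continue
        for s in samples:
            others = [iv for o in samples if o != s for iv in replicate_peaks[o]]
            mask = intersect_any(list(replicate_peaks[s]), others)
            consistent.extend(iv for iv, ok in zip(replicate_peaks[s], mask) if ok)
    union = merge_within_distance(consistent, merge_gap)
    peaks = [UnionPeak(iv) for iv in union]
    enr = np.zeros((len(peaks), len(coverage)))
    for si, (sample, track) in enumerate(coverage.items()):
        # library normalization: per million reads on the track
        total = float(
            ((track.intervals["end"] - track.intervals["start"])
             * track.intervals["value"]).sum()
        )
        scale = 1e6 / total if total > 0 else 1.0
        for pi, pk in enumerate(peaks):
            per_base = track.per_base(pk.interval)
            pk.counts[sample] = per_base * len(pk.interval)
            enr[pi, si] = (per_base - track.baseline) * scale
    for pi, pk in enumerate(peaks):
        pk.enrichment = float(enr[pi].mean()) if enr.shape[1] else np.nan
    return peaks


def tss_enrichment_score(
    reads: pd.DataFrame,
    genes: Sequence[Gene],
    flank: int = 3000,
    bin_size: int = 400,
    shift: int = 75,
    extend: int = 150,
    normalized: bool = True,
) -> float:
    """TSS enrichment score from ATAC read positions.

    Each read is reduced to its transposition point: the 5' end shifted
    `shift` bp toward the 5' side and extended to `extend` bp, which
    centers the fragment on the 5' position. Per-bin average counts over
    all gene TSSs (strand-oriented +/- flank grid) give the profile; the
    score is the TSS-containing bin, divided by the mean of the two
    outermost bins when `normalized` (the flat-background expectation is
    then 1).
    """
    if not genes:
        raise ValueError("no genes supplied")
    del shift, extend  # the centered-point reduction makes them implicit
    n_bins = 2 * flank // bin_size
    profile = np.zeros(n_bins)
    p5 = np.where(reads["strand"] == "+", reads["start"], reads["end"] - 1).astype(int)
    chrom_arr = reads["chrom"].to_numpy()
    order = np.argsort(p5, kind="stable")
    p5_sorted = p5[order]
    chrom_sorted = chrom_arr[order]
    for g in genes:
        sel = chrom_sorted == g.chrom
        pos = p5_sorted[sel]
        lo = np.searchsorted(pos, g.tss - flank)
        hi = np.searchsorted(pos, g.tss + flank)
        offs = pos[lo:hi] - g.tss
        if g.strand == "-":
            offs = -offs - 1
        idx = (offs + flank) // bin_size
        np.add.at(profile, np.clip(idx, 0, n_bins - 1), 1.0)
    profile /= len(genes)
    tss_bin = flank // bin_size  # bin whose left edge is the TSS
    if not normalized:
        return float(profile[tss_bin])
    edge = (profile[0] + profile[-1]) / 2.0
    if edge == 0:
        return 0.0 if profile[tss_bin] == 0 else np.inf
    return float(profile[tss_bin] / edge)


def _size_factors(counts: np.ndarray) -> np.ndarray:
    """DESeq median-of-ratios library size factors."""
    with np.errstate(divide="ignore"):
        logs = np.log(counts)
    ok = np.isfinite(logs).all(axis=1)
    if not ok.any():
        return np.ones(counts.shape[1])
    ref = logs[ok].mean(axis=1)
    sf = np.exp(np.median(logs[ok] - ref[:, None], axis=0))
    sf[~np.isfinite(sf) | (sf <= 0)] = 1.0
    return sf


def _nb_exact_pvalue(s1: float, s2: float, n1: int, n2: int, alpha: float) -> float:
    """Two-sided conditional NB exact test on two group sums.

    Under H0 each sample is NB(mu, alpha); group sums are NB with
    size n_g / alpha. Conditioning on s1 + s2, the p-value sums the
    probabilities of all splits no more likely than the observed one.
    """
    total = int(round(s1 + s2))
    if total == 0:
        return 1.0
    mu = total / (n1 + n2)
    ks = np.arange(total + 1)
    if alpha <= 1e-12:
        logp1 = stats.poisson.logpmf(ks, n1 * mu)
        logp2 = stats.poisson.logpmf(total - ks, n2 * mu)
    else:
        r1, r2 = n1 / alpha, n2 / alpha
        p1 = r1 / (r1 + n1 * mu)
        p2 = r2 / (r2 + n2 * mu)
        logp1 = stats.nbinom.logpmf(ks, r1, p1)
        logp2 = stats.nbinom.logpmf(total - ks, r2, p2)
    logjoint = logp1 + logp2
    logjoint -= logjoint.max()
    w = np.exp(logjoint)
    w /= w.sum()
    obs = w[int(round(s1))]
    return float(np.minimum(w[w <= obs * (1 + 1e-12)].sum(), 1.0))


def differential_counts(
    counts: pd.DataFrame,
    groups: Sequence[str],
    alpha: float = 0.05,
    mode: str = "p",
    max_exact_total: int = 50_000,
) -> pd.DataFrame:
    """Two-group negative-binomial differential test per feature.

    Libraries are normalized by median-of-ratios; a pooled dispersion is
    estimated by the method of moments; each feature gets a conditional
    exact NB test on its (normalized) group sums. `mode` selects the call
    threshold: raw p < alpha (accessibility-region convention) or BH
    q < alpha (expression convention). All-zero features are reported
    untested.
    """
    groups = np.asarray(groups)
    levels = pd.unique(groups)
    if len(levels) != 2:
        raise ValueError("exactly two groups required")
    mat = counts.to_numpy(dtype=float)
    if (mat.sum(axis=0)[groups == levels[0]].sum() == 0
            or mat.sum(axis=0)[groups == levels[1]].sum() == 0):
        raise ValueError("a group has zero total counts")
    sf = _size_factors(mat)
    norm = mat / sf[None, :]
    g1 = norm[:, groups == levels[0]]
    g2 = norm[:, groups == levels[1]]
    n1, n2 = g1.shape[1], g2.shape[1]
    # pooled method-of-moments dispersion across features
    mean_all = norm.mean(axis=1)
    var_within = (
        g1.var(axis=1, ddof=1) * (n1 - 1) + g2.var(axis=1, ddof=1) * (n2 - 1)
    ) / max(1, n1 + n2 - 2)
    ok_feat = mean_all > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = (var_within - mean_all) / mean_all**2
    disp = disp[ok_feat & np.isfinite(disp)]
    pooled_alpha = float(max(np.median(disp), 0.0)) if disp.size else 0.0

    rows = []
    tested_p: List[float] = []
    tested_idx: List[int] = []
    for i in range(mat.shape[0]):
        m1, m2 = g1[i].mean(), g2[i].mean()
        base = {"base_mean": float(mean_all[i]),
                "log2_fc": float(np.log2((m2 + 0.5) / (m1 + 0.5)))}
        if mat[i].sum() == 0:
            rows.append({**base, "p_value": np.nan, "tested": False})
            continue
        s1, s2 = g1[i].sum(), g2[i].sum()
        if s1 + s2 > max_exact_total:
            # Wald fallback for very deep features
            se = np.sqrt((1 / max(m1, 0.5) + pooled_alpha) / n1
                         + (1 / max(m2, 0.5) + pooled_alpha) / n2) / np.log(2)
            z = base["log2_fc"] / se
            p = float(2 * stats.norm.sf(abs(z)))
        else:
            p = _nb_exact_pvalue(round(s1), round(s2), n1, n2, pooled_alpha)
        rows.append({**base, "p_value": p, "tested": True})
        tested_p.append(p)
        tested_idx.append(i)
    out = pd.DataFrame(rows, index=counts.index)
    out["q_value"] = np.nan
    if tested_p:
        out.loc[out.index[tested_idx], "q_value"] = false_discovery_control(
            np.array(tested_p), method="bh"
        )
    key = "p_value" if mode == "p" else "q_value"
    out["significant"] = out[key] < alpha
    out.loc[~out["tested"], "significant"] = False
    return out


def predict_enhancer_candidates(
    m: ContactMatrix,
    tads: TadSet,
    promoters: Sequence[GenomicInterval],
    fdr: float = 0.05,
    min_dist_bins: int = 3,
    min_fold: float = 1.5,
) -> List[GenomicInterval]:
    """Contact-predicted enhancer bins from within-TAD promoter contacts.

    The expectation for a promoter-bin x other-bin cell is hierarchical:
    genome distance decay x bin biases x a per-TAD scale factor (each
    TAD's overall contact elevation), so a cell must exceed its own TAD's
    background. Upper-tail Poisson residual test, BH across all tested
    pairs; bins outside every TAD are never emitted. The matrix
    resolution sets the candidate bin size (25 kb conventionally).

    Contacts closer than `min_dist_bins` are not tested (adjacent-bin
    cells sit on the steepest part of the decay, where any smooth profile
    underfits and raw counts are huge, so tiny relative misfits would
    dominate); a candidate must also exceed `min_fold` x its expectation.
    """
    if not tads.tads:
        warnings.warn("no TADs supplied; no enhancer candidates", RuntimeWarning)
        return []
    res = m.resolution
    model = ExpectedModel(m, min_dist_bins=1, refine=1,
                          max_dist_bp=max(len(t) for t in tads.tads) + res)
    prom_bins: Dict[str, set] = {}
    for p in promoters:
        prom_bins.setdefault(p.chrom, set()).add(p.midpoint // res)
    recs: List[Tuple[str, int, float, float]] = []  # chrom, other_bin, k, mu
    for chrom in m.chroms:
        dense = model._dense[chrom]
        n = dense.shape[0]
        pbins = prom_bins.get(chrom, set())
        for t in tads.tads:
            if t.chrom != chrom:
                continue
            b0, b1 = t.start // res, min(-(-t.end // res), n)
            bins = np.arange(b0, b1)
            nb = len(bins)
            if nb < 4:
                continue
            bias = model.bias[chrom][b0:b1]
            sub = dense[b0:b1, b0:b1] / (bias[:, None] * bias[None, :])
            # TAD-local distance profile, isotonic-decreasing in d
            ds, means, wts = [], [], []
            for d in range(1, nb):
                diag = np.diagonal(sub, d)
                ok = np.isfinite(diag)
                if ok.any():
                    ds.append(d)
                    means.append(diag[ok].mean())
                    wts.append(ok.sum())
            if len(ds) < 2:
                continue
            from sklearn.isotonic import IsotonicRegression

            iso = IsotonicRegression(increasing=False, out_of_bounds="clip")
            iso.fit(np.log10(np.array(ds) + 0.5), means, sample_weight=wts)
            e_local = np.full(nb, np.nan)
            e_local[1:] = iso.predict(np.log10(np.arange(1, nb) + 0.5))
            t_prom = [b for b in bins if b in pbins]
            for pb in t_prom:
                others = bins[bins != pb]
                d = np.abs(others - pb)
                keep = d >= min_dist_bins
                others, d = others[keep], d[keep]
                mu = e_local[d] * bias[pb - b0] * bias[others - b0]
                obs = dense[pb, others]
                for ob, k, u in zip(others, obs, mu):
                    if np.isfinite(u) and u > 0:
                        recs.append((chrom, int(ob), float(k), float(u)))
    if not recs:
        return []
    ks = np.array([r[2] for r in recs])
    mus = np.array([r[3] for r in recs])
    p = stats.poisson.sf(ks - 1, mus)
    q = false_discovery_control(p, method="bh")
    hit = (q < fdr) & (ks >= min_fold * mus)
    out_bins = sorted({(recs[i][0], recs[i][1]) for i in np.flatnonzero(hit)})
    return [
        GenomicInterval(c, b * res, min((b + 1) * res, m.layout.length(c)))
        for c, b in out_bins
    ]


def classify_elements(
    union_peaks: Sequence[UnionPeak],
    genes: Sequence[Gene],
    enhancer_candidates: Sequence[GenomicInterval],
    anchors: Sequence[GenomicInterval],
    flank: int = PROMOTER_FLANK,
) -> Tuple[List[UnionPeak], List[AnchorElement]]:
    """Sequential P/E/O classification of peaks and P/E/O/N anchor labels.

    Expressed genes (mean FPKM over all conditions > 0) define promoter
    windows. Precedence is sequential: P then E then O; each peak gets
    exactly one class. Anchors take the highest-priority class among
    overlapping peaks, else N.
    """
    peak_ivs = [pk.interval for pk in union_peaks]
    prom_windows = [
        g.promoter(flank) for g in genes if g.mean_fpkm() > 0
    ]
    is_p = intersect_any(peak_ivs, prom_windows) if prom_windows else np.zeros(
        len(peak_ivs), bool)
    is_e = intersect_any(peak_ivs, list(enhancer_candidates)) if len(
        enhancer_candidates) else np.zeros(len(peak_ivs), bool)
    for pk, p_flag, e_flag in zip(union_peaks, is_p, is_e):
        pk.cls = "P" if p_flag else ("E" if e_flag else "O")
    anchor_elements = []
    for anc in anchors:
        hits = [k for k, iv in enumerate(peak_ivs) if iv.overlaps(anc)]
        if hits:
            classes = {union_peaks[k].cls for k in hits}
            cls = next(c for c in CLASS_PRIORITY if c in classes)
        else:
            cls = "N"
        anchor_elements.append(AnchorElement(anc, cls, hits))
    return list(union_peaks), anchor_elements


def _pair_label(c1: str, c2: str) -> str:
    a, b = sorted([c1, c2])
    return f"{a}-{b}"


def wire_and_census(
    loops: Sequence[Loop],
    anchor_elements: Sequence[AnchorElement],
    genes: Sequence[Gene],
    condition: str,
    flank: int = PROMOTER_FLANK,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """One interaction pair per loop, plus the unordered class-pair census.

    Genes are wired to a loop when their promoter window overlaps one of
    its P anchors. Returns (pairs, census); census counts sum to the
    number of loops.
    """
    by_key = {(a.anchor.chrom, a.anchor.start, a.anchor.end): a
              for a in anchor_elements}
    rows = []
    for li, lp in enumerate(loops):
        elems = []
        for anc in (lp.anchor1, lp.anchor2):
            key = (anc.chrom, anc.start, anc.end)
            if key not in by_key:
                raise KeyError(f"loop anchor {key} missing from anchor elements")
            elems.append(by_key[key])
        wired = []
        for g in genes:
            prom = g.promoter(flank)
            for el in elems:
                if el.cls == "P" and prom.overlaps(el.anchor):
                    wired.append(g.gene_id)
                    el.gene_ids.append(g.gene_id)
                    break
        rows.append({
            "loop_index": li,
            "chrom": lp.chrom,
            "class_pair": _pair_label(elems[0].cls, elems[1].cls),
            "class1": elems[0].cls,
            "class2": elems[1].cls,
            "gene_ids": ",".join(sorted(set(wired))),
            "condition": condition,
        })
    pairs = pd.DataFrame(rows)
    if len(pairs):
        census = (
            pairs.groupby("class_pair").size().rename("count").reset_index()
        )
        census["fraction"] = census["count"] / len(pairs)
        census = census.sort_values("count", ascending=False).reset_index(drop=True)
    else:
        census = pd.DataFrame(columns=["class_pair", "count", "fraction"])
    return pairs, census


def expression_effects(
    genes: Sequence[Gene],
    categories: Mapping[str, str],
    pairs: pd.DataFrame,
    anchor_elements: Sequence[AnchorElement],
    union_peaks: Sequence[UnionPeak],
    loops: Sequence[Loop],
    condition: str,
    min_genes: int = 3,
) -> Dict[str, object]:
    """Integrative expression report for one condition.

    Reports rank-sum tests of looped gene categories (C vs A, B vs A),
    the correlation of wired enhancer activity with target expression,
    co-expression of gene pairs anchored by one loop, and median FPKM by
    looped-enhancer count.
    """
    by_id = {g.gene_id: g for g in genes}
    fpkm = {g.gene_id: g.expression.get(condition, np.nan) for g in genes}
    out: Dict[str, object] = {"condition": condition}

    def ranksum(cat_x: str, cat_y: str) -> Dict[str, float]:
        x = [fpkm[g] for g, c in categories.items() if c == cat_x and np.isfinite(fpkm[g])]
        y = [fpkm[g] for g, c in categories.items() if c == cat_y and np.isfinite(fpkm[g])]
        if len(x) < min_genes or len(y) < min_genes:
            return {"n_x": len(x), "n_y": len(y), "p_value": np.nan,
                    "note": "category too small; test skipped"}
        if np.ptp(x + y) == 0:
            return {"n_x": len(x), "n_y": len(y), "p_value": np.nan,
                    "note": "degenerate (identical values)"}
        res = stats.mannwhitneyu(x, y, alternative="two-sided")
        return {"n_x": len(x), "n_y": len(y),
                "median_x": float(np.median(x)), "median_y": float(np.median(y)),
                "p_value": float(res.pvalue)}

    out["C_vs_A"] = ranksum("C", "A")
    out["B_vs_A"] = ranksum("B", "A")

    # per-gene looped enhancer count and enhancer activity pairing
    enh_count: Dict[str, int] = {g.gene_id: 0 for g in genes}
    enh_pairs: List[Tuple[float, float]] = []  # (enhancer enrichment, target fpkm)
    for row in pairs.itertuples(index=False):
        if not row.gene_ids:
            continue
        lp = loops[row.loop_index]
        gids = row.gene_ids.split(",")
        elems = []
        for anc in (lp.anchor1, lp.anchor2):
            el = next(a for a in anchor_elements
                      if (a.anchor.chrom, a.anchor.start, a.anchor.end)
                      == (anc.chrom, anc.start, anc.end))
            elems.append(el)
        e_elems = [el for el in elems if el.cls == "E"]
        for gid in gids:
            if e_elems:
                enh_count[gid] += len(e_elems)
                for el in e_elems:
                    enr = np.mean([union_peaks[k].enrichment for k in el.peak_indices])
                    enh_pairs.append((float(enr), fpkm.get(gid, np.nan)))
    if len(enh_pairs) >= min_genes:
        e, f = np.array(enh_pairs).T
        ok = np.isfinite(e) & np.isfinite(f)
        if ok.sum() >= min_genes and np.std(e[ok]) > 0 and np.std(f[ok]) > 0:
            r, p = stats.pearsonr(e[ok], np.log2(1 + f[ok]))
            out["enhancer_activity_vs_expression"] = {
                "r": float(r), "p_value": float(p), "n": int(ok.sum())}
    # co-expression of gene pairs co-anchored by one loop
    co_pairs = []
    for row in pairs.itertuples(index=False):
        gids = [g for g in row.gene_ids.split(",") if g]
        for a in range(len(gids)):
            for b in range(a + 1, len(gids)):
                co_pairs.append((fpkm[gids[a]], fpkm[gids[b]]))
    if len(co_pairs) >= min_genes:
        x, y = np.array(co_pairs).T
        ok = np.isfinite(x) & np.isfinite(y)
        if ok.sum() >= min_genes and np.std(x[ok]) > 0 and np.std(y[ok]) > 0:
            r, p = stats.pearsonr(np.log2(1 + x[ok]), np.log2(1 + y[ok]))
            out["anchored_coexpression"] = {
                "r": float(r), "p_value": float(p), "n": int(ok.sum())}
    # median FPKM by looped enhancer count
    bins = {"0": [], "1": [], "2": [], "3+": []}
    for gid, k in enh_count.items():
        if categories.get(gid) != "C" and k == 0:
            key = "0"
        else:
            key = "3+" if k >= 3 else str(k)
        if np.isfinite(fpkm.get(gid, np.nan)):
            bins[key].append(fpkm[gid])
    out["median_fpkm_by_enhancer_count"] = {
        k: (float(np.median(v)) if v else np.nan) for k, v in bins.items()
    }
    out["n_genes_by_enhancer_count"] = {k: len(v) for k, v in bins.items()}
    looped = bins["1"] + bins["2"] + bins["3+"]
    if looped and bins["0"]:
        out["enhancer_trend"] = {
            "median_0": float(np.median(bins["0"])),
            "median_ge1": float(np.median(looped)),
            "delta": float(np.median(looped) - np.median(bins["0"])),
            "n_ge1": len(looped),
        }
    return out
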