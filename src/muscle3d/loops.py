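"""Point-interaction (loop) calling, comparison and aggregate analysis.

Significant interactions are found Fit-Hi-C style: a smoothed, monotone
distance-decay expectation with bin biases, an upper-tail Poisson test per
cell and Benjamini-Hochberg control. Loop calling then applies local
HICCUPS-style background filters (donut, lower-left, horizontal and
vertical stripes) so that only point-like enrichments survive. APA
averages observed/expected windows around loop pixels; P2LL is the center
over the mean of the lower-left quadrant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
from scipy import stats
from scipy.stats import false_discovery_control
from sklearn.isotonic import IsotonicRegression

from .genome import Gene, GenomicInterval
from .hic import ContactMatrix

__all__ = [
    "Loop",
    "ApaResult",
    "ExpectedModel",
    "call_significant_interactions",
    "call_loops",
    "differential_loops",
    "apa",
    "categorize_genes_by_loops",
]


@dataclass
class Loop:
    """A called point interaction between two ordered anchors."""

    anchor1: GenomicInterval
    anchor2: GenomicInterval
    resolution: int
    count: float
    expected: float
    enrichment: Dict[str, float] = field(default_factory=dict)
    p_value: float = np.nan
    q_value: float = np.nan
    stage_specific: bool = False

    def __post_init__(self) -> None:
        if self.anchor1.chrom != self.anchor2.chrom:
            raise ValueError("loop anchors must be on one chromosome")
        if self.anchor1.start > self.anchor2.start:
            self.anchor1, self.anchor2 = self.anchor2, self.anchor1
        if self.length <= 0:
            raise ValueError("loop length must be > 0")

    @property
    def chrom(self) -> str:
        return self.anchor1.chrom

    @property
    def length(self) -> int:
        return self.anchor2.midpoint - self.anchor1.midpoint

    def key(self) -> Tuple[str, int, int]:
        return (self.chrom, self.anchor1.start, self.anchor2.start)


class ExpectedModel:
    """Distance-decay expectation with per-bin biases for one matrix.

    The expectation for cell (i, j) at distance d is E(d) * b_i * b_j with
    b the relative cis coverage and E(d) an isotonic-decreasing fit of the
    bias-normalized mean count per distance, re-estimated after removing
    outlier cells (`refine` passes).
    """

    def __init__(
        self,
        m: ContactMatrix,
        min_dist_bins: int = 2,
        max_dist_bp: int = 3_000_000,
        refine: int = 2,
        outlier_q: float = 0.1,
        min_cells_per_stratum: int = 50,
    ):
        self.m = m
        self.min_dist_bins = min_dist_bins
        self.max_dist_bins = max(min_dist_bins + 1, max_dist_bp // m.resolution)
        self.bias: Dict[str, np.ndarray] = {}
        self.expected_d: Dict[str, np.ndarray] = {}
        self._dense: Dict[str, np.ndarray] = {}
        self.min_cells = min_cells_per_stratum
        self._fit(refine, outlier_q)

    def _diag_stats(
        self, chrom: str, exclude: Optional[Dict[str, np.ndarray]] = None
    ) -> Tuple[np.ndarray, np.ndarray]:
        N = self._norm[chrom]
        n = N.shape[0]
        dmax = min(self.max_dist_bins, n - 1)
        sums = np.zeros(dmax + 1)
        cnts = np.zeros(dmax + 1)
        for d in range(self.min_dist_bins, dmax + 1):
            diag = np.diagonal(N, d)
            ok = np.isfinite(diag)
            if exclude is not None:
                ex = np.diagonal(exclude[chrom], d).astype(bool)
                ok = ok & ~ex
            sums[d] = diag[ok].sum()
            cnts[d] = ok.sum()
        return sums, cnts

    def _fit(self, refine: int, outlier_q: float) -> None:
        m = self.m
        self._norm = {}
        for chrom in m.chroms:
            cov = m.cis_coverage(chrom).astype(float)
            mask = m.mask(chrom) | (cov <= 0)
            b = np.ones(len(cov))
            b[mask] = np.nan
            self.bias[chrom] = b
            dense = m.dense(chrom)
            self._dense[chrom] = dense
            self._norm[chrom] = dense.copy()
        exclude: Optional[Dict[str, np.ndarray]] = None
        for it in range(refine + 1):
            # alternate the distance curve and the per-bin bias a few times:
            # biases are deviations from the distance profile, not raw
            # coverage, so chromosome-end truncation does not distort them
            for _bias_round in range(3):
                self._refit_curve(exclude)
                self._refit_bias()
            if it == refine:
                break
            # flag outlier cells and refit without them
            exclude = {}
            for chrom in m.chroms:
                i, j, p = self._cell_pvalues(chrom)
                ex = np.zeros_like(self._norm[chrom], dtype=bool)
                if len(p):
                    q = false_discovery_control(p, method="bh")
                    out = q < outlier_q
                    ex[i[out], j[out]] = True
                    ex[j[out], i[out]] = True
                exclude[chrom] = ex

    def _refit_curve(self, exclude: Optional[Dict[str, np.ndarray]]) -> None:
        m = self.m
        dmax = max(min(self.max_dist_bins, self._norm[c].shape[0] - 1)
                   for c in m.chroms)
        sums = np.zeros(dmax + 1)
        cnts = np.zeros(dmax + 1)
        for chrom in m.chroms:
            s, c = self._diag_stats(chrom, exclude)
            sums[:len(s)] += s
            cnts[:len(c)] += c
        ds = np.arange(self.min_dist_bins, dmax + 1)
        ok = cnts[ds] > 0
        mean = np.zeros(len(ds))
        mean[ok] = sums[ds][ok] / cnts[ds][ok]
        iso = IsotonicRegression(increasing=False, out_of_bounds="clip")
        iso.fit(np.log10(ds[ok] + 0.5), mean[ok], sample_weight=cnts[ds][ok])
        fitted = np.full(dmax + 1, np.nan)
        fitted[ds] = iso.predict(np.log10(ds + 0.5))
        for chrom in m.chroms:
            self.expected_d[chrom] = fitted

    def _refit_bias(self) -> None:
        """b_i = mean of raw_ij / (E(d) b_j) over in-range cells of row i."""
        for chrom in self.m.chroms:
            dense = self._dense[chrom]
            n = dense.shape[0]
            b = self.bias[chrom]
            e = self.expected_d[chrom]
            dmax = len(e) - 1
            num = np.zeros(n)
            den = np.zeros(n)
            for d in range(self.min_dist_bins, min(dmax, n - 1) + 1):
                if not np.isfinite(e[d]) or e[d] <= 0:
                    continue
                diag = np.diagonal(dense, d)
                bj = b[d:]
                bi = b[:n - d]
                ok_j = np.isfinite(bj)
                ok_i = np.isfinite(bi)
                contrib_i = np.where(ok_j, diag / (e[d] * np.where(ok_j, bj, 1)), 0.0)
                num[:n - d] += contrib_i
                den[:n - d] += ok_j.astype(float)
                contrib_j = np.where(ok_i, diag / (e[d] * np.where(ok_i, bi, 1)), 0.0)
                num[d:] += contrib_j
                den[d:] += ok_i.astype(float)
            with np.errstate(invalid="ignore", divide="ignore"):
                new_b = num / den
            bad = ~np.isfinite(new_b) | (new_b <= 0) | ~np.isfinite(b)
            new_b[bad] = np.nan
            live = new_b[np.isfinite(new_b)]
            if live.size:
                new_b /= live.mean()
            self.bias[chrom] = new_b
            self._norm[chrom] = dense / (new_b[:, None] * new_b[None, :])

    def expected_cell(self, chrom: str, i: np.ndarray, j: np.ndarray) -> np.ndarray:
        d = np.abs(np.asarray(j) - np.asarray(i))
        e = self.expected_d[chrom][d]
        return e * self.bias[chrom][i] * self.bias[chrom][j]

    def oe(self, chrom: str) -> np.ndarray:
        """Dense observed/expected (NaN at masked bins / out-of-range d)."""
        n = self._norm[chrom].shape[0]
        d = np.abs(np.arange(n)[:, None] - np.arange(n)[None, :])
        dmax = len(self.expected_d[chrom]) - 1
        e = np.where(d <= dmax, self.expected_d[chrom][np.minimum(d, dmax)], np.nan)
        with np.errstate(divide="ignore", invalid="ignore"):
            return self._norm[chrom] / e

    def _cell_pvalues(self, chrom: str) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Upper-tail Poisson p for non-empty upper-triangle cells in range."""
        dense = self._dense[chrom]
        n = dense.shape[0]
        iu, ju = np.nonzero(np.triu(dense, k=self.min_dist_bins))
        d = ju - iu
        sel = d <= min(self.max_dist_bins, n - 1)
        iu, ju = iu[sel], ju[sel]
        mu = self.expected_cell(chrom, iu, ju)
        k = dense[iu, ju]
        ok = np.isfinite(mu) & (mu > 0)
        iu, ju, mu, k = iu[ok], ju[ok], mu[ok], k[ok]
        p = stats.poisson.sf(k - 1, mu)
        return iu, ju, p


def call_significant_interactions(
    m: ContactMatrix,
    fdr: float = 0.05,
    min_dist_bins: int = 2,
    max_dist_bp: int = 3_000_000,
    model: Optional[ExpectedModel] = None,
) -> List[Loop]:
    """Cells whose count exceeds the distance-decay expectation at q < fdr.

    Cells with zero counts are never significant (upper tail); the BH
    correction runs across all tested (non-empty, in-range) cells.
    """
    model = model or ExpectedModel(m, min_dist_bins, max_dist_bp)
    res = m.resolution
    recs = []
    for chrom in m.chroms:
        iu, ju, p = model._cell_pvalues(chrom)
        mu = model.expected_cell(chrom, iu, ju)
        k = model._dense[chrom][iu, ju]
        recs.append((chrom, iu, ju, p, mu, k))
    all_p = np.concatenate([r[3] for r in recs]) if recs else np.array([])
    if len(all_p) == 0:
        return []
    q = false_discovery_control(all_p, method="bh")
    loops: List[Loop] = []
    off = 0
    for chrom, iu, ju, p, mu, k in recs:
        qs = q[off:off + len(p)]
        off += len(p)
        keep = qs < fdr
        L = m.layout.length(chrom)
        for i, j, pv, qv, e, cnt in zip(iu[keep], ju[keep], p[keep], qs[keep],
                                        mu[keep], k[keep]):
            loops.append(Loop(
                GenomicInterval(chrom, i * res, min((i + 1) * res, L)),
                GenomicInterval(chrom, j * res, min((j + 1) * res, L)),
                res, float(cnt), float(e), {}, float(pv), float(qv),
            ))
    return loops


def _local_enrichment(
    oe: np.ndarray, i: int, j: int, w: int, inner: int = 1
) -> Dict[str, float]:
    """Center O/E over mean O/E of four local neighborhoods."""
    n = oe.shape[0]
    lo_i, hi_i = max(0, i - w), min(n, i + w + 1)
    lo_j, hi_j = max(0, j - w), min(n, j + w + 1)
    win = oe[lo_i:hi_i, lo_j:hi_j]
    ci, cj = i - lo_i, j - lo_j
    center = oe[i, j]
    out: Dict[str, float] = {}
    mask_inner = np.zeros_like(win, dtype=bool)
    mask_inner[max(0, ci - inner):ci + inner + 1, max(0, cj - inner):cj + inner + 1] = True

    def mean_of(sel: np.ndarray) -> float:
        vals = win[sel & ~mask_inner]
        vals = vals[np.isfinite(vals)]
        return float(vals.mean()) if vals.size else np.nan

    ring = np.ones_like(win, dtype=bool)
    out["donut"] = mean_of(ring)
    ll = np.zeros_like(win, dtype=bool)
    ll[ci + 1:, :cj] = True
    out["lower_left"] = mean_of(ll)
    horiz = np.zeros_like(win, dtype=bool)
    horiz[max(0, ci - inner):ci + inner + 1, :] = True
    out["horizontal"] = mean_of(horiz)
    vert = np.zeros_like(win, dtype=bool)
    vert[:, max(0, cj - inner):cj + inner + 1] = True
    out["vertical"] = mean_of(vert)
    for key in list(out):
        denom = out[key]
        out[key] = center / denom if denom and np.isfinite(denom) and denom > 0 else np.inf
    return out


def call_loops(
    matrices: Union[ContactMatrix, Dict[int, ContactMatrix]],
    w: int = 5,
    fold_donut: float = 1.75,
    fold_lower_left: float = 1.75,
    fold_stripe: float = 1.5,
    fdr: float = 0.05,
    min_dist_bins: int = 2,
    max_dist_bp: int = 3_000_000,
) -> List[Loop]:
    """Loops = significant interactions passing all local background filters.

    With matrices at several resolutions, loops found at more than one are
    merged by anchor overlap, keeping the finer-resolution coordinates.
    """
    if isinstance(matrices, ContactMatrix):
        matrices = {matrices.resolution: matrices}
    per_res: Dict[int, List[Loop]] = {}
    for res in sorted(matrices):
        m = matrices[res]
        if w >= min(m.n_bins(c) for c in m.chroms):
            raise ValueError("neighborhood w too large for this matrix")
        model = ExpectedModel(m, min_dist_bins, max_dist_bp)
        cands = call_significant_interactions(
            m, fdr, min_dist_bins, max_dist_bp, model=model
        )
        oes = {c: model.oe(c) for c in m.chroms}
        passing = []
        local_p = []
        for lp in cands:
            i = lp.anchor1.start // res
            j = lp.anchor2.start // res
            if j - i <= w:
                # the local background windows would cross the diagonal
                continue
            enr = _local_enrichment(oes[lp.chrom], i, j, w)
            lp.enrichment = enr
            if not (
                enr["donut"] >= fold_donut
                and enr["lower_left"] >= fold_lower_left
                and enr["horizontal"] >= fold_stripe
                and enr["vertical"] >= fold_stripe
            ):
                continue
            # Poisson test of the center against each neighborhood's own
            # expectation; the weakest neighborhood governs
            mu = model.expected_cell(lp.chrom, np.array([i]), np.array([j]))[0]
            p_worst = 0.0
            for key in ("donut", "lower_left", "horizontal", "vertical"):
                ratio = enr[key]
                lam_nb = lp.count / ratio if np.isfinite(ratio) and ratio > 0 else mu
                lam_nb = max(lam_nb, 1e-12)
                p_worst = max(p_worst, float(stats.poisson.sf(lp.count - 1, lam_nb)))
            passing.append(lp)
            local_p.append(p_worst)
        kept = []
        if passing:
            # BH against the full search space: candidates were selected
            # from every tested cell, so that count is the correction m
            n_tests = sum(len(model._cell_pvalues(c)[2]) for c in m.chroms)
            p_arr = np.array(local_p)
            order = np.argsort(p_arr)
            ranks = np.empty_like(order)
            ranks[order] = np.arange(1, len(p_arr) + 1)
            q_raw = p_arr * n_tests / ranks
            # enforce monotonicity in p-order
            q_sorted = np.minimum.accumulate(q_raw[order][::-1])[::-1]
            q_local = np.empty_like(q_raw)
            q_local[order] = np.minimum(q_sorted, 1.0)
            for lp, qv in zip(passing, q_local):
                if qv < fdr:
                    kept.append(lp)
        per_res[res] = kept
    # merge across resolutions: finer coordinates win
    merged: List[Loop] = []
    for res in sorted(per_res):
        for lp in per_res[res]:
            dup = any(
                ml.chrom == lp.chrom
                and ml.anchor1.overlaps(lp.anchor1)
                and ml.anchor2.overlaps(lp.anchor2)
                for ml in merged
            )
            if not dup:
                merged.append(lp)
    merged.sort(key=Loop.key)
    return merged


def differential_loops(
    loops_x: Sequence[Loop],
    m_x: ContactMatrix,
    loops_y: Sequence[Loop],
    m_y: ContactMatrix,
    fdr: float = 0.05,
) -> Tuple[List[Loop], List[Loop]]:
    """Stage-specific loops by presence/absence in the other matrix.

    A loop of x is x-specific when its pixel in m_y is not significantly
    enriched over m_y's local expectation (BH across the tested loops).
    """
    if m_x.layout != m_y.layout:
        raise ValueError("matrices must share a layout")

    def specific(loops: Sequence[Loop], other: ContactMatrix) -> List[Loop]:
        if not loops:
            return []
        model = ExpectedModel(other)
        res = other.resolution
        ps = []
        for lp in loops:
            i = lp.anchor1.midpoint // res
            j = lp.anchor2.midpoint // res
            mu = model.expected_cell(lp.chrom, np.array([i]), np.array([j]))[0]
            k = model._dense[lp.chrom][i, j]
            p = stats.poisson.sf(k - 1, mu) if np.isfinite(mu) and mu > 0 else 1.0
            ps.append(p)
        q = false_discovery_control(np.array(ps), method="bh")
        out = []
        for lp, qv in zip(loops, q):
            if qv >= fdr:
                lp.stage_specific = True
                out.append(lp)
        return out

    return specific(loops_x, m_y), specific(loops_y, m_x)


@dataclass
class ApaResult:
    """Aggregate peak analysis over a loop list."""

    matrix: np.ndarray  # (2w+1) x (2w+1) mean O/E
    p2ll: float
    zscore_ll: float
    n_loops: int


def apa(
    loops: Sequence[Loop],
    m: ContactMatrix,
    w: int = 10,
    model: Optional[ExpectedModel] = None,
) -> ApaResult:
    """Average O/E windows centered on loop pixels.

    Loops closer than w bins to the diagonal or the matrix edge are
    excluded. P2LL = center / mean(lower-left w x w quadrant);
    ZscoreLL = (center - mean LL) / sd LL.
    """
    model = model or ExpectedModel(m, max_dist_bp=max(
        (lp.anchor2.midpoint - lp.anchor1.midpoint for lp in loops), default=3_000_000
    ) + (w + 2) * m.resolution)
    res = m.resolution
    oes = {c: model.oe(c) for c in m.chroms}
    acc = np.zeros((2 * w + 1, 2 * w + 1))
    cnt = np.zeros_like(acc)
    used = 0
    for lp in loops:
        i = lp.anchor1.midpoint // res
        j = lp.anchor2.midpoint // res
        n = oes[lp.chrom].shape[0]
        if j - i <= w or i - w < 0 or j + w >= n or i + w >= n or j - w < 0:
            continue
        win = oes[lp.chrom][i - w:i + w + 1, j - w:j + w + 1]
        ok = np.isfinite(win)
        acc[ok] += win[ok]
        cnt += ok
        used += 1
    if used == 0:
        raise ValueError("no usable loops for APA (all too close to diagonal/edge)")
    with np.errstate(invalid="ignore"):
        mean = acc / cnt
    p2ll, z = quadrant_stats(mean)
    return ApaResult(mean, p2ll, z, used)


def quadrant_stats(mean: np.ndarray) -> Tuple[float, float]:
    """P2LL and ZscoreLL of an odd-sized aggregate window.

    The lower-left quadrant is the w x w block between the center pixel
    and the diagonal (larger first index, smaller second index).
    """
    if mean.shape[0] != mean.shape[1] or mean.shape[0] % 2 == 0:
        raise ValueError("window must be square and odd-sized")
    w = mean.shape[0] // 2
    center = mean[w, w]
    ll = mean[w + 1:, :w]
    ll_vals = ll[np.isfinite(ll)]
    p2ll = float(center / ll_vals.mean()) if ll_vals.size else np.nan
    z = (float((center - ll_vals.mean()) / ll_vals.std())
         if ll_vals.size > 1 else np.nan)
    return p2ll, z


def categorize_genes_by_loops(
    genes: Sequence[Gene], loops: Sequence[Loop], flank: int = 3000
) -> Dict[str, str]:
    """Assign each gene to A (outside loops), B (inside a loop span) or C
    (promoter overlaps a loop anchor); C takes precedence over B."""
    by_chrom: Dict[str, List[Loop]] = {}
    for lp in loops:
        by_chrom.setdefault(lp.chrom, []).append(lp)
    out: Dict[str, str] = {}
    for g in genes:
        prom = g.promoter(flank)
        cat = "A"
        for lp in by_chrom.get(g.chrom, []):
            if prom.overlaps(lp.anchor1) or prom.overlaps(lp.anchor2):
                cat = "C"
                break
            if prom.start >= lp.anchor1.start and prom.end <= lp.anchor2.end:
                cat = "B"
        out[g.gene_id] = cat
    return out
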