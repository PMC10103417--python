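"""Contact-matrix construction, ICE balancing, decay curves and comparisons.

A :class:`ContactMatrix` holds per-chromosome symmetric sparse cis count
matrices, per-chromosome-pair trans blocks, and (after ICE) per-bin
balancing weights; the balanced value of a cell is ``raw * w_i * w_j``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .genome import GenomeLayout

logger = logging.getLogger(__name__)

__all__ = [
    "ContactMatrix",
    "DecayCurve",
    "bin_valid_pairs",
    "ice_normalize",
    "matrix_correlation",
    "contact_decay",
    "resolution_capability",
    "trans_contact_summary",
    "oe_matrix",
    "expected_by_distance",
]


class ContactMatrix:
    """Binned Hi-C contact counts at one resolution.

    cis[chrom] is a symmetric CSR matrix of raw counts (both triangles
    populated, diagonal stored once). trans[(c1, c2)] with c1 before c2 in
    layout order is a rectangular CSR block. weights[chrom] is a positive
    per-bin array with NaN at masked bins, or None before balancing.
    """

    def __init__(
        self,
        layout: GenomeLayout,
        resolution: int,
        cis: Dict[str, sp.csr_matrix],
        trans: Optional[Dict[Tuple[str, str], sp.csr_matrix]] = None,
        weights: Optional[Dict[str, np.ndarray]] = None,
    ):
        self.layout = layout
        self.resolution = int(resolution)
        self.cis = cis
        self.trans = trans or {}
        self.weights = weights
        self.converged: Optional[bool] = None

    # -- basic accessors ---------------------------------------------------

    def n_bins(self, chrom: str) -> int:
        return self.layout.n_bins(chrom, self.resolution)

    @property
    def chroms(self) -> List[str]:
        return self.layout.chroms

    def dense(self, chrom: str) -> np.ndarray:
        return np.asarray(self.cis[chrom].todense(), dtype=float)

    def balanced(self, chrom: str) -> np.ndarray:
        """Dense balanced cis matrix; masked rows/columns are NaN."""
        if self.weights is None:
            raise ValueError("matrix is not balanced; run ice_normalize first")
        w = self.weights[chrom]
        return self.dense(chrom) * w[:, None] * w[None, :]

    def mask(self, chrom: str) -> np.ndarray:
        """Boolean array, True where the bin is masked out."""
        if self.weights is None:
            return np.zeros(self.n_bins(chrom), dtype=bool)
        return ~np.isfinite(self.weights[chrom])

    def cis_coverage(self, chrom: str) -> np.ndarray:
        return np.asarray(self.cis[chrom].sum(axis=1)).ravel()

    def coverage(self, chrom: str) -> np.ndarray:
        """Per-bin total raw pair count, cis plus trans."""
        cov = self.cis_coverage(chrom).astype(float)
        for (c1, c2), block in self.trans.items():
            if c1 == chrom:
                cov += np.asarray(block.sum(axis=1)).ravel()
            elif c2 == chrom:
                cov += np.asarray(block.sum(axis=0)).ravel()
        return cov

    def total_cis(self) -> int:
        # upper triangle + diagonal: each off-diagonal pair stored twice
        tot = 0.0
        for c in self.chroms:
            m = self.cis[c]
            tot += (m.sum() + m.diagonal().sum()) / 2.0
        return int(round(tot))

    def total_trans(self) -> int:
        return int(sum(b.sum() for b in self.trans.values()))

    # -- triplet text I/O --------------------------------------------------

    def bin_table(self) -> pd.DataFrame:
        rows = []
        idx = 0
        for c in self.chroms:
            n = self.n_bins(c)
            L = self.layout.length(c)
            for b in range(n):
                rows.append(
                    (c, b * self.resolution, min((b + 1) * self.resolution, L), idx)
                )
                idx += 1
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "bin_id"])

    def _offsets(self) -> Dict[str, int]:
        off, acc = {}, 0
        for c in self.chroms:
            off[c] = acc
            acc += self.n_bins(c)
        return off

    def write_triplet(self, matrix_path: str, bins_path: str) -> None:
        """Upper-triangle triplet text (bin_i, bin_j, count) + companion bin BED."""
        off = self._offsets()
        self.bin_table().to_csv(bins_path, sep="\t", header=False, index=False)
        with open(matrix_path, "w") as fh:
            for c in self.chroms:
                coo = sp.triu(self.cis[c]).tocoo()
                order = np.lexsort((coo.col, coo.row))
                for i, j, v in zip(coo.row[order], coo.col[order], coo.data[order]):
                    fh.write(f"{off[c] + i}\t{off[c] + j}\t{v:g}\n")
            for (c1, c2), block in self.trans.items():
                coo = block.tocoo()
                order = np.lexsort((coo.col, coo.row))
                for i, j, v in zip(coo.row[order], coo.col[order], coo.data[order]):
                    fh.write(f"{off[c1] + i}\t{off[c2] + j}\t{v:g}\n")

    @classmethod
    def read_triplet(
        cls, matrix_path: str, bins_path: str, layout: GenomeLayout, resolution: int
    ) -> "ContactMatrix":
        bins = pd.read_csv(
            bins_path, sep="\t", names=["chrom", "start", "end", "bin_id"],
            dtype={"chrom": str},
        )
        trip = pd.read_csv(matrix_path, sep="\t", names=["i", "j", "count"])
        chrom_of = bins["chrom"].to_numpy()
        obj = cls.empty(layout, resolution)
        off = obj._offsets()
        ci = chrom_of[trip["i"].to_numpy()]
        cj = chrom_of[trip["j"].to_numpy()]
        cis_sel = ci == cj
        for c in layout.chroms:
            sel = cis_sel & (ci == c)
            n = obj.n_bins(c)
            i = trip["i"].to_numpy()[sel] - off[c]
            j = trip["j"].to_numpy()[sel] - off[c]
            v = trip["count"].to_numpy()[sel].astype(float)
            upper = sp.coo_matrix((v, (i, j)), shape=(n, n)).tocsr()
            obj.cis[c] = _symmetrize(upper)
        for (a, b) in [(a, b) for ai, a in enumerate(layout.chroms)
                       for b in layout.chroms[ai + 1:]]:
            sel = (~cis_sel) & (ci == a) & (cj == b)
            if not sel.any():
                continue
            i = trip["i"].to_numpy()[sel] - off[a]
            j = trip["j"].to_numpy()[sel] - off[b]
            v = trip["count"].to_numpy()[sel].astype(float)
            obj.trans[(a, b)] = sp.coo_matrix(
                (v, (i, j)), shape=(obj.n_bins(a), obj.n_bins(b))
            ).tocsr()
        return obj

    @classmethod
    def empty(cls, layout: GenomeLayout, resolution: int) -> "ContactMatrix":
        cis = {
            c: sp.csr_matrix((layout.n_bins(c, resolution),) * 2)
            for c in layout.chroms
        }
        return cls(layout, resolution, cis)


def _symmetrize(upper: sp.spmatrix) -> sp.csr_matrix:
    m = upper + upper.T
    m = m - sp.diags(upper.diagonal())
    return m.tocsr()


def bin_valid_pairs(
    pairs: pd.DataFrame, layout: GenomeLayout, resolution: int
) -> ContactMatrix:
    """Bin valid pairs into a contact matrix.

    Each pair increments exactly one (i, j) cell with i <= j (cis) or one
    trans block cell. Pairs on chromosomes absent from the layout are
    skipped with a logged count; positions beyond the chromosome length
    raise.
    """
    known = set(layout.chroms)
    ok = pairs["chrom1"].isin(known) & pairs["chrom2"].isin(known)
    n_skip = int((~ok).sum())
    if n_skip:
        logger.warning("skipped %d pairs on chromosomes outside the layout", n_skip)
    df = pairs.loc[ok]
    for col_c, col_p in (("chrom1", "pos1"), ("chrom2", "pos2")):
        lens = df[col_c].map(layout.to_dict()).to_numpy()
        pos = df[col_p].to_numpy()
        if (pos < 0).any() or (pos >= lens).any():
            bad = int(np.argmax((pos < 0) | (pos >= lens)))
            raise ValueError(
                f"pair position outside chromosome bounds at row {df.index[bad]}"
            )
    order = {c: k for k, c in enumerate(layout.chroms)}
    c1 = df["chrom1"].to_numpy()
    c2 = df["chrom2"].to_numpy()
    b1 = (df["pos1"].to_numpy() // resolution).astype(np.int64)
    b2 = (df["pos2"].to_numpy() // resolution).astype(np.int64)
    # canonical orientation: chrom order, then bin order within a chromosome
    k1 = np.vectorize(order.get)(c1) if len(c1) else np.array([], dtype=int)
    k2 = np.vectorize(order.get)(c2) if len(c2) else np.array([], dtype=int)
    flip = (k1 > k2) | ((k1 == k2) & (b1 > b2))
    c1f = np.where(flip, c2, c1)
    c2f = np.where(flip, c1, c2)
    b1f = np.where(flip, b2, b1)
    b2f = np.where(flip, b1, b2)

    obj = ContactMatrix.empty(layout, resolution)
    cis_sel = c1f == c2f
    for c in layout.chroms:
        sel = cis_sel & (c1f == c)
        n = obj.n_bins(c)
        upper = sp.coo_matrix(
            (np.ones(int(sel.sum())), (b1f[sel], b2f[sel])), shape=(n, n)
        ).tocsr()
        obj.cis[c] = _symmetrize(upper)
    for ai, a in enumerate(layout.chroms):
        for b in layout.chroms[ai + 1:]:
            sel = (c1f == a) & (c2f == b)
            if not sel.any():
                continue
            obj.trans[(a, b)] = sp.coo_matrix(
                (np.ones(int(sel.sum())), (b1f[sel], b2f[sel])),
                shape=(obj.n_bins(a), obj.n_bins(b)),
            ).tocsr()
    return obj


def ice_normalize(
    m: ContactMatrix,
    max_iter: int = 200,
    tol: float = 1e-4,
    low_coverage_fraction: float = 0.02,
) -> ContactMatrix:
    """Iterative correction: find per-bin weights equalizing cis row sums.

    The lowest `low_coverage_fraction` of non-zero-coverage bins (and all
    zero-coverage bins) are masked per chromosome. Returns a new matrix
    sharing the raw counts, with `weights` set; `converged` records whether
    every chromosome reached `tol` (max relative row-sum deviation).
    """
    weights: Dict[str, np.ndarray] = {}
    all_converged = True
    any_bins = False
    for chrom in m.chroms:
        R = m.cis[chrom].astype(float)
        n = R.shape[0]
        cov = np.asarray(R.sum(axis=1)).ravel()
        masked = cov <= 0
        nz = np.flatnonzero(~masked)
        k = int(np.floor(low_coverage_fraction * len(nz)))
        if k > 0:
            cutoff_idx = nz[np.argsort(cov[nz], kind="stable")[:k]]
            masked[cutoff_idx] = True
        w = np.ones(n)
        w[masked] = np.nan
        if masked.all():
            weights[chrom] = w
            continue
        any_bins = True
        b = np.ones(n)
        b[masked] = 0.0
        converged = False
        for _ in range(max_iter):
            s = b * (R @ b)
            live = s[~masked]
            mean_s = live.mean()
            if mean_s <= 0:
                break
            rel = np.abs(live / mean_s - 1.0).max()
            if rel < tol:
                converged = True
                break
            adj = np.ones(n)
            adj[~masked] = s[~masked] / mean_s
            b /= np.sqrt(adj)
        if not converged:
            all_converged = False
            warnings.warn(
                f"ICE did not converge on {chrom} within {max_iter} iterations; "
                "weights are partial",
                RuntimeWarning,
            )
        w[~masked] = b[~masked]
        weights[chrom] = w
    if not any_bins:
        raise ValueError("no non-masked bins on any chromosome; cannot balance")
    out = ContactMatrix(m.layout, m.resolution, m.cis, m.trans, weights)
    out.converged = all_converged
    return out


def matrix_correlation(
    a: ContactMatrix, b: ContactMatrix, log: bool = False
) -> float:
    """Pearson r of balanced values over the union of non-masked cis cells.

    Cells masked in either matrix are excluded; the union of cells with a
    non-zero raw count in either matrix is compared. With `log`, values are
    log10(1 + x)-transformed first.
    """
    if a.resolution != b.resolution or a.layout != b.layout:
        raise ValueError("matrices must share layout and resolution")
    xs, ys = [], []
    for chrom in a.chroms:
        A = a.balanced(chrom)
        B = b.balanced(chrom)
        valid = np.isfinite(A) & np.isfinite(B)
        nonzero = (a.dense(chrom) > 0) | (b.dense(chrom) > 0)
        iu = np.triu_indices(A.shape[0])
        sel = valid[iu] & nonzero[iu]
        xs.append(A[iu][sel])
        ys.append(B[iu][sel])
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    if log:
        x = np.log10(1 + x)
        y = np.log10(1 + y)
    return float(np.corrcoef(x, y)[0, 1])


@dataclass
class DecayCurve:
    """Cis contact probability P(s) on log-spaced distance bins."""

    distances: np.ndarray  # geometric bin centers, bp
    prob: np.ndarray  # mean contact probability per distance bin
    slope: float  # OLS log-log slope within fit_range
    fit_range: Tuple[int, int]


def contact_decay(
    m: ContactMatrix,
    fit_range: Tuple[int, int] = (80_000, 8_000_000),
    n_log_bins: int = 50,
) -> DecayCurve:
    """Contact probability vs genomic distance from raw cis counts.

    P at distance d = (counts at d summed over chromosomes) / (number of
    bin pairs at d) / (total cis pairs); the slope is fitted by ordinary
    least squares on (log10 s, log10 P) within `fit_range`.
    """
    lo, hi = fit_range
    if lo >= hi:
        raise ValueError("empty fit_range")
    res = m.resolution
    max_bins = max(m.n_bins(c) for c in m.chroms)
    counts = np.zeros(max_bins)
    npairs = np.zeros(max_bins)
    for chrom in m.chroms:
        n = m.n_bins(chrom)
        coo = sp.triu(m.cis[chrom], k=0).tocoo()
        d = coo.col - coo.row
        np.add.at(counts, d, coo.data)
        npairs[:n] += n - np.arange(n)
    total = counts.sum()
    if total <= 0:
        raise ValueError("matrix has no cis counts")
    with np.errstate(divide="ignore", invalid="ignore"):
        p_per_d = counts / npairs / total
    dist_bp = (np.arange(max_bins) + 0.5) * res  # mid-distance of each separation

    edges = np.geomspace(res / 2, max_bins * res, n_log_bins + 1)
    which = np.digitize(dist_bp, edges) - 1
    centers, probs = [], []
    for k in range(n_log_bins):
        sel = (which == k) & (npairs > 0)
        if not sel.any():
            continue
        centers.append(np.exp(np.mean(np.log(dist_bp[sel]))))
        probs.append(np.nanmean(p_per_d[sel]))
    centers = np.array(centers)
    probs = np.array(probs)

    fit_sel = (centers >= lo) & (centers <= hi) & (probs > 0)
    if fit_sel.sum() < 2:
        raise ValueError("fit_range contains fewer than two usable distance bins")
    slope = float(
        np.polyfit(np.log10(centers[fit_sel]), np.log10(probs[fit_sel]), 1)[0]
    )
    return DecayCurve(centers, probs, slope, fit_range)


def resolution_capability(
    m: ContactMatrix,
    candidate_resolutions: Sequence[int],
    min_pairs: int = 1000,
    fraction: float = 0.8,
) -> Optional[int]:
    """Smallest candidate resolution where >= `fraction` of bins hold
    >= `min_pairs` total (cis+trans) raw pairs.

    The matrix must be at a resolution dividing every candidate; per-bin
    counts at coarser resolutions are obtained by exact aggregation.
    """
    if not candidate_resolutions:
        raise ValueError("empty candidate resolution list")
    for r in candidate_resolutions:
        if r % m.resolution:
            raise ValueError(
                f"candidate {r} is not a multiple of matrix resolution {m.resolution}"
            )
    qualifying = []
    for r in sorted(candidate_resolutions, reverse=True):
        fracs = []
        for chrom in m.chroms:
            cov = m.coverage(chrom)
            if cov.sum() == 0:
                continue  # empty chromosome: excluded from the census
            factor = r // m.resolution
            n_coarse = m.layout.n_bins(chrom, r)
            agg = np.zeros(n_coarse)
            np.add.at(agg, np.arange(len(cov)) // factor, cov)
            fracs.append(agg >= min_pairs)
        if not fracs:
            return None
        ok = np.concatenate(fracs)
        if ok.mean() >= fraction:
            qualifying.append(r)
        else:
            break  # finer resolutions only get sparser
    return min(qualifying) if qualifying else None


def trans_contact_summary(
    a: ContactMatrix, b: Optional[ContactMatrix] = None
) -> pd.DataFrame:
    """Observed/expected inter-chromosomal contact table.

    expected(c1,c2) is proportional to nbins(c1)*nbins(c2), scaled so the
    expected totals match the observed trans total. With `b`, a
    ``difference`` column (a - b) is added.
    """
    if b is not None and (a.layout != b.layout or a.resolution != b.resolution):
        raise ValueError("matrices must share layout and resolution")

    def normalized(m: ContactMatrix) -> Dict[Tuple[str, str], float]:
        chroms = m.chroms
        pairs = [(c1, c2) for i, c1 in enumerate(chroms) for c2 in chroms[i + 1:]]
        sizes = {p: m.n_bins(p[0]) * m.n_bins(p[1]) for p in pairs}
        total = m.total_trans()
        denom = sum(sizes.values())
        out = {}
        for p in pairs:
            obs = float(m.trans[p].sum()) if p in m.trans else 0.0
            exp = sizes[p] * total / denom if denom else np.nan
            out[p] = obs / exp if exp else np.nan
        return out

    na = normalized(a)
    rows = []
    nb = normalized(b) if b is not None else None
    for (c1, c2), v in na.items():
        row = {"chrom1": c1, "chrom2": c2, "normalized": v}
        if nb is not None:
            row["normalized_b"] = nb[(c1, c2)]
            row["difference"] = v - nb[(c1, c2)]
        rows.append(row)
    return pd.DataFrame(rows)


def expected_by_distance(balanced: np.ndarray) -> np.ndarray:
    """Mean balanced value at each bin separation, NaN-aware."""
    n = balanced.shape[0]
    exp = np.full(n, np.nan)
    for d in range(n):
        diag = np.diagonal(balanced, offset=d)
        if np.isfinite(diag).any():
            exp[d] = np.nanmean(diag)
    return exp


def oe_matrix(m: ContactMatrix, chrom: str) -> np.ndarray:
    """Observed/expected balanced matrix for one chromosome (NaN at masked)."""
    bal = m.balanced(chrom)
    exp = expected_by_distance(bal)
    n = bal.shape[0]
    idx = np.abs(np.arange(n)[:, None] - np.arange(n)[None, :])
    e = exp[idx]
    with np.errstate(divide="ignore", invalid="ignore"):
        oe = bal / e
    return oe
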