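"""Directionality-index TAD calling and cross-stage TAD comparison.

The directionality index (DI) measures, per bin, the imbalance between
contacts reaching upstream (A) and downstream (B) within a fixed window
(default 2 Mb at 40 kb bins):

    E = (A + B) / 2
    DI = sign(B - A) * [ (A - E)^2 / E + (B - E)^2 / E ]

The upstream portion of a domain is biased toward downstream contacts
(DI > 0) and the downstream portion toward upstream contacts (DI < 0), so
a domain runs from the first DownstreamBias bin to the end of the
following UpstreamBias run, with states decoded by a 3-state Gaussian HMM.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from .genome import GenomeLayout, GenomicInterval
from .hic import ContactMatrix

__all__ = [
    "DiTrack",
    "TadSet",
    "SpTadMapping",
    "compute_di",
    "call_tads",
    "compare_boundaries",
    "detect_split_tads",
]

STATE_NAMES = ("UpstreamBias", "NoBias", "DownstreamBias")
BOUNDARY_MAX = 400_000  # inter-TAD gaps below this are boundaries


@dataclass
class DiTrack:
    """Per-bin DI values, and HMM states once decoded."""

    layout: GenomeLayout
    resolution: int
    window: int
    A: Dict[str, np.ndarray]
    B: Dict[str, np.ndarray]
    di: Dict[str, np.ndarray]
    states: Dict[str, np.ndarray] = field(default_factory=dict)  # -1/0/+1
    posterior: Dict[str, np.ndarray] = field(default_factory=dict)

    def values(self) -> np.ndarray:
        return np.concatenate([self.di[c] for c in self.layout.chroms])


@dataclass
class TadSet:
    """Called TADs with boundaries (< 400 kb gaps) and unorganized gaps."""

    resolution: int
    tads: List[GenomicInterval]
    boundaries: List[GenomicInterval]
    unorganized: List[GenomicInterval]

    def __post_init__(self) -> None:
        self.tads = sorted(self.tads, key=lambda t: (t.chrom, t.start))
        for a, b in zip(self.tads, self.tads[1:]):
            if a.chrom == b.chrom and a.end > b.start:
                raise ValueError(f"overlapping TADs {a} / {b}")
        for bd in self.boundaries:
            if len(bd) >= BOUNDARY_MAX:
                raise ValueError("boundary length must be < 400 kb")


@dataclass
class SpTadMapping:
    """One ucTAD covered by >= 2 spTADs from the other condition."""

    ucTAD: GenomicInterval
    uc_condition: str
    spTADs: List[GenomicInterval]
    sp_condition: str
    coverage: float  # fraction of ucTAD covered by the spTADs


def compute_di(
    m: ContactMatrix, window: int = 2_000_000, use_balanced: bool = True
) -> DiTrack:
    """Directionality index per bin from balanced (default) or raw counts.

    Bins within `window` of a chromosome end use the truncated window.
    DI = 0 when A = B or A + B = 0; masked bins contribute zero contacts.
    """
    res = m.resolution
    W = window // res
    if W < 1:
        raise ValueError("window smaller than one bin at this resolution")
    A: Dict[str, np.ndarray] = {}
    B: Dict[str, np.ndarray] = {}
    DI: Dict[str, np.ndarray] = {}
    for chrom in m.chroms:
        if use_balanced:
            mat = np.nan_to_num(m.balanced(chrom), nan=0.0)
        else:
            mat = m.dense(chrom)
        n = mat.shape[0]
        # prefix sums along each row: S[i, j] = sum of mat[i, :j]
        S = np.concatenate([np.zeros((n, 1)), np.cumsum(mat, axis=1)], axis=1)
        idx = np.arange(n)
        lo = np.maximum(idx - W, 0)
        hi = np.minimum(idx + W, n - 1)
        a = S[idx, idx] - S[idx, lo]          # contacts to [i-W, i-1]
        b = S[idx, hi + 1] - S[idx, idx + 1]  # contacts to [i+1, i+W]
        e = (a + b) / 2.0
        with np.errstate(divide="ignore", invalid="ignore"):
            stat = (a - e) ** 2 / e + (b - e) ** 2 / e
        di = np.sign(b - a) * stat
        di[(a == b) | (a + b == 0)] = 0.0
        A[chrom], B[chrom], DI[chrom] = a, b, di
    return DiTrack(m.layout, res, window, A, B, DI)


def _tercile_states(di: DiTrack) -> None:
    """Fallback state assignment by DI terciles (posterior fixed at 1)."""
    allv = di.values()
    lo, hi = np.quantile(allv, [1 / 3, 2 / 3])
    for chrom in di.layout.chroms:
        v = di.di[chrom]
        st = np.zeros(len(v), dtype=int)
        st[v <= lo] = -1
        st[v >= hi] = +1
        di.states[chrom] = st
        di.posterior[chrom] = np.ones(len(v))


def decode_states(di: DiTrack, max_iter: int = 100, random_state: int = 0) -> None:
    """Decode Upstream/No/Downstream bias states with a 3-state Gaussian HMM.

    The DI is variance-stabilized (signed log) and standardized; emission
    means and variances are anchored at (-1.5, 0, +1.5) and (1, 0.3, 1) on
    that scale, and EM fits the transition structure. Anchoring the
    emissions keeps the middle state from collapsing on clean data and
    makes the state <-> bias mapping unambiguous (DI > 0 = downstream
    bias). On EM failure the tercile fallback is used with a warning.
    """
    from hmmlearn.hmm import GaussianHMM

    allv = np.sign(di.values()) * np.log1p(np.abs(di.values()))
    sd = allv.std()
    if sd == 0:
        _tercile_states(di)
        return
    z = {
        c: (np.sign(di.di[c]) * np.log1p(np.abs(di.di[c])) - allv.mean()) / sd
        for c in di.layout.chroms
    }
    zall = np.concatenate([z[c] for c in di.layout.chroms])[:, None]
    lengths = [len(z[c]) for c in di.layout.chroms]
    model = GaussianHMM(
        n_components=3, covariance_type="diag", n_iter=max_iter,
        random_state=random_state, init_params="", params="st",
    )
    model.startprob_ = np.full(3, 1 / 3)
    model.transmat_ = np.array(
        [[0.8, 0.15, 0.05], [0.1, 0.8, 0.1], [0.05, 0.15, 0.8]]
    )
    model.means_ = np.array([-2.0, 0.0, 2.0])[:, None]
    model.covars_ = np.array([0.5, 0.1, 0.5])[:, None]
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model.fit(zall, lengths)
        order = np.argsort(model.means_.ravel())  # most negative first
        rank = {int(s): k - 1 for k, s in enumerate(order)}  # -> -1, 0, +1
        post = model.predict_proba(zall, lengths)
        hard = np.argmax(post, axis=1)
        states = np.array([rank[int(s)] for s in hard])
        gamma = post[np.arange(len(hard)), hard]
    except Exception as exc:  # pragma: no cover - EM failure path
        warnings.warn(f"HMM fit failed ({exc}); falling back to tercile states",
                      RuntimeWarning)
        _tercile_states(di)
        return
    off = 0
    for chrom, ln in zip(di.layout.chroms, lengths):
        di.states[chrom] = states[off:off + ln]
        di.posterior[chrom] = gamma[off:off + ln]
        off += ln


def _runs(states: np.ndarray) -> List[Tuple[int, int, int]]:
    """(start, end_exclusive, state) runs of a state sequence."""
    out = []
    start = 0
    for i in range(1, len(states) + 1):
        if i == len(states) or states[i] != states[start]:
            out.append((start, i, int(states[start])))
            start = i
    return out


def call_tads(
    di: DiTrack,
    median_posterior_threshold: float = 0.99,
    min_run: int = 2,
    boundary_max: int = BOUNDARY_MAX,
    hmm_max_iter: int = 100,
) -> TadSet:
    """Call TADs from decoded DI states.

    A candidate domain runs from the first DownstreamBias bin of a biased
    run to the end of the following UpstreamBias run. Domains whose median
    state posterior falls below `median_posterior_threshold`, or whose
    initiating/terminating biased runs are shorter than `min_run` bins,
    are discarded. Gaps between retained TADs shorter than `boundary_max`
    become boundaries; longer gaps are unorganized chromatin.
    """
    if not di.states:
        decode_states(di, max_iter=hmm_max_iter)
    res = di.resolution
    tads: List[GenomicInterval] = []
    for chrom in di.layout.chroms:
        st = di.states[chrom]
        post = di.posterior[chrom]
        runs = _runs(st)
        k = 0
        while k < len(runs):
            s0, e0, lab = runs[k]
            if lab != +1:
                k += 1
                continue
            # find the next UpstreamBias run
            k2 = k + 1
            while k2 < len(runs) and runs[k2][2] != -1:
                # a new DownstreamBias run before any upstream run restarts
                # the candidate at the later, stronger start
                k2 += 1
            if k2 == len(runs):
                break
            s1, e1, _ = runs[k2]
            d_len = e0 - s0
            u_len = e1 - s1
            # median probability is assessed over the biased runs that
            # delimit the domain; interior NoBias bins are legitimately soft
            dom_post = np.concatenate([post[s0:e0], post[s1:e1]])
            if (
                d_len >= min_run
                and u_len >= min_run
                and np.median(dom_post) >= median_posterior_threshold
            ):
                tads.append(GenomicInterval(chrom, s0 * res, e1 * res))
            k = k2 + 1
    boundaries: List[GenomicInterval] = []
    unorganized: List[GenomicInterval] = []
    for a, b in zip(tads, tads[1:]):
        if a.chrom != b.chrom or a.end >= b.start:
            continue
        gap = GenomicInterval(a.chrom, a.end, b.start)
        (boundaries if len(gap) < boundary_max else unorganized).append(gap)
    return TadSet(res, tads, boundaries, unorganized)


def compare_boundaries(
    x: TadSet, y: TadSet, tolerance_bins: int = 1
) -> Tuple[List[GenomicInterval], List[GenomicInterval]]:
    """Stage-specific boundaries: present in one set, absent (beyond
    +/- tolerance_bins * resolution, midpoint-to-midpoint) in the other."""
    if x.resolution != y.resolution:
        raise ValueError("TadSets must share resolution")
    tol = tolerance_bins * x.resolution

    def specific(a: TadSet, b: TadSet) -> List[GenomicInterval]:
        out = []
        for bd in a.boundaries:
            matched = any(
                ob.chrom == bd.chrom and abs(ob.midpoint - bd.midpoint) <= tol
                for ob in b.boundaries
            )
            if not matched:
                out.append(bd)
        return out

    return specific(x, y), specific(y, x)


def detect_split_tads(
    x: TadSet,
    y: TadSet,
    containment: float = 0.8,
    coverage: float = 0.8,
    x_condition: str = "x",
    y_condition: str = "y",
) -> List[SpTadMapping]:
    """Find TADs of one condition split into >= 2 TADs in the other.

    A TAD u is a ucTAD when >= 2 TADs of the other condition each lie
    >= `containment` of their own length inside u and together cover
    >= `coverage` of u; those TADs are its spTADs. Both directions are
    scanned.
    """

    def scan(uc: TadSet, sp: TadSet, uc_cond: str, sp_cond: str) -> List[SpTadMapping]:
        out = []
        for u in uc.tads:
            members = [
                t for t in sp.tads
                if len(t) > 0 and u.overlap_len(t) >= containment * len(t)
            ]
            if len(members) < 2:
                continue
            cov = sum(u.overlap_len(t) for t in members) / len(u)
            if cov >= coverage:
                out.append(SpTadMapping(u, uc_cond, members, sp_cond, float(cov)))
        return out

    return scan(x, y, x_condition, y_condition) + scan(y, x, y_condition, x_condition)
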