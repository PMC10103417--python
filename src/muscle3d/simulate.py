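"""Synthetic multi-omic data with planted ground truth.

Every generator is a pure function of (config, seed): Hi-C valid pairs with
power-law distance decay modulated by a planted compartment checkerboard,
within-TAD enrichment and point loops; replicate ATAC peaks with
signal-over-background structure; expression coupled to compartment state
and looped-enhancer count; and two-population diploid genotypes with
planted high-differentiation windows.

The planted structures are what the downstream callers must recover, so
their coordinates are emitted in a :class:`SimTruth` alongside the data.
"""

from __future__ import annotations

import json
import warnings
import zlib
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .genome import Gene, GenomeLayout, GenomicInterval
from .hic import ContactMatrix, _symmetrize
import scipy.sparse as sp

__all__ = [
    "SimConfig",
    "SimTruth",
    "CoverageTrack",
    "seed_for",
    "default_layout",
    "simulate_hic",
    "expected_matrix",
    "make_genes",
    "simulate_atac",
    "simulate_atac_reads",
    "simulate_expression",
    "simulate_genotypes",
]

CONDITIONS = ("fetal", "adult")


def seed_for(base_seed: int, name: str) -> int:
    """Stable per-generator seed derived from the config seed (< 2^31)."""
    return (int(base_seed) * 1_000_003 + zlib.crc32(name.encode())) % (2**31 - 1)


def default_layout() -> GenomeLayout:
    # Toy genome: large enough for 1 Mb compartment bins and 2 Mb DI windows,
    # small enough that paper-like sequencing depth per bp stays desk-scale.
    return GenomeLayout({"chr1": 20_000_000, "chr2": 20_000_000})


@dataclass
class SimConfig:
    """Study conditions for the synthetic benchmark.

    Depth and structure strengths are scaled-down analogues of a deeply
    sequenced tissue Hi-C / ATAC / RNA / resequencing design: a two-stage
    (fetal vs adult) comparison on a 2 x 40 Mb toy genome.
    """

    layout: GenomeLayout = field(default_factory=default_layout)
    # Hi-C
    fine_resolution: int = 10_000
    di_resolution: int = 40_000
    compartment_resolution: int = 1_000_000
    n_pairs: int = 8_000_000
    trans_fraction: float = 0.2
    decay_exponent: float = -1.0
    compartment_block_scale: float = 1.6
    compartment_flip_fraction: float = 0.25
    tad_count: int = 24
    tad_split_fraction: float = 0.2
    tad_fold: float = 3.0
    loop_count: int = 50
    loop_fold: float = 8.0
    loop_specific_fraction: float = 0.3
    loop_pp_fraction: float = 0.2  # promoter-promoter loops (co-anchored genes)
    # ATAC
    atac_replicates: int = 2
    promoter_peak_fraction: float = 0.3
    atac_signal_to_noise: float = 8.0
    atac_peak_width: int = 400
    n_background_peaks: int = 150
    atac_dar_fraction: float = 0.2
    atac_dar_fold: float = 4.0
    atac_mean_count: float = 50.0
    atac_dispersion: float = 0.1
    # expression
    n_genes: int = 400
    expr_alpha: float = 1.0  # log2 FPKM shift for compartment A
    expr_beta: float = 0.5  # log2 FPKM increment per looped enhancer
    expr_base_log2: float = 4.0
    expr_dispersion: float = 0.08
    expr_replicates: int = 3
    expr_gene_sd: float = 0.6
    # genotypes
    pop_sizes: Tuple[int, int] = (60, 26)
    n_variants: int = 20_000
    background_fst: float = 0.0
    sweep_window_count: int = 5
    sweep_window_size: int = 50_000
    sweep_fst: float = 0.8
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_pairs", "tad_count", "loop_count", "n_genes", "n_variants"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in (
            "trans_fraction", "compartment_flip_fraction", "tad_split_fraction",
            "loop_specific_fraction", "promoter_peak_fraction", "atac_dar_fraction",
        ):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")


@dataclass
class SimTruth:
    """Planted ground truth consumed by the benchmark suite."""

    # per-condition per-1Mb-bin A/B labels
    compartments: pd.DataFrame = field(default_factory=pd.DataFrame)
    # per-condition planted TADs
    tads: Dict[str, List[GenomicInterval]] = field(default_factory=dict)
    # split relations: ucTAD in one condition <-> >= 2 spTADs in the other
    splits: List[dict] = field(default_factory=list)
    # per-condition planted loops
    loops: Dict[str, pd.DataFrame] = field(default_factory=dict)
    # planted enhancer-side anchor intervals (fine-resolution bins)
    enhancer_anchors: List[GenomicInterval] = field(default_factory=list)
    # planted high-Fst windows
    sweep_windows: List[GenomicInterval] = field(default_factory=list)
    # per-gene planted couplings (compartment label, looped enhancer count)
    expression_links: pd.DataFrame = field(default_factory=pd.DataFrame)
    # planted ATAC peak catalog with class and DAR fold
    atac_peaks: pd.DataFrame = field(default_factory=pd.DataFrame)

    def to_json(self, path: str) -> None:
        def ivs(lst):
            return [[iv.chrom, iv.start, iv.end] for iv in lst]

        payload = {
            "compartments": self.compartments.to_dict(orient="list"),
            "tads": {c: ivs(t) for c, t in self.tads.items()},
            "splits": [
                {**s, "ucTAD": [s["ucTAD"].chrom, s["ucTAD"].start, s["ucTAD"].end],
                 "spTADs": ivs(s["spTADs"])}
                for s in self.splits
            ],
            "loops": {c: df.to_dict(orient="list") for c, df in self.loops.items()},
            "enhancer_anchors": ivs(self.enhancer_anchors),
            "sweep_windows": ivs(self.sweep_windows),
            "expression_links": self.expression_links.to_dict(orient="list"),
            "atac_peaks": self.atac_peaks.to_dict(orient="list"),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path: str) -> "SimTruth":
        with open(path) as fh:
            d = json.load(fh)

        def univs(lst):
            return [GenomicInterval(c, s, e) for c, s, e in lst]

        return cls(
            compartments=pd.DataFrame(d["compartments"]),
            tads={c: univs(t) for c, t in d["tads"].items()},
            splits=[
                {**s, "ucTAD": GenomicInterval(*s["ucTAD"]),
                 "spTADs": univs(s["spTADs"])}
                for s in d["splits"]
            ],
            loops={c: pd.DataFrame(v) for c, v in d["loops"].items()},
            enhancer_anchors=univs(d["enhancer_anchors"]),
            sweep_windows=univs(d["sweep_windows"]),
            expression_links=pd.DataFrame(d["expression_links"]),
            atac_peaks=pd.DataFrame(d["atac_peaks"]),
        )


# ---------------------------------------------------------------------------
# structure planting
# ---------------------------------------------------------------------------


def _plant_compartments(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Alternating A/B blocks of 2-5 Mb; the adult condition flips a
    fraction of blocks, creating both A->B and B->A transitions. Flips
    that would collapse a chromosome's mosaic (fewer than 4 runs or one
    label nearly absent) are skipped: an eigenvector can only resolve an
    alternating pattern."""
    res = config.compartment_resolution
    rows = []
    per_chrom = []  # (chrom, labels, adult, blocks, min_side)
    for ci, chrom in enumerate(config.layout.chroms):
        n = config.layout.n_bins(chrom, res)
        labels = np.empty(n, dtype="<U1")
        blocks = []
        pos, lab = 0, rng.choice(["A", "B"])
        while pos < n:
            size = int(rng.integers(2, 6))
            blocks.append((pos, min(pos + size, n)))
            labels[pos:min(pos + size, n)] = lab
            lab = "A" if lab == "B" else "B"
            pos += size
        adult = labels.copy()
        n_flip = int(round(config.compartment_flip_fraction * len(blocks)))
        # draw flips evenly from A and B blocks so both transition
        # directions (A->B and B->A) are planted
        a_blocks = [k for k, (s, e) in enumerate(blocks) if labels[s] == "A"]
        b_blocks = [k for k, (s, e) in enumerate(blocks) if labels[s] == "B"]
        pools = [a_blocks, b_blocks] if ci % 2 == 0 else [b_blocks, a_blocks]
        chosen = []
        for pool, k in ((pools[0], n_flip // 2 + n_flip % 2),
                        (pools[1], n_flip // 2)):
            k = min(k, len(pool))
            chosen.extend(rng.choice(pool, size=k, replace=False))
        min_side = max(3, int(0.15 * n))

        def mosaic_ok(arr):
            n_runs = 1 + int((arr[1:] != arr[:-1]).sum())
            return (min((arr == "A").sum(), (arr == "B").sum()) >= min_side
                    and n_runs >= 4)

        for bi in chosen:
            s, e = blocks[bi]
            flipped = adult.copy()
            flipped[s:e] = np.where(flipped[s:e] == "A", "B", "A")
            if mosaic_ok(flipped):
                adult = flipped
        per_chrom.append((chrom, labels, adult, blocks, mosaic_ok))
    # guarantee both transition directions exist genome-wide: if one is
    # missing, flip the first eligible block of the needed fetal label
    for needed in ("A", "B"):  # fetal label that must flip (A->B / B->A)
        present = any(
            ((labels[s] == needed) and (adult[s] != labels[s]))
            for _, labels, adult, blocks, _ in per_chrom
            for s, _e in blocks
        )
        if present:
            continue
        done = False
        for chrom, labels, adult, blocks, mosaic_ok in per_chrom:
            for s, e in blocks:
                if labels[s] != needed or adult[s] != labels[s]:
                    continue
                flipped = adult.copy()
                flipped[s:e] = np.where(flipped[s:e] == "A", "B", "A")
                if mosaic_ok(flipped):
                    adult[:] = flipped
                    done = True
                    break
            if done:
                break
    for chrom, labels, adult, _blocks, _ok in per_chrom:
        n = len(labels)
        L = config.layout.length(chrom)
        for b in range(n):
            rows.append(
                (chrom, b * res, min((b + 1) * res, L), labels[b], adult[b])
            )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "fetal", "adult"])


def _plant_tads(
    config: SimConfig, rng: np.random.Generator
) -> Tuple[Dict[str, List[GenomicInterval]], List[dict]]:
    res = config.di_resolution
    base: List[GenomicInterval] = []
    for chrom in config.layout.chroms:
        n = config.layout.n_bins(chrom, res)
        pos = int(rng.integers(2, 6))
        while len(base) < config.tad_count:
            size = int(rng.integers(20, 61))  # 0.8-2.4 Mb at 40 kb
            if pos + size > n - 2:
                break
            base.append(GenomicInterval(chrom, pos * res, (pos + size) * res))
            if rng.random() < 0.8:
                gap = int(rng.integers(2, 9))  # 80-320 kb -> boundary
            else:
                gap = int(rng.integers(13, 26))  # 520 kb - 1 Mb -> unorganized
            pos += size + gap
        if len(base) >= config.tad_count:
            break
    n_split = int(round(config.tad_split_fraction * len(base)))
    splittable = [i for i, t in enumerate(base) if len(t) >= 40 * res]
    split_idx = list(rng.choice(splittable, size=min(n_split, len(splittable)),
                                replace=False))
    tads = {c: [] for c in CONDITIONS}
    splits: List[dict] = []
    for i, t in enumerate(base):
        if i in split_idx:
            # ucTAD kept whole in one condition, split into 2 spTADs in the other
            nbins = len(t) // res
            cut = int(rng.integers(nbins // 3, 2 * nbins // 3))
            gap = 2  # 80 kb internal gap -> a boundary in the split condition
            left = GenomicInterval(t.chrom, t.start, t.start + cut * res)
            right = GenomicInterval(t.chrom, t.start + (cut + gap) * res, t.end)
            split_cond = CONDITIONS[int(rng.integers(2))]
            whole_cond = CONDITIONS[1 - CONDITIONS.index(split_cond)]
            tads[split_cond].extend([left, right])
            tads[whole_cond].append(t)
            splits.append(
                {"uc_condition": whole_cond, "sp_condition": split_cond,
                 "ucTAD": t, "spTADs": [left, right]}
            )
        else:
            for c in CONDITIONS:
                tads[c].append(t)
    for c in CONDITIONS:
        tads[c].sort(key=lambda iv: (iv.chrom, iv.start))
    return tads, splits


def _plant_loops(
    config: SimConfig,
    tads: Dict[str, List[GenomicInterval]],
    splits: List[dict],
    compartments: pd.DataFrame,
    rng: np.random.Generator,
) -> Tuple[Dict[str, pd.DataFrame], List[GenomicInterval]]:
    """Plant loops inside TADs.

    Enhancer-promoter loops are gene-centric: a promoter anchor wired to
    1-3 enhancer anchors within the same TAD, so looped-enhancer counts
    vary. A loop_pp_fraction of loops instead joins two gene promoters
    (co-anchored, hence co-varying, genes). A loop_specific_fraction of
    loops is planted in only one condition.
    """
    res = config.fine_resolution
    split_set = {(s["ucTAD"].chrom, s["ucTAD"].start) for s in splits}
    stable = [t for t in tads["fetal"]
              if (t.chrom, t.start) not in split_set and t in tads["adult"]]
    stable = [t for t in stable if len(t) >= 60 * res]
    # active loops concentrate in A compartments: weight TAD choice by the
    # fraction of its span labeled A in both stages
    weights = []
    for t in stable:
        sel = compartments[(compartments["chrom"] == t.chrom)
                           & (compartments["start"] < t.end)
                           & (compartments["end"] > t.start)]
        frac_a = float(((sel["fetal"] == "A").mean()
                        + (sel["adult"] == "A").mean()) / 2) if len(sel) else 0.5
        weights.append(0.1 + 0.9 * frac_a)
    weights = np.array(weights) / np.sum(weights)
    rows = []
    enhancer_anchors: List[GenomicInterval] = []
    n_specific = int(round(config.loop_specific_fraction * config.loop_count))
    condition_of = (["fetal"] * (n_specific // 2) + ["adult"] * (n_specific - n_specific // 2)
                    + ["both"] * (config.loop_count - n_specific))
    rng.shuffle(condition_of)
    n_pp = int(round(config.loop_pp_fraction * config.loop_count))
    k_cycle = [1, 2, 3]
    li = 0
    gi = 0
    while li < config.loop_count:
        tad = stable[int(rng.choice(len(stable), p=weights))]
        t0, t1 = tad.start // res, tad.end // res
        pp = li < n_pp
        k = 1 if pp else min(k_cycle[gi % len(k_cycle)], config.loop_count - li)
        gi += 1
        # promoter anchor in the upstream third of the TAD
        p_bin = int(rng.integers(t0 + 2, t0 + (t1 - t0) // 3))
        used = set()
        for _ in range(k):
            for _try in range(50):
                e_bin = int(rng.integers(p_bin + 20, t1 - 2))  # >= 200 kb away
                if e_bin not in used:
                    break
            used.add(e_bin)
            cond = condition_of[li]
            anc1 = (p_bin * res, (p_bin + 1) * res)
            anc2 = (e_bin * res, (e_bin + 1) * res)
            rows.append(
                {"chrom": tad.chrom, "start1": anc1[0], "end1": anc1[1],
                 "start2": anc2[0], "end2": anc2[1], "condition": cond,
                 "kind": "pp" if pp else "ep", "gene_slot": gi - 1,
                 "fold": config.loop_fold}
            )
            if not pp:
                enhancer_anchors.append(GenomicInterval(tad.chrom, anc2[0], anc2[1]))
            li += 1
            if li >= config.loop_count:
                break
    df = pd.DataFrame(rows)
    loops = {
        c: df[(df["condition"] == c) | (df["condition"] == "both")].reset_index(drop=True)
        for c in CONDITIONS
    }
    return loops, enhancer_anchors


def _plant_sweeps(config: SimConfig, rng: np.random.Generator) -> List[GenomicInterval]:
    out: List[GenomicInterval] = []
    size = config.sweep_window_size
    attempts = 0
    while len(out) < config.sweep_window_count and attempts < 1000:
        attempts += 1
        chrom = config.layout.chroms[int(rng.integers(len(config.layout.chroms)))]
        start = int(rng.integers(0, (config.layout.length(chrom) - size) // 10_000)) * 10_000
        iv = GenomicInterval(chrom, start, start + size)
        if all(not iv.overlaps(GenomicInterval(o.chrom, max(0, o.start - size),
                                               o.end + size))
               for o in out if o.chrom == iv.chrom):
            out.append(iv)
    out.sort(key=lambda iv: (iv.chrom, iv.start))
    return out


def plant_truth(config: SimConfig) -> SimTruth:
    """All planted structures, deterministic in config.rng_seed."""
    rng = np.random.default_rng(seed_for(config.rng_seed, "truth"))
    compartments = _plant_compartments(config, rng)
    tads, splits = _plant_tads(config, rng)
    loops, enhancer_anchors = _plant_loops(config, tads, splits,
                                           compartments, rng)
    sweeps = _plant_sweeps(config, rng)
    return SimTruth(
        compartments=compartments, tads=tads, splits=splits, loops=loops,
        enhancer_anchors=enhancer_anchors, sweep_windows=sweeps,
    )


# ---------------------------------------------------------------------------
# Hi-C
# ---------------------------------------------------------------------------


def _structure_weights(
    config: SimConfig, truth: SimTruth, condition: str, chrom: str, resolution: int
) -> np.ndarray:
    """Upper-triangular weight matrix over bins of one chromosome."""
    n = config.layout.n_bins(chrom, resolution)
    d = np.abs(np.arange(n)[:, None] - np.arange(n)[None, :])
    w = ((d + 1.0) * resolution) ** config.decay_exponent
    # compartment checkerboard: same-label bins up-weighted
    comp = truth.compartments[truth.compartments["chrom"] == chrom]
    labels = np.empty(n, dtype="<U1")
    labels[:] = "B"
    for row in comp.itertuples(index=False):
        lab = getattr(row, condition)
        b0 = row.start // resolution
        b1 = -(-row.end // resolution)
        labels[b0:min(b1, n)] = lab
    same = labels[:, None] == labels[None, :]
    w *= np.where(same, config.compartment_block_scale, 1.0)
    # within-TAD enrichment: uniform multiplier inside the triangle
    for t in truth.tads.get(condition, []):
        if t.chrom != chrom:
            continue
        b0, b1 = t.start // resolution, -(-t.end // resolution)
        w[b0:b1, b0:b1] *= config.tad_fold
    # loop point masses (1 bin at the finest resolution; mapped to coarser)
    loops = truth.loops.get(condition)
    if loops is not None and len(loops):
        sel = loops["chrom"] == chrom
        for row in loops[sel].itertuples(index=False):
            i = row.start1 // resolution
            j = row.start2 // resolution
            if i != j:
                w[i, j] *= row.fold
                w[j, i] *= row.fold
    # Equalize the visibility contributed by the planted structures (not the
    # decay itself, whose edge truncation is a real feature of chromosomes):
    # real loci show near-uniform visibility, which is also ICE's premise.
    decay = ((d + 1.0) * resolution) ** config.decay_exponent
    base = decay.sum(axis=1)
    for _ in range(20):
        r = w.sum(axis=1) / base
        r /= r.mean()
        np.sqrt(r, out=r)
        w /= r[:, None]
        w /= r[None, :]
    return w


def expected_matrix(
    config: SimConfig,
    condition: str,
    resolution: Optional[int] = None,
    truth: Optional[SimTruth] = None,
) -> ContactMatrix:
    """Noise-free expected contact matrix (float counts) at `resolution`.

    Weights are always built at the finest resolution (where loops are
    single pixels) and aggregated, so coarse matrices see the same
    structure the sampled pairs would. Total cis counts scale to
    n_pairs * (1 - trans_fraction); this is the Poisson mean surface that
    `simulate_hic` samples from, exposed directly for noise-free
    benchmarking.
    """
    truth = truth if truth is not None else plant_truth(config)
    resolution = resolution or config.fine_resolution
    if resolution % config.fine_resolution:
        raise ValueError("resolution must be a multiple of fine_resolution")
    factor = resolution // config.fine_resolution
    ws = {c: _structure_weights(config, truth, condition, c, config.fine_resolution)
          for c in config.layout.chroms}
    total_w = sum(w.sum() for w in ws.values())
    n_cis = config.n_pairs * (1 - config.trans_fraction)
    cis = {}
    for c, w in ws.items():
        lam = w * (n_cis / total_w)
        if factor > 1:
            edges = np.arange(0, lam.shape[0], factor)
            lam = np.add.reduceat(np.add.reduceat(lam, edges, axis=0), edges, axis=1)
        cis[c] = sp.csr_matrix(lam)
    m = ContactMatrix(config.layout, resolution, cis)
    return m


def sample_matrix(
    config: SimConfig,
    condition: str,
    resolution: Optional[int] = None,
    truth: Optional[SimTruth] = None,
    seed_name: str = "matrix",
) -> ContactMatrix:
    """Poisson-sampled contact matrix drawn directly from the expected
    surface (no pair-text expansion) — the fast path for benchmarking."""
    truth = truth if truth is not None else plant_truth(config)
    rng = np.random.default_rng(seed_for(config.rng_seed, f"{seed_name}:{condition}"))
    exp = expected_matrix(config, condition, resolution, truth)
    cis = {}
    for c in exp.chroms:
        lam = np.triu(exp.dense(c))
        counts = rng.poisson(lam).astype(float)
        cis[c] = _symmetrize(sp.csr_matrix(counts))
    return ContactMatrix(config.layout, exp.resolution, cis)


def simulate_hic(
    config: SimConfig, condition: str, truth: Optional[SimTruth] = None
) -> Tuple[pd.DataFrame, SimTruth]:
    """Sample valid pairs for one condition.

    Cis pairs are Poisson draws from the structured expected surface at the
    finest resolution, with uniform within-bin positions; trans pairs are
    uniform over chromosome pairs. Deterministic given config.rng_seed.
    """
    truth = truth if truth is not None else plant_truth(config)
    rng = np.random.default_rng(seed_for(config.rng_seed, f"hic:{condition}"))
    res = config.fine_resolution
    n_cis_target = config.n_pairs * (1 - config.trans_fraction)
    total_bins = sum(config.layout.n_bins(c, res) for c in config.layout.chroms)
    if n_cis_target < total_bins:
        warnings.warn(
            "n_pairs is small relative to the number of bins at the finest "
            "resolution; the matrix will be very sparse",
            RuntimeWarning,
        )
    ws = {c: np.triu(_structure_weights(config, truth, condition, c, res))
          for c in config.layout.chroms}
    total_w = sum(w.sum() for w in ws.values())

    recs = []
    for chrom, w in ws.items():
        lam = w * (n_cis_target / total_w)
        counts = rng.poisson(lam)
        i, j = np.nonzero(counts)
        reps = counts[i, j]
        bi = np.repeat(i, reps)
        bj = np.repeat(j, reps)
        L = config.layout.length(chrom)
        p1 = bi * res + rng.integers(0, res, size=len(bi))
        p2 = bj * res + rng.integers(0, res, size=len(bj))
        recs.append(pd.DataFrame({
            "chrom1": chrom, "pos1": np.minimum(p1, L - 1),
            "chrom2": chrom, "pos2": np.minimum(p2, L - 1),
        }))
    # trans: uniform over all chromosome pairs, proportional to bin products
    chroms = config.layout.chroms
    pairs = [(a, b) for k, a in enumerate(chroms) for b in chroms[k + 1:]]
    if pairs:
        n_trans = int(round(config.n_pairs * config.trans_fraction))
        sizes = np.array([config.layout.length(a) / 1e6 * config.layout.length(b) / 1e6
                          for a, b in pairs])
        alloc = rng.multinomial(n_trans, sizes / sizes.sum())
        for (a, b), cnt in zip(pairs, alloc):
            recs.append(pd.DataFrame({
                "chrom1": a, "pos1": rng.integers(0, config.layout.length(a), cnt),
                "chrom2": b, "pos2": rng.integers(0, config.layout.length(b), cnt),
            }))
    df = pd.concat(recs, ignore_index=True)
    df.insert(0, "read_id", [f"r{k:08d}" for k in range(len(df))])
    df["strand1"] = np.where(rng.random(len(df)) < 0.5, "+", "-")
    df["strand2"] = np.where(rng.random(len(df)) < 0.5, "+", "-")
    df = df[["read_id", "chrom1", "pos1", "strand1", "chrom2", "pos2", "strand2"]]
    return df, truth


# ---------------------------------------------------------------------------
# genes / expression
# ---------------------------------------------------------------------------


def make_genes(config: SimConfig, truth: SimTruth) -> List[Gene]:
    """Gene models tied to the planted loop structure.

    Promoter-anchor genes (planted category C) sit at the promoter anchors
    of enhancer-promoter loops; some genes are placed strictly inside loop
    spans (planted B); the rest are background (planted A). Planted
    couplings per gene and condition are recorded in
    truth.expression_links.
    """
    rng = np.random.default_rng(seed_for(config.rng_seed, "genes"))
    res = config.fine_resolution
    genes: List[Gene] = []
    links = []
    gene_len = 20_000

    def add_gene(gid, chrom, tss, planted):
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "+":
            iv = GenomicInterval(chrom, tss, tss + gene_len)
        else:
            iv = GenomicInterval(chrom, max(0, tss - gene_len + 1), tss + 1)
        genes.append(Gene(gid, iv, strand))
        comp = truth.compartments
        for cond in CONDITIONS:
            bins = comp[(comp["chrom"] == chrom) & (comp["start"] <= tss)
                        & (tss < comp["end"])]
            label = bins.iloc[0][cond] if len(bins) else "B"
            n_enh = planted["n_enh"].get(cond, 0)
            links.append({
                "gene_id": gid, "condition": cond, "comp_label": label,
                "n_enhancers": n_enh, "planted_category": planted["category"],
            })

    # C genes at promoter anchors of planted ep loops, grouped by gene_slot
    all_loops = pd.concat([truth.loops[c] for c in CONDITIONS]).drop_duplicates(
        subset=["chrom", "start1", "start2"]
    )
    gi = 0
    for slot, grp in all_loops.groupby("gene_slot"):
        chrom = grp.iloc[0]["chrom"]
        tss = int(grp.iloc[0]["start1"]) + res // 2
        ep = grp[grp["kind"] == "ep"]
        n_enh = {
            cond: int(((ep["condition"] == cond) | (ep["condition"] == "both")).sum())
            for cond in CONDITIONS
        }
        add_gene(f"geneC{gi:04d}", chrom, tss, {"n_enh": n_enh, "category": "C"})
        gi += 1
    # second promoter of each promoter-promoter loop gets its own gene
    for row in all_loops[all_loops["kind"] == "pp"].itertuples(index=False):
        add_gene(f"geneC{gi:04d}", row.chrom, int(row.start2) + res // 2,
                 {"n_enh": {c: 0 for c in CONDITIONS}, "category": "C"})
        gi += 1

    # B genes strictly inside loop spans
    n_b = max(10, config.n_genes // 8)
    spans = all_loops.sample(n=min(n_b, len(all_loops)), random_state=int(rng.integers(2**31)))
    for k, row in enumerate(spans.itertuples(index=False)):
        lo, hi = row.end1 + 5000, row.start2 - 5000
        if hi - lo < 12_000:
            continue
        tss = int(rng.integers(lo + 4000, hi - 4000))
        add_gene(f"geneB{k:04d}", row.chrom, tss,
                 {"n_enh": {c: 0 for c in CONDITIONS}, "category": "B"})

    # background genes away from all loops
    anchor_bins = set()
    for row in all_loops.itertuples(index=False):
        for s in (row.start1, row.start2):
            for off in (-res, 0, res):
                anchor_bins.add((row.chrom, s + off))
    span_list = [(row.chrom, row.start1, row.end2)
                 for row in all_loops.itertuples(index=False)]
    # background genes are biased toward A compartments (gene-dense open
    # chromatin), which is what lets an activity track orient PC1; bins A
    # in both stages are the densest
    comp_idx = truth.compartments.set_index(["chrom", "start"])
    cres = config.compartment_resolution
    k = 0
    while len(genes) < config.n_genes:
        chrom = config.layout.chroms[int(rng.integers(len(config.layout.chroms)))]
        tss = int(rng.integers(50_000, config.layout.length(chrom) - 50_000))
        in_span = any(c == chrom and s - 5000 <= tss < e + 5000
                      for c, s, e in span_list)
        if in_span:
            continue
        key = (chrom, tss // cres * cres)
        if key in comp_idx.index:
            row = comp_idx.loc[key]
            n_a = (row["fetal"] == "A") + (row["adult"] == "A")
        else:
            n_a = 0
        if rng.random() > (0.3 + 0.2 * n_a):
            continue
        add_gene(f"geneA{k:04d}", chrom, tss,
                 {"n_enh": {c: 0 for c in CONDITIONS}, "category": "A"})
        k += 1
    truth.expression_links = pd.DataFrame(links)
    return genes


def simulate_expression(
    config: SimConfig, truth: SimTruth, genes: List[Gene]
) -> pd.DataFrame:
    """Replicated NB counts and FPKM for two conditions.

    log2 mean FPKM = base + alpha*[compartment A] + beta*(looped enhancers)
    + gene effect; counts are negative-binomial around the FPKM-implied
    mean. Gene.expression is filled with per-condition mean FPKM.
    """
    rng = np.random.default_rng(seed_for(config.rng_seed, "expression"))
    links = truth.expression_links.set_index(["gene_id", "condition"])
    gene_eff = {g.gene_id: rng.normal(0, config.expr_gene_sd) for g in genes}
    rows = []
    for g in genes:
        row = {"gene_id": g.gene_id, "chrom": g.chrom,
               "start": g.interval.start, "end": g.interval.end, "strand": g.strand}
        for cond in CONDITIONS:
            lk = links.loc[(g.gene_id, cond)]
            log2_mu = (config.expr_base_log2
                       + config.expr_alpha * (lk["comp_label"] == "A")
                       + config.expr_beta * lk["n_enhancers"]
                       + gene_eff[g.gene_id])
            mu_fpkm = 2.0 ** log2_mu
            # counts at an arbitrary depth: mean count = FPKM * (len/1e3)
            mu_count = mu_fpkm * (len(g.interval) / 1e3)
            reps = []
            for r in range(config.expr_replicates):
                if config.expr_dispersion > 0:
                    shape = 1.0 / config.expr_dispersion
                    lam = rng.gamma(shape, mu_count / shape)
                else:
                    lam = mu_count
                cnt = int(rng.poisson(lam))
                row[f"count_{cond}_r{r + 1}"] = cnt
                reps.append(cnt)
            fpkm = float(np.mean(reps) / (len(g.interval) / 1e3))
            row[f"fpkm_{cond}"] = fpkm
            g.expression[cond] = fpkm
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# ATAC
# ---------------------------------------------------------------------------


@dataclass
class CoverageTrack:
    """Per-base read coverage: a flat baseline plus elevated intervals."""

    baseline: float
    intervals: pd.DataFrame  # chrom, start, end, value (per-base rate)

    def per_base(self, iv: GenomicInterval) -> float:
        """Mean per-base coverage over an interval."""
        sel = self.intervals[
            (self.intervals["chrom"] == iv.chrom)
            & (self.intervals["start"] < iv.end)
            & (self.intervals["end"] > iv.start)
        ]
        total = self.baseline * len(iv)
        for row in sel.itertuples(index=False):
            ov = min(row.end, iv.end) - max(row.start, iv.start)
            total += (row.value - self.baseline) * ov
        return total / len(iv)

    def write(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write(f"#baseline={self.baseline!r}\n")
            for row in self.intervals.itertuples(index=False):
                fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t{row.value!r}\n")

    @classmethod
    def read(cls, path: str) -> "CoverageTrack":
        baseline = 0.0
        rows = []
        with open(path) as fh:
            for line in fh:
                if line.startswith("#baseline="):
                    baseline = float(line.split("=", 1)[1])
                    continue
                c, s, e, v = line.rstrip("\n").split("\t")
                rows.append((c, int(s), int(e), float(v)))
        return cls(baseline, pd.DataFrame(rows, columns=["chrom", "start", "end", "value"]))


def simulate_atac(
    config: SimConfig, genes: Sequence[Gene], truth: Optional[SimTruth] = None
) -> Tuple[Dict[str, List[GenomicInterval]], Dict[str, CoverageTrack], pd.DataFrame, SimTruth]:
    """Replicate ATAC peak sets, per-sample coverage, and a count matrix.

    Peaks fall at TSSs (promoter class), inside planted enhancer anchors,
    and at random background positions, in proportions set by
    promoter_peak_fraction. Replicate peaks are jittered <= 20 bp. Counts
    are negative-binomial with planted fold changes defining DAR truth.
    """
    truth = truth if truth is not None else plant_truth(config)
    rng = np.random.default_rng(seed_for(config.rng_seed, "atac"))
    width = config.atac_peak_width
    catalog = []  # (chrom, start, end, class)
    enh_sites = [(iv.chrom, iv.midpoint) for iv in truth.enhancer_anchors]
    n_enh = len(enh_sites)
    n_bg = config.n_background_peaks
    # promoter peaks at gene TSSs so that the planted promoter fraction holds
    n_prom = int(round(config.promoter_peak_fraction / max(1e-9, 1 - config.promoter_peak_fraction)
                       * (n_enh + n_bg)))
    prom_genes = list(genes)[: n_prom]
    for g in prom_genes:
        catalog.append((g.chrom, max(0, g.tss - width // 2), g.tss + width // 2, "P"))
    for chrom, mid in enh_sites:
        catalog.append((chrom, max(0, mid - width // 2), mid + width // 2, "E"))
    spans = {(c, s, e) for c, s, e, _ in catalog}
    while sum(1 for c in catalog if c[3] == "O") < n_bg:
        chrom = config.layout.chroms[int(rng.integers(len(config.layout.chroms)))]
        start = int(rng.integers(1000, config.layout.length(chrom) - 1000))
        key = (chrom, start, start + width)
        if key not in spans:
            catalog.append((chrom, start, start + width, "O"))
            spans.add(key)
    cat = pd.DataFrame(catalog, columns=["chrom", "start", "end", "class"])
    cat = cat.sort_values(["chrom", "start"]).reset_index(drop=True)
    cat["peak_id"] = [f"peak{k:05d}" for k in range(len(cat))]
    # planted DARs: fold change between conditions
    is_dar = rng.random(len(cat)) < config.atac_dar_fraction
    fold = np.where(is_dar,
                    np.where(rng.random(len(cat)) < 0.5,
                             config.atac_dar_fold, 1 / config.atac_dar_fold),
                    1.0)
    cat["dar_fold_adult"] = fold
    truth.atac_peaks = cat

    peaks: Dict[str, List[GenomicInterval]] = {}
    coverage: Dict[str, CoverageTrack] = {}
    counts: Dict[str, np.ndarray] = {}
    base_mean = config.atac_mean_count
    for cond in CONDITIONS:
        cond_mean = base_mean * np.where(cond == "adult", cat["dar_fold_adult"], 1.0)
        for r in range(1, config.atac_replicates + 1):
            sample = f"{cond}_r{r}"
            jitter = rng.integers(-20, 21, size=(len(cat), 2))
            ivs = [
                GenomicInterval(row.chrom, max(0, row.start + int(j0)),
                                row.end + int(j1), name=row.peak_id)
                for row, (j0, j1) in zip(cat.itertuples(index=False), jitter)
            ]
            peaks[sample] = ivs
            shape = 1.0 / config.atac_dispersion
            lam = rng.gamma(shape, np.asarray(cond_mean, dtype=float) / shape)
            cnt = rng.poisson(lam)
            counts[sample] = cnt
            baseline = base_mean / width / config.atac_signal_to_noise
            cov = pd.DataFrame({
                "chrom": cat["chrom"], "start": cat["start"], "end": cat["end"],
                "value": cnt / width + baseline,
            })
            coverage[sample] = CoverageTrack(baseline, cov)
    count_df = pd.DataFrame(counts)
    count_df.insert(0, "peak_id", cat["peak_id"])
    count_df.insert(1, "chrom", cat["chrom"])
    count_df.insert(2, "start", cat["start"])
    count_df.insert(3, "end", cat["end"])
    return peaks, coverage, count_df, truth


def simulate_atac_reads(
    config: SimConfig,
    genes: Sequence[Gene],
    n_reads: int = 50_000,
    tss_fraction: float = 0.5,
    read_len: int = 50,
) -> pd.DataFrame:
    """Single-end-style read intervals enriched around TSSs (QC input)."""
    rng = np.random.default_rng(seed_for(config.rng_seed, "atac_reads"))
    n_tss = int(round(n_reads * tss_fraction))
    rows = {"chrom": [], "start": [], "strand": []}
    gene_list = list(genes)
    for _ in range(n_tss):
        g = gene_list[int(rng.integers(len(gene_list)))]
        offset = int(rng.normal(0, 150))
        pos = max(0, g.tss + offset)
        rows["chrom"].append(g.chrom)
        rows["start"].append(pos)
        rows["strand"].append("+" if rng.random() < 0.5 else "-")
    for _ in range(n_reads - n_tss):
        chrom = config.layout.chroms[int(rng.integers(len(config.layout.chroms)))]
        rows["chrom"].append(chrom)
        rows["start"].append(int(rng.integers(0, config.layout.length(chrom) - read_len)))
        rows["strand"].append("+" if rng.random() < 0.5 else "-")
    df = pd.DataFrame(rows)
    df["end"] = df["start"] + read_len
    return df[["chrom", "start", "end", "strand"]]


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------


def simulate_genotypes(
    config: SimConfig, truth: Optional[SimTruth] = None
) -> Tuple[pd.DataFrame, List[str], SimTruth]:
    """Two-population diploid genotypes with planted high-Fst windows.

    Background sites share allele frequencies between the populations;
    sites inside planted windows have divergent frequencies targeting
    config.sweep_fst (at sweep_fst = 1, alternately fixed differences).
    Hardy-Weinberg sampling within population. Returns a genotype table
    (columns: chrom, pos0, ref, alt, then one dosage column per sample;
    -1 = missing), population labels per sample, and the truth.
    """
    truth = truth if truth is not None else plant_truth(config)
    rng = np.random.default_rng(seed_for(config.rng_seed, "genotypes"))
    n1, n2 = config.pop_sizes
    chroms_arr, pos_arr = [], []
    per_chrom = np.round(
        config.n_variants
        * np.array([config.layout.length(c) for c in config.layout.chroms])
        / config.layout.total_length()
    ).astype(int)
    for c, k in zip(config.layout.chroms, per_chrom):
        pos = np.sort(rng.choice(config.layout.length(c), size=k, replace=False))
        chroms_arr.extend([c] * k)
        pos_arr.extend(pos.tolist())
    chroms_arr = np.array(chroms_arr)
    pos_arr = np.array(pos_arr)
    n_sites = len(pos_arr)

    in_sweep = np.zeros(n_sites, dtype=bool)
    for iv in truth.sweep_windows:
        in_sweep |= (chroms_arr == iv.chrom) & (pos_arr >= iv.start) & (pos_arr < iv.end)

    p1 = np.empty(n_sites)
    p2 = np.empty(n_sites)
    shared = rng.uniform(0.05, 0.95, size=n_sites)
    if config.background_fst > 0:
        d = np.sqrt(config.background_fst)
        sign = np.where(rng.random(n_sites) < 0.5, 1.0, -1.0)
        p1[:] = np.clip(shared + sign * d / 2, 0, 1)
        p2[:] = np.clip(shared - sign * d / 2, 0, 1)
    else:
        p1[:] = shared
        p2[:] = shared
    # planted windows: symmetric divergence around 0.5 reaching the target
    d = np.sqrt(config.sweep_fst)
    alt_sign = np.where(np.arange(n_sites) % 2 == 0, 1.0, -1.0)
    p1[in_sweep] = 0.5 + alt_sign[in_sweep] * d / 2
    p2[in_sweep] = 0.5 - alt_sign[in_sweep] * d / 2

    g1 = rng.binomial(2, np.repeat(p1[:, None], n1, axis=1))
    g2 = rng.binomial(2, np.repeat(p2[:, None], n2, axis=1))
    geno = np.concatenate([g1, g2], axis=1)
    bases = np.array(list("ACGT"))
    ref_i = rng.integers(0, 4, n_sites)
    alt_i = (ref_i + 1 + rng.integers(0, 3, n_sites)) % 4
    samples = [f"HBPC{k:03d}" for k in range(n1)] + [f"LBPC{k:03d}" for k in range(n2)]
    table = pd.concat(
        [pd.DataFrame({"chrom": chroms_arr, "pos0": pos_arr,
                       "ref": bases[ref_i], "alt": bases[alt_i]}),
         pd.DataFrame(geno, columns=samples)],
        axis=1,
    )
    labels = ["HBPC"] * n1 + ["LBPC"] * n2
    return table, labels, truth
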