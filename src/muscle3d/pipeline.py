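"""End-to-end orchestration: synthetic inputs -> matrices -> structures ->
regulatory wiring -> sweep scan -> integration report.

Every stage writes plain-text artifacts plus a manifest recording the
seed, configuration hash and package version, so a rerun with the same
configuration is bit-identical for deterministic stages.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from . import compartments as comp_mod
from . import hic, io, loops as loops_mod, regulatory as reg_mod, sweep as sweep_mod
from . import tads as tads_mod
from .genome import GenomicInterval
from .simulate import (
    CONDITIONS,
    SimConfig,
    make_genes,
    plant_truth,
    simulate_atac,
    simulate_expression,
    simulate_genotypes,
    simulate_hic,
)

logger = logging.getLogger(__name__)

ALL_STAGES = ("simulate", "hic", "compartments", "tads", "loops", "regulatory", "sweep")
STAGE_DEPS = {
    "hic": ("simulate",),
    "compartments": ("hic",),
    "tads": ("hic",),
    "loops": ("hic",),
    "regulatory": ("loops",),
    "sweep": ("simulate",),
}


@dataclass
class PipelineConfig:
    """Configuration surface for the full run; every threshold that the
    analysis conventions fix (400 kb boundary rule, +/-3 kb promoter
    window, 10 bp peak merge gap, ZFst > 3, FDR 0.05, HMM 0.99/2) is a
    named key with that value as its default."""

    outdir: str = "muscle3d_run"
    rng_seed: int = 0
    stages: Sequence[str] = ALL_STAGES
    sim: SimConfig = field(default_factory=SimConfig)
    # resolutions
    compartment_resolution: int = 1_000_000
    di_resolution: int = 40_000
    loop_resolutions: Sequence[int] = (10_000,)
    # thresholds
    di_window: int = 2_000_000
    hmm_median_posterior: float = 0.99
    hmm_min_run: int = 2
    boundary_max: int = 400_000
    boundary_tolerance_bins: int = 1
    split_containment: float = 0.8
    split_coverage: float = 0.8
    loop_fdr: float = 0.05
    promoter_flank: int = 3_000
    peak_merge_gap: int = 10
    enhancer_resolution: int = 25_000
    enhancer_fdr: float = 0.05
    dar_alpha: float = 0.05
    deg_alpha: float = 0.05
    fst_window: int = 10_000
    fst_step: int = 5_000
    zfst_threshold: float = 3.0
    ice_low_coverage_fraction: float = 0.02

    def __post_init__(self) -> None:
        self.sim = dataclasses.replace(self.sim, rng_seed=self.rng_seed)
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        active = set(self.stages)
        for st in self.stages:
            missing = set(STAGE_DEPS.get(st, ())) - active
            if missing:
                raise ValueError(
                    f"stage '{st}' requires {sorted(missing)}; enable them"
                )

    def config_hash(self) -> str:
        payload = {k: v for k, v in dataclasses.asdict(self).items()
                   if k != "outdir"}
        payload["sim"]["layout"] = self.sim.layout.to_dict()
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _dump(obj, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, sort_keys=True, indent=1, default=_json_default)
        fh.write("\n")


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, GenomicInterval):
        return [o.chrom, o.start, o.end]
    raise TypeError(f"not JSON-serializable: {type(o)}")


def run_pipeline(config: PipelineConfig) -> Dict[str, object]:
    """Execute the configured stages and return the integration report.

    Artifacts land under config.outdir; a failure in any stage aborts
    with the stage name in the exception, retaining partial outputs.
    """
    os.makedirs(config.outdir, exist_ok=True)
    report: Dict[str, object] = {}
    manifest = {
        "version": __version__,
        "seed": config.rng_seed,
        "config_hash": config.config_hash(),
        "stages": list(config.stages),
        "outputs": [],
    }
    state: Dict[str, object] = {}
    for stage in ALL_STAGES:
        if stage not in config.stages:
            continue
        t0 = time.time()
        try:
            _STAGE_FUNCS[stage](config, state, report, manifest)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc
        logger.info("stage %s done in %.1f s", stage, time.time() - t0)
    _dump(report, os.path.join(config.outdir, "report.json"))
    manifest["outputs"].append("report.json")
    manifest["outputs"] = sorted(set(manifest["outputs"]))
    _dump(manifest, os.path.join(config.outdir, "manifest.json"))
    return report


def _out(config: PipelineConfig, manifest: dict, name: str) -> str:
    manifest["outputs"].append(name)
    return os.path.join(config.outdir, name)


def _stage_simulate(config, state, report, manifest) -> None:
    sim = config.sim
    truth = plant_truth(sim)
    genes = make_genes(sim, truth)
    expr = simulate_expression(sim, truth, genes)
    atac_peaks, atac_cov, atac_counts, truth = simulate_atac(sim, genes, truth)
    geno_table, pop_labels, truth = simulate_genotypes(sim, truth)
    state.update(
        truth=truth, genes=genes, expr=expr, atac_peaks=atac_peaks,
        atac_cov=atac_cov, atac_counts=atac_counts,
        geno_table=geno_table, pop_labels=pop_labels,
    )
    io.write_layout(sim.layout, _out(config, manifest, "genome.chrom.sizes"))
    io.write_gene_table(genes, _out(config, manifest, "genes.tsv"))
    expr.to_csv(_out(config, manifest, "expression.tsv"), sep="\t", index=False)
    atac_counts.to_csv(_out(config, manifest, "atac_counts.tsv"), sep="\t", index=False)
    for sample, ivs in atac_peaks.items():
        io.write_bed(ivs, _out(config, manifest, f"atac_peaks.{sample}.bed"))
    samples = [f"{s}{k:03d}" for s, n in zip(("HBPC", "LBPC"), sim.pop_sizes)
               for k in range(n)]
    io.write_vcf(
        _out(config, manifest, "genotypes.vcf"), sim.layout,
        geno_table["chrom"].tolist(), geno_table["pos0"].tolist(),
        geno_table["ref"].tolist(), geno_table["alt"].tolist(),
        geno_table[samples].to_numpy(), samples,
    )
    truth.to_json(_out(config, manifest, "truth.json"))
    pairs = {}
    for cond in CONDITIONS:
        df, _ = simulate_hic(sim, cond, truth)
        path = _out(config, manifest, f"pairs.{cond}.allValidPairs")
        io.write_valid_pairs(df, path)
        pairs[cond] = df
    state["pairs"] = pairs


def _stage_hic(config, state, report, manifest) -> None:
    sim = config.sim
    mats: Dict[str, Dict[int, hic.ContactMatrix]] = {}
    resolutions = sorted({config.compartment_resolution, config.di_resolution,
                          *config.loop_resolutions, config.enhancer_resolution})
    for cond in CONDITIONS:
        mats[cond] = {}
        base = hic.bin_valid_pairs(state["pairs"][cond], sim.layout,
                                   min(resolutions))
        for res in resolutions:
            if res == base.resolution:
                m = base
            else:
                m = hic.bin_valid_pairs(state["pairs"][cond], sim.layout, res)
            m = hic.ice_normalize(
                m, low_coverage_fraction=config.ice_low_coverage_fraction
            )
            mats[cond][res] = m
        m40 = mats[cond][config.di_resolution]
        m40.write_triplet(
            _out(config, manifest, f"matrix.{cond}.{config.di_resolution}.txt"),
            _out(config, manifest, f"bins.{cond}.{config.di_resolution}.bed"),
        )
        decay = hic.contact_decay(m40)
        report.setdefault("decay_slope", {})[cond] = round(decay.slope, 4)
        base_res = min(resolutions)
        rescap = hic.resolution_capability(
            mats[cond][base_res],
            [r for r in resolutions
             if r <= config.di_resolution and r % base_res == 0],
        )
        report.setdefault("resolution_capability", {})[cond] = rescap
    report["matrix_correlation"] = {
        str(res): round(hic.matrix_correlation(mats["fetal"][res],
                                               mats["adult"][res]), 4)
        for res in (config.compartment_resolution, config.di_resolution)
    }
    trans = hic.trans_contact_summary(mats["fetal"][config.di_resolution],
                                      mats["adult"][config.di_resolution])
    trans.to_csv(_out(config, manifest, "trans_contacts.tsv"), sep="\t", index=False)
    state["mats"] = mats


def _stage_compartments(config, state, report, manifest) -> None:
    genes = state["genes"]
    sim = config.sim
    track = comp_mod.gene_density_track(sim.layout, genes,
                                        config.compartment_resolution)
    cts = {}
    for cond in CONDITIONS:
        ct = comp_mod.call_compartments(
            state["mats"][cond][config.compartment_resolution], track
        )
        cts[cond] = ct
        frame = ct.to_frame()
        frame.to_csv(_out(config, manifest, f"compartments.{cond}.bedgraph"),
                     sep="\t", index=False, header=False)
        report.setdefault("compartment_fractions", {})[cond] = {
            k: round(v, 2) for k, v in ct.fractions().items()
        }
    trans = comp_mod.compartment_transitions(cts["fetal"], cts["adult"], genes,
                                             conditions=CONDITIONS)
    trans.table.to_csv(_out(config, manifest, "compartment_transitions.bed"),
                       sep="\t", index=False, header=False)
    trans.tests.to_csv(_out(config, manifest, "compartment_transition_tests.tsv"),
                       sep="\t", index=False)
    report["compartment_transitions_mb"] = {
        k: round(v, 1) for k, v in trans.mb_per_class.items()
    }
    report["compartment_transition_tests"] = trans.tests.to_dict(orient="records")
    state["compartments"] = cts


def _stage_tads(config, state, report, manifest) -> None:
    tsets = {}
    for cond in CONDITIONS:
        di = tads_mod.compute_di(state["mats"][cond][config.di_resolution],
                                 window=config.di_window)
        ts = tads_mod.call_tads(
            di,
            median_posterior_threshold=config.hmm_median_posterior,
            min_run=config.hmm_min_run,
            boundary_max=config.boundary_max,
        )
        tsets[cond] = ts
        io.write_bedgraph(
            [GenomicInterval(c, b * di.resolution,
                             min((b + 1) * di.resolution, di.layout.length(c)))
             for c in di.layout.chroms for b in range(len(di.di[c]))],
            np.concatenate([di.di[c] for c in di.layout.chroms]),
            _out(config, manifest, f"di.{cond}.bedgraph"),
        )
        io.write_bed(ts.tads, _out(config, manifest, f"tads.{cond}.bed"))
        io.write_bed(ts.boundaries, _out(config, manifest, f"boundaries.{cond}.bed"))
        report.setdefault("tads", {})[cond] = {
            "n_tads": len(ts.tads),
            "n_boundaries": len(ts.boundaries),
            "mean_length_kb": round(float(np.mean([len(t) for t in ts.tads]) / 1e3), 2)
            if ts.tads else np.nan,
        }
    spx, spy = tads_mod.compare_boundaries(
        tsets["fetal"], tsets["adult"], config.boundary_tolerance_bins
    )
    report["stage_specific_boundaries"] = {"fetal": len(spx), "adult": len(spy)}
    maps = tads_mod.detect_split_tads(
        tsets["fetal"], tsets["adult"], config.split_containment,
        config.split_coverage, "fetal", "adult",
    )
    rows = [{"uc_condition": m.uc_condition, "ucTAD": m.ucTAD.display(),
             "n_spTADs": len(m.spTADs), "coverage": round(m.coverage, 3)}
            for m in maps]
    pd.DataFrame(rows).to_csv(_out(config, manifest, "split_tads.tsv"),
                              sep="\t", index=False)
    report["split_tads"] = {
        "n_mappings": len(maps),
        "n_spTADs": int(sum(len(m.spTADs) for m in maps)),
    }
    state["tads"] = tsets


def _stage_loops(config, state, report, manifest) -> None:
    loop_sets = {}
    for cond in CONDITIONS:
        mats = {res: state["mats"][cond][res] for res in config.loop_resolutions}
        lps = loops_mod.call_loops(mats, fdr=config.loop_fdr)
        loop_sets[cond] = lps
        df = pd.DataFrame([
            {"chrom1": l.chrom, "start1": l.anchor1.start, "end1": l.anchor1.end,
             "chrom2": l.chrom, "start2": l.anchor2.start, "end2": l.anchor2.end,
             "name": f"loop_{k}", "score": round(-np.log10(max(l.q_value, 1e-300)), 3),
             "count": l.count, "expected": round(l.expected, 3),
             "q_value": l.q_value}
            for k, l in enumerate(lps)
        ])
        io.write_bedpe(df, _out(config, manifest, f"loops.{cond}.bedpe")) if len(df) \
            else open(_out(config, manifest, f"loops.{cond}.bedpe"), "w").close()
        entry = {
            "n_loops": len(lps),
            "mean_length_kb": round(float(np.mean([l.length for l in lps]) / 1e3), 2)
            if lps else np.nan,
        }
        fine = min(config.loop_resolutions)
        usable = [l for l in lps if l.length > 12 * fine]
        if usable:
            ap = loops_mod.apa(usable, state["mats"][cond][fine])
            entry["apa_p2ll"] = round(ap.p2ll, 3)
            entry["apa_zscore_ll"] = round(ap.zscore_ll, 3)
        report.setdefault("loops", {})[cond] = entry
    fine = min(config.loop_resolutions)
    spec_f, spec_a = loops_mod.differential_loops(
        loop_sets["fetal"], state["mats"]["fetal"][fine],
        loop_sets["adult"], state["mats"]["adult"][fine],
        fdr=config.loop_fdr,
    )
    report["stage_specific_loops"] = {"fetal": len(spec_f), "adult": len(spec_a)}
    state["loops"] = loop_sets
    state["specific_loops"] = {"fetal": spec_f, "adult": spec_a}


def _stage_regulatory(config, state, report, manifest) -> None:
    sim = config.sim
    genes = state["genes"]
    condition_of = {s: ("fetal" if s.startswith("fetal") else "adult")
                    for s in state["atac_peaks"]}
    union = reg_mod.build_union_peaks(
        state["atac_peaks"], state["atac_cov"], condition_of,
        merge_gap=config.peak_merge_gap,
    )
    # differential accessibility on the simulated count matrix
    count_cols = [c for c in state["atac_counts"].columns
                  if c not in ("peak_id", "chrom", "start", "end")]
    dar = reg_mod.differential_counts(
        state["atac_counts"][count_cols],
        [condition_of[c] for c in count_cols],
        alpha=config.dar_alpha, mode="p",
    )
    report["n_dars"] = int(dar["significant"].sum())
    # differential expression (q-value convention)
    expr = state["expr"]
    cnt_cols = [c for c in expr.columns if c.startswith("count_")]
    deg = reg_mod.differential_counts(
        expr[cnt_cols],
        ["fetal" if "fetal" in c else "adult" for c in cnt_cols],
        alpha=config.deg_alpha, mode="q",
    )
    report["n_degs"] = int(deg["significant"].sum())

    # one element catalog: enhancer candidates pooled over conditions
    expressed_promoters = [g.promoter(config.promoter_flank) for g in genes
                           if g.mean_fpkm() > 0]
    enh_all: List[GenomicInterval] = []
    for cond in CONDITIONS:
        enh_all.extend(reg_mod.predict_enhancer_candidates(
            state["mats"][cond][config.enhancer_resolution],
            state["tads"][cond],
            expressed_promoters,
            fdr=config.enhancer_fdr,
        ))
    out: Dict[str, object] = {}
    for cond in CONDITIONS:
        lps = state["loops"][cond]
        anchors = []
        seen = set()
        for l in lps:
            for anc in (l.anchor1, l.anchor2):
                key = (anc.chrom, anc.start, anc.end)
                if key not in seen:
                    seen.add(key)
                    anchors.append(anc)
        union_c, anchor_elems = reg_mod.classify_elements(
            union, genes, enh_all, anchors, flank=config.promoter_flank
        )
        pairs, census = reg_mod.wire_and_census(
            lps, anchor_elems, genes, cond, flank=config.promoter_flank
        )
        cats = loops_mod.categorize_genes_by_loops(genes, lps,
                                                   flank=config.promoter_flank)
        effects = reg_mod.expression_effects(
            genes, cats, pairs, anchor_elems, union_c, lps, cond
        )
        io.write_bed(
            [GenomicInterval(p.interval.chrom, p.interval.start, p.interval.end,
                             name=p.cls, score=round(p.enrichment, 4))
             for p in union_c],
            _out(config, manifest, f"union_peaks.{cond}.bed"),
        )
        io.write_bed(
            [GenomicInterval(a.anchor.chrom, a.anchor.start, a.anchor.end,
                             name=a.cls) for a in anchor_elems],
            _out(config, manifest, f"anchors.{cond}.bed"),
        )
        pairs.to_csv(_out(config, manifest, f"interaction_pairs.{cond}.tsv"),
                     sep="\t", index=False)
        census.to_csv(_out(config, manifest, f"pair_census.{cond}.tsv"),
                      sep="\t", index=False)
        class_counts = pd.Series([p.cls for p in union_c]).value_counts().to_dict()
        out[cond] = {
            "n_union_peaks": len(union_c),
            "peak_classes": class_counts,
            "n_anchor_N": int(sum(1 for a in anchor_elems if a.cls == "N")),
            "n_interaction_pairs": int(len(pairs)),
            "top_pairs": census.head(3).to_dict(orient="records"),
            "expression_effects": effects,
        }
        state.setdefault("anchor_elements", {})[cond] = anchor_elems
        state.setdefault("union_peaks", {})[cond] = union_c
        state.setdefault("gene_categories", {})[cond] = cats
    report["regulatory"] = out


def _stage_sweep(config, state, report, manifest) -> None:
    sim = config.sim
    filt = sweep_mod.filter_variants(state["geno_table"])
    win = sweep_mod.windowed_zfst(filt, state["pop_labels"], sim.layout,
                                  window=config.fst_window, step=config.fst_step)
    win.to_csv(_out(config, manifest, "fst_windows.tsv"), sep="\t", index=False)
    regions = sweep_mod.call_sweep_regions(win, config.zfst_threshold)
    io.write_bed(
        [GenomicInterval(r.interval.chrom, r.interval.start, r.interval.end,
                         name=f"z={r.max_zfst:.2f}") for r in regions],
        _out(config, manifest, "sweep_regions.bed"),
    )
    report["sweep"] = {
        "n_variants": int(len(filt)),
        "n_windows": int(np.isfinite(win["zfst"]).sum()),
        "n_sweep_regions": len(regions),
        "max_zfst": round(float(win["zfst"].max()), 3),
    }
    # enrichment of regulatory element classes in sweeps (fetal catalog)
    if "anchor_elements" in state:
        union_c = state["union_peaks"]["fetal"]
        anchor_elems = state["anchor_elements"]["fetal"]
        query = {
            cls: [p.interval for p in union_c if p.cls == cls]
            for cls in ("P", "E", "O")
        }
        query["N"] = [a.anchor for a in anchor_elems if a.cls == "N"]
        enr = sweep_mod.region_enrichment(query, regions, sim.layout,
                                          bin_size=config.fst_window)
        enr.to_csv(_out(config, manifest, "sweep_enrichment.tsv"),
                   sep="\t", index=False)
        report["sweep"]["enrichment"] = enr.to_dict(orient="records")


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "hic": _stage_hic,
    "compartments": _stage_compartments,
    "tads": _stage_tads,
    "loops": _stage_loops,
    "regulatory": _stage_regulatory,
    "sweep": _stage_sweep,
}
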