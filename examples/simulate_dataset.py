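"""Generate a complete synthetic multi-omic dataset with planted truth.

Every downstream example starts from data like this: Hi-C valid pairs
with planted compartments/TADs/loops, ATAC replicate peaks, an expression
table coupled to the planted structures, and two-population genotypes
with planted selection sweeps.
"""

from muscle3d.simulate import (
    SimConfig, make_genes, plant_truth, simulate_atac, simulate_expression,
    simulate_genotypes, simulate_hic,
)

cfg = SimConfig(rng_seed=1)
truth = plant_truth(cfg)
genes = make_genes(cfg, truth)

pairs, _ = simulate_hic(cfg, "fetal", truth)
expr = simulate_expression(cfg, truth, genes)
peaks, coverage, counts, truth = simulate_atac(cfg, genes, truth)
geno, labels, truth = simulate_genotypes(cfg, truth)

print(f"genome: {cfg.layout.to_dict()}")
print(f"valid pairs (fetal): {len(pairs):,} "
      f"({cfg.trans_fraction:.0%} trans)")
print(f"planted TADs: fetal {len(truth.tads['fetal'])}, "
      f"adult {len(truth.tads['adult'])} "
      f"({len(truth.splits)} split relations)")
print(f"planted loops: fetal {len(truth.loops['fetal'])}, "
      f"adult {len(truth.loops['adult'])}")
print(f"genes: {len(genes)}; ATAC samples: {list(peaks)}")
print(f"genotypes: {len(geno):,} sites x {len(labels)} samples; "
      f"{len(truth.sweep_windows)} planted sweep windows")
# The truth object records exactly what each caller below must recover.
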