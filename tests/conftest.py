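import numpy as np
import pytest

from muscle3d.genome import GenomeLayout
from muscle3d.hic import ice_normalize
from muscle3d.simulate import SimConfig, expected_matrix, plant_truth, sample_matrix


@pytest.fixture(scope="session")
def tad_config():
    """Noise-free TAD benchmark: 20 planted TADs, no competing structure."""
    return SimConfig(rng_seed=1, tad_count=20, compartment_block_scale=1.0,
                     loop_fold=1.0)


@pytest.fixture(scope="session")
def tad_truth(tad_config):
    return plant_truth(tad_config)


@pytest.fixture(scope="session")
def tad_matrices(tad_config, tad_truth):
    """ICE-balanced noise-free 40 kb matrices for both conditions."""
    return {
        cond: ice_normalize(expected_matrix(tad_config, cond, 40_000, tad_truth))
        for cond in ("fetal", "adult")
    }


@pytest.fixture(scope="session")
def loop_config():
    """Deep single-chromosome benchmark: 50 planted loops at 10 kb."""
    return SimConfig(layout=GenomeLayout({"chr1": 20_000_000}), n_pairs=9_000_000,
                     trans_fraction=0.0, tad_count=8, loop_count=50, rng_seed=1)


@pytest.fixture(scope="session")
def loop_truth(loop_config):
    return plant_truth(loop_config)


@pytest.fixture(scope="session")
def loop_matrix(loop_config, loop_truth):
    return ice_normalize(sample_matrix(loop_config, "fetal", 10_000, loop_truth))


@pytest.fixture(scope="session")
def default_truth():
    cfg = SimConfig(rng_seed=1)
    return cfg, plant_truth(cfg)


def boundary_recovery(planted_tads, called_tadset, resolution=40_000):
    """Fraction of planted inter-TAD boundaries matched by a called
    transition (boundary or TAD junction) within the gap +/- 1 bin."""
    transitions = []
    for a, b in zip(called_tadset.tads, called_tadset.tads[1:]):
        if a.chrom == b.chrom:
            transitions.append((a.chrom, a.end, max(a.end + 1, b.start)))
    hit = tot = 0
    for a, b in zip(planted_tads, planted_tads[1:]):
        if a.chrom != b.chrom:
            continue
        tot += 1
        lo, hi = a.end - resolution, b.start + resolution
        if any(c == a.chrom and s <= hi and e >= lo for c, s, e in transitions):
            hit += 1
    return hit, tot
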