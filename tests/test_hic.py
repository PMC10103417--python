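import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from muscle3d.genome import GenomeLayout
from muscle3d.hic import (
    ContactMatrix,
    bin_valid_pairs,
    contact_decay,
    ice_normalize,
    matrix_correlation,
    resolution_capability,
    trans_contact_summary,
)
from muscle3d.simulate import SimConfig, plant_truth, sample_matrix, simulate_hic


def pairs_frame(rows):
    return pd.DataFrame(
        [{"read_id": f"r{k}", "chrom1": c1, "pos1": p1, "strand1": "+",
          "chrom2": c2, "pos2": p2, "strand2": "-"}
         for k, (c1, p1, c2, p2) in enumerate(rows)]
    )


LAYOUT = GenomeLayout({"chr1": 200_000, "chr2": 120_000})


class TestBinning:
    def test_single_cis_pair(self):
        m = bin_valid_pairs(pairs_frame([("chr1", 5_000, "chr1", 45_000)]),
                            LAYOUT, 40_000)
        assert m.cis["chr1"][0, 1] == 1 and m.cis["chr1"][1, 0] == 1
        assert m.total_cis() == 1 and m.total_trans() == 0

    def test_duplicate_pair_counts_twice(self):
        m = bin_valid_pairs(pairs_frame([("chr1", 5_000, "chr1", 45_000)] * 2),
                            LAYOUT, 40_000)
        assert m.cis["chr1"][0, 1] == 2

    def test_trans_pair_goes_to_block(self):
        m = bin_valid_pairs(pairs_frame([("chr2", 10, "chr1", 10)]), LAYOUT, 40_000)
        assert m.total_cis() == 0
        assert m.trans[("chr1", "chr2")][0, 0] == 1

    def test_unknown_chromosome_skipped(self, caplog):
        m = bin_valid_pairs(
            pairs_frame([("chrX", 10, "chr1", 10), ("chr1", 1, "chr1", 2)]),
            LAYOUT, 40_000)
        assert m.total_cis() == 1

    def test_out_of_bounds_position_raises(self):
        with pytest.raises(ValueError):
            bin_valid_pairs(pairs_frame([("chr1", 300_000, "chr1", 10)]),
                            LAYOUT, 40_000)

    def test_pair_conservation(self):
        cfg = SimConfig(rng_seed=7, n_pairs=50_000)
        df, _ = simulate_hic(cfg, "fetal")
        m = bin_valid_pairs(df, cfg.layout, 40_000)
        assert m.total_cis() + m.total_trans() == len(df)

    def test_triplet_round_trip(self, tmp_path):
        cfg = SimConfig(rng_seed=7, n_pairs=20_000)
        df, _ = simulate_hic(cfg, "fetal")
        m = bin_valid_pairs(df, cfg.layout, 1_000_000)
        mp, bp = str(tmp_path / "m.txt"), str(tmp_path / "b.bed")
        m.write_triplet(mp, bp)
        back = ContactMatrix.read_triplet(mp, bp, cfg.layout, 1_000_000)
        for c in m.chroms:
            assert (m.cis[c] != back.cis[c]).nnz == 0
        for k in m.trans:
            assert (m.trans[k] != back.trans[k]).nnz == 0


class TestIce:
    def _matrix(self, dense, chrom_len=None):
        n = dense.shape[0]
        lay = GenomeLayout({"chr1": (chrom_len or n * 10)})
        return ContactMatrix(lay, 10, {"chr1": sp.csr_matrix(dense.astype(float))})

    def test_already_balanced(self):
        m = ice_normalize(self._matrix(np.array([[0, 4], [4, 0]])),
                          low_coverage_fraction=0.0)
        w = m.weights["chr1"]
        assert np.allclose(w[0], w[1])
        assert m.converged

    def test_unequal_coverage_converges(self):
        dense = np.array([[0, 10, 2], [10, 0, 1], [2, 1, 0]], float)
        m = ice_normalize(self._matrix(dense), tol=1e-6,
                          low_coverage_fraction=0.0)
        bal = m.balanced("chr1")
        rows = np.nansum(bal, axis=1)
        assert rows.std() / rows.mean() < 1e-3

    def test_zero_row_masked_others_converge(self):
        dense = np.array([[0, 5, 0], [5, 0, 0], [0, 0, 0]], float)
        m = ice_normalize(self._matrix(dense), low_coverage_fraction=0.0)
        assert m.mask("chr1").tolist() == [False, False, True]

    def test_all_empty_raises(self):
        with pytest.raises(ValueError):
            ice_normalize(self._matrix(np.zeros((3, 3))))

    def test_balanced_stays_symmetric(self):
        rng = np.random.default_rng(0)
        dense = rng.poisson(5, (20, 20)).astype(float)
        dense = dense + dense.T
        m = ice_normalize(self._matrix(dense))
        bal = m.balanced("chr1")
        ok = np.isfinite(bal)
        assert np.allclose(bal[ok & ok.T], bal.T[ok & ok.T])


@pytest.fixture(scope="module")
def balanced():
    cfg = SimConfig(rng_seed=3)
    truth = plant_truth(cfg)
    return ice_normalize(sample_matrix(cfg, "fetal", 1_000_000, truth))


class TestCorrelation:
    def test_self_correlation_is_one(self, balanced):
        assert matrix_correlation(balanced, balanced) == pytest.approx(1.0)

    def test_scale_invariance(self, balanced):
        doubled = ContactMatrix(
            balanced.layout, balanced.resolution,
            {c: balanced.cis[c] * 2 for c in balanced.chroms},
            weights=balanced.weights,
        )
        assert matrix_correlation(balanced, doubled) == pytest.approx(1.0)

    def test_independent_matrices_uncorrelated(self):
        # same decay but disjoint seeds and no shared structure; distance
        # decay is removed per diagonal so only noise could correlate
        r = []
        for seed in (11, 12):
            cfg = SimConfig(rng_seed=seed, compartment_block_scale=1.0,
                            tad_fold=1.0, loop_fold=1.0, n_pairs=500_000)
            truth = plant_truth(cfg)
            truth.loops = {c: truth.loops[c].assign(fold=1.0) for c in truth.loops}
            r.append(sample_matrix(cfg, "fetal", 1_000_000, truth))
        a, b = r
        va, vb = [], []
        for c in a.chroms:
            da, db = a.dense(c), b.dense(c)
            for off in range(3, 15):
                x, y = np.diagonal(da, off), np.diagonal(db, off)
                va.extend(x - x.mean())
                vb.extend(y - y.mean())
        resid_r = np.corrcoef(va, vb)[0, 1]
        assert abs(resid_r) < 0.1

    def test_resolution_mismatch_rejected(self, balanced):
        cfg = SimConfig(rng_seed=3)
        other = sample_matrix(cfg, "fetal", 500_000)
        other = ice_normalize(other)
        with pytest.raises(ValueError):
            matrix_correlation(balanced, other)


class TestDecay:
    def test_power_law_slope_recovered(self):
        cfg = SimConfig(rng_seed=2, compartment_block_scale=1.0, tad_fold=1.0,
                        loop_fold=1.0)
        truth = plant_truth(cfg)
        truth.loops = {c: truth.loops[c].assign(fold=1.0) for c in truth.loops}
        m = sample_matrix(cfg, "fetal", 40_000, truth)
        assert contact_decay(m).slope == pytest.approx(-1.0, abs=0.05)

    def test_constant_matrix_slope_zero(self):
        lay = GenomeLayout({"chr1": 10_000_000})
        dense = np.ones((250, 250))
        m = ContactMatrix(lay, 40_000, {"chr1": sp.csr_matrix(dense)})
        assert contact_decay(m).slope == pytest.approx(0.0, abs=1e-6)

    def test_long_range_excess_flattens_slope(self):
        base = SimConfig(rng_seed=4, compartment_block_scale=1.0, tad_fold=1.0,
                         loop_fold=1.0)
        steep = SimConfig(rng_seed=4, decay_exponent=-1.2,
                          compartment_block_scale=1.0, tad_fold=1.0, loop_fold=1.0)
        s_base = contact_decay(sample_matrix(base, "fetal", 40_000)).slope
        s_steep = contact_decay(sample_matrix(steep, "fetal", 40_000)).slope
        assert s_base > s_steep

    def test_empty_fit_range_rejected(self):
        cfg = SimConfig(rng_seed=2, n_pairs=100_000)
        m = sample_matrix(cfg, "fetal", 40_000)
        with pytest.raises(ValueError):
            contact_decay(m, fit_range=(1000, 1000))


class TestResolutionCapability:
    def _uniform_matrix(self, per_bin_pairs, n=100, res=5_000):
        lay = GenomeLayout({"chr1": n * res})
        dense = np.full((n, n), per_bin_pairs / n)
        return ContactMatrix(lay, res, {"chr1": sp.csr_matrix(dense)})

    def test_returns_smallest_qualifying(self):
        # ~600 pairs per 5 kb bin -> 1200 per 10 kb bin: only 10 kb qualifies
        m = self._uniform_matrix(600)
        assert resolution_capability(m, [5_000, 10_000]) == 10_000

    def test_all_qualify_returns_finest(self):
        m = self._uniform_matrix(2_000)
        assert resolution_capability(m, [5_000, 10_000]) == 5_000

    def test_none_qualify(self):
        m = self._uniform_matrix(10)
        assert resolution_capability(m, [5_000, 10_000]) is None

    def test_empty_candidates_rejected(self):
        with pytest.raises(ValueError):
            resolution_capability(self._uniform_matrix(10), [])


class TestTransSummary:
    def test_uniform_trans_near_one(self):
        cfg = SimConfig(rng_seed=5, trans_fraction=0.5, n_pairs=2_000_000)
        df, _ = simulate_hic(cfg, "fetal")
        m = bin_valid_pairs(df, cfg.layout, 1_000_000)
        tab = trans_contact_summary(m)
        assert np.allclose(tab["normalized"], 1.0, atol=0.1)

    def test_self_difference_is_zero(self):
        cfg = SimConfig(rng_seed=5, n_pairs=200_000)
        df, _ = simulate_hic(cfg, "fetal")
        m = bin_valid_pairs(df, cfg.layout, 1_000_000)
        tab = trans_contact_summary(m, m)
        assert np.allclose(tab["difference"], 0.0)

    def test_planted_excess_recovered(self):
        lay = GenomeLayout({"chr1": 2_000_000, "chr2": 2_000_000,
                            "chr3": 2_000_000})
        m = ContactMatrix.empty(lay, 1_000_000)
        n = 2
        base = np.full((n, n), 50.0)
        m.trans[("chr1", "chr2")] = sp.csr_matrix(base * 3)
        m.trans[("chr1", "chr3")] = sp.csr_matrix(base)
        m.trans[("chr2", "chr3")] = sp.csr_matrix(base)
        tab = trans_contact_summary(m).set_index(["chrom1", "chrom2"])
        assert tab.loc[("chr1", "chr2"), "normalized"] == pytest.approx(1.8)
        # 3x planted excess stands out against the uniform pairs
        assert tab.loc[("chr1", "chr2"), "normalized"] > \
            2.5 * tab.loc[("chr1", "chr3"), "normalized"]
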