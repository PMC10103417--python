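import numpy as np
import pandas as pd
import pytest
from scipy import stats

from muscle3d.genome import GenomeLayout, GenomicInterval
from muscle3d.simulate import SimConfig, simulate_genotypes
from muscle3d.sweep import (
    SweepRegion,
    call_sweep_regions,
    filter_variants,
    genotype_pca,
    region_enrichment,
    wc_components,
    windowed_zfst,
)


def table_from(geno, positions=None, chrom="chr1"):
    n_sites, n_samp = geno.shape
    pos = positions if positions is not None else np.arange(n_sites) * 100
    df = pd.DataFrame({"chrom": chrom, "pos0": pos,
                       "ref": "A", "alt": "G"})
    for k in range(n_samp):
        df[f"s{k}"] = geno[:, k]
    return df


class TestFilterVariants:
    def test_missing_rate_boundary(self):
        # 40% missing -> removed; 20% missing -> kept
        geno = np.array([
            [-1, -1, 1, 1, 1, 1, 1, 1, 0, 0],   # 20% missing
            [-1, -1, -1, -1, 1, 1, 1, 1, 0, 0],  # 40% missing
        ])
        out = filter_variants(table_from(geno), max_missing=0.3, maf=0.0)
        assert len(out) == 1
        assert out["pos0"].iloc[0] == 0

    def test_maf_strictly_greater(self):
        # 50 diploids: one alt allele -> MAF = 0.01 exactly -> removed
        geno_low = np.zeros((1, 50), int)
        geno_low[0, 0] = 1
        assert len(filter_variants(table_from(geno_low), maf=0.01)) == 0
        geno_ok = np.zeros((1, 50), int)
        geno_ok[0, :2] = 1  # MAF 0.02 > 0.01
        assert len(filter_variants(table_from(geno_ok), maf=0.01)) == 1

    def test_common_fully_called_site_kept(self):
        geno = np.tile([0, 1, 2, 1], (1, 5))
        assert len(filter_variants(table_from(geno))) == 1


class TestWeirCockerham:
    def hand_toy(self):
        """4-sample toy (2 per population), worked by hand.

        pop1: genotypes 2, 2 (p1 = 1, h1 = 0); pop2: 0, 0 (p2 = 0, h2 = 0).
        nbar = 2, nc = 2, pbar = 0.5, s2 = 0.5, hbar = 0.
        a = (2/2) * (0.5 - (0.5*0.5 - 0.25*... )):
          inner = (pbar(1-pbar) - s2/2 - hbar/4)/(nbar-1) = (0.25 - 0.25)/1 = 0
          a = 0.5
        b = (2/1) * (0.25 - 0.25 - 0) = 0;  c = 0.  Fst = a/(a+b+c) = 1.
        """
        geno = np.array([[2, 2, 0, 0]])
        return geno

    def test_hand_computed_components(self):
        geno = self.hand_toy()
        a, b, c = wc_components(geno, np.array([True, True, False, False]),
                                np.array([False, False, True, True]))
        assert a[0] == pytest.approx(0.5)
        assert b[0] == pytest.approx(0.0)
        assert c[0] == pytest.approx(0.0)

    def test_het_toy_components(self):
        # pop1: 1,1 (p=0.5, h=1); pop2: 1,1 -> identical pops, all het
        # pbar=0.5, s2=0, hbar=1: a = (2/2)(0 - (0.25 - 0 - 0.25)/1) = 0
        # b = 2*(0.25 - 0 - (3/8)*1) = -0.25 ; c = 0.5
        geno = np.array([[1, 1, 1, 1]])
        a, b, c = wc_components(geno, np.array([True, True, False, False]),
                                np.array([False, False, True, True]))
        assert a[0] == pytest.approx(0.0)
        assert b[0] == pytest.approx(-0.25)
        assert c[0] == pytest.approx(0.5)

    def test_insufficient_samples_nan(self):
        geno = np.array([[2, -1, 0, 0]])
        a, _, _ = wc_components(geno, np.array([True, True, False, False]),
                                np.array([False, False, True, True]))
        assert np.isnan(a[0])


class TestWindowedZfst:
    def _layout(self, length=100_000):
        return GenomeLayout({"chr1": length})

    def test_fixed_differences_fst_one(self):
        rng = np.random.default_rng(0)
        n1, n2 = 8, 8
        fixed = np.hstack([np.full((20, n1), 2), np.full((20, n2), 0)])
        shared = rng.binomial(2, 0.5, (100, n1 + n2))
        pos = np.concatenate([np.arange(20) * 100,          # window 1: fixed
                              50_000 + np.arange(100) * 100])
        table = table_from(np.vstack([fixed, shared]), positions=pos)
        labels = ["p1"] * n1 + ["p2"] * n2
        win = windowed_zfst(table, labels, self._layout())
        first = win[(win["start"] == 0)]
        assert first["fst"].iloc[0] == pytest.approx(1.0)

    def test_identical_frequencies_fst_near_zero(self):
        rng = np.random.default_rng(1)
        geno = rng.binomial(2, 0.4, (400, 100))
        table = table_from(geno)
        win = windowed_zfst(table, ["p1"] * 50 + ["p2"] * 50, self._layout())
        assert abs(np.nanmean(win["fst"])) < 0.02

    def test_zfst_standardization_exact(self):
        rng = np.random.default_rng(2)
        geno = rng.binomial(2, 0.4, (1000, 40))
        table = table_from(geno)
        win = windowed_zfst(table, ["p1"] * 20 + ["p2"] * 20, self._layout())
        z = win["zfst"].to_numpy()
        z = z[np.isfinite(z)]
        assert abs(z.mean()) < 1e-6
        assert abs(z.std() - 1) < 1e-6
        # a window at the scan mean has ZFst 0 by definition
        f = win["fst"].to_numpy()
        mu = f[np.isfinite(f)].mean()
        assert np.interp(mu, sorted(f[np.isfinite(f)]),
                         sorted(z)) == pytest.approx(0.0, abs=1e-9)

    def test_degenerate_scan_rejected(self):
        geno = np.zeros((50, 20), int)
        geno[:, :] = 1  # every sample het at every site: zero variance scan
        table = table_from(geno)
        with pytest.raises(ValueError):
            windowed_zfst(table, ["p1"] * 10 + ["p2"] * 10, self._layout())


class TestSweepRegions:
    def _windows(self, zvals, step=5_000, size=10_000):
        rows = [("chr1", k * step, k * step + size, 5, 0.1, z)
                for k, z in enumerate(zvals)]
        return pd.DataFrame(rows, columns=["chrom", "start", "end",
                                           "n_variants", "fst", "zfst"])

    def test_no_window_above_threshold(self):
        assert call_sweep_regions(self._windows([0, 1, 2.9])) == []

    def test_consecutive_windows_merge(self):
        regs = call_sweep_regions(self._windows([0, 4, 5, 4, 0]))
        assert len(regs) == 1
        assert (regs[0].interval.start, regs[0].interval.end) == (5_000, 25_000)
        assert regs[0].max_zfst == 5
        assert regs[0].n_windows == 3

    def test_separate_runs_stay_separate(self):
        regs = call_sweep_regions(self._windows([4, 0, 0, 0, 4]))
        assert len(regs) == 2

    def test_planted_sweeps_recovered_with_specificity(self):
        cfg = SimConfig(rng_seed=11)
        table, labels, truth = simulate_genotypes(cfg)
        win = windowed_zfst(filter_variants(table), labels, cfg.layout)
        regs = call_sweep_regions(win)
        for planted in truth.sweep_windows:
            assert any(r.interval.overlaps(planted) for r in regs), planted
        from muscle3d.genome import intersect_any

        ok = win[np.isfinite(win["zfst"])]
        wiv = [GenomicInterval(r.chrom, r.start, r.end)
               for r in ok.itertuples(index=False)]
        in_planted = intersect_any(wiv, truth.sweep_windows)
        background_ok = (ok["zfst"].to_numpy() <= 3) | in_planted
        assert background_ok.mean() >= 0.95


def hypergeom_two_sided(a, b, c, d):
    """Enumeration oracle for Fisher's exact: sum of table probabilities
    no larger than the observed one, margins fixed."""
    n = a + b + c + d
    r1, c1 = a + b, a + c
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    probs = {k: stats.hypergeom.pmf(k, n, r1, c1) for k in range(lo, hi + 1)}
    obs = probs[a]
    return min(1.0, sum(p for p in probs.values() if p <= obs * (1 + 1e-9)))


class TestRegionEnrichment:
    def _layout(self):
        return GenomeLayout({"chr1": 1_000_000})  # 100 x 10 kb bins

    def _sweeps(self, spans):
        return [SweepRegion(GenomicInterval("chr1", s, e), 5.0, 1)
                for s, e in spans]

    def test_query_equals_sweeps_gives_enumerated_tail(self):
        spans = [(0, 50_000), (200_000, 230_000)]
        sweeps = self._sweeps(spans)
        query = {"P": [GenomicInterval("chr1", s, e) for s, e in spans]}
        out = region_enrichment(query, sweeps, self._layout())
        row = out.iloc[0]
        assert row["both"] == 8 and row["query_only"] == 0
        assert np.isinf(row["odds_ratio"])
        assert row["p_value"] == pytest.approx(
            hypergeom_two_sided(8, 0, 0, 92), rel=1e-9)

    def test_disjoint_query_odds_below_one(self):
        sweeps = self._sweeps([(0, 100_000)])
        query = {"E": [GenomicInterval("chr1", 500_000, 600_000)]}
        out = region_enrichment(query, sweeps, self._layout())
        assert out.iloc[0]["odds_ratio"] < 1

    def test_fisher_matches_enumeration_small_margins(self):
        rng = np.random.default_rng(3)
        # exhaustively for all totals <= 14, plus random tables with
        # margins up to 30
        tables = [(a, b, c, d)
                  for a in range(8) for b in range(8)
                  for c in range(8) for d in range(8)
                  if 0 < a + b + c + d <= 14]
        for _ in range(300):
            t = tuple(int(x) for x in rng.integers(0, 16, 4))
            if sum(t) and max(t[0] + t[1], t[2] + t[3]) <= 30:
                tables.append(t)
        for a, b, c, d in tables:
            _, p = stats.fisher_exact([[a, b], [c, d]])
            assert p == pytest.approx(hypergeom_two_sided(a, b, c, d),
                                      rel=1e-7, abs=1e-12), (a, b, c, d)

    def test_minimal_universe_runs(self):
        out = region_enrichment({"P": []}, [], GenomeLayout({"chr1": 1}))
        assert len(out) == 1 and out.iloc[0]["both"] == 0


class TestGenotypePca:
    def test_two_populations_separate_on_pc1(self):
        cfg = SimConfig(rng_seed=12, background_fst=0.1)
        table, labels, _ = simulate_genotypes(cfg)
        coords, frac = genotype_pca(table)
        lab = np.array(labels)
        pc1 = coords[:, 0]
        assert (pc1[lab == "HBPC"].mean() - pc1[lab == "LBPC"].mean()) ** 2 > \
            4 * (pc1[lab == "HBPC"].var() + pc1[lab == "LBPC"].var())
        assert frac[0] > frac[1]
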