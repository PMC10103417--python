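import numpy as np
import pandas as pd
import pytest
from scipy import stats

from muscle3d.genome import Gene, GenomeLayout, GenomicInterval
from muscle3d.loops import Loop
from muscle3d.regulatory import (
    AnchorElement,
    build_union_peaks,
    classify_elements,
    differential_counts,
    predict_enhancer_candidates,
    tss_enrichment_score,
    wire_and_census,
)
from muscle3d.simulate import CoverageTrack, SimConfig, make_genes, plant_truth


def iv(s, e, chrom="chr1"):
    return GenomicInterval(chrom, s, e)


def flat_coverage(peaks, value=5.0, baseline=1.0):
    rows = [(p.chrom, p.start, p.end, value) for p in peaks]
    return CoverageTrack(baseline, pd.DataFrame(
        rows, columns=["chrom", "start", "end", "value"]))


class TestUnionPeaks:
    def test_identical_replicates_reproduce_set(self):
        peaks = [iv(100, 200), iv(500, 700)]
        got = build_union_peaks(
            {"c_r1": peaks, "c_r2": list(peaks)},
            {"c_r1": flat_coverage(peaks), "c_r2": flat_coverage(peaks)},
            {"c_r1": "c", "c_r2": "c"},
        )
        assert [(p.interval.start, p.interval.end) for p in got] == \
            [(100, 200), (500, 700)]

    def test_cross_condition_gap_rule(self):
        a = [iv(100, 200)]
        b = [iv(205, 300)]
        got = build_union_peaks(
            {"x_r1": a, "x_r2": a, "y_r1": b, "y_r2": b},
            {s: flat_coverage(p) for s, p in
             [("x_r1", a), ("x_r2", a), ("y_r1", b), ("y_r2", b)]},
            {"x_r1": "x", "x_r2": "x", "y_r1": "y", "y_r2": "y"},
        )
        assert [(p.interval.start, p.interval.end) for p in got] == [(100, 300)]

    def test_inconsistent_replicate_peak_dropped(self):
        got = build_union_peaks(
            {"c_r1": [iv(100, 200), iv(900, 950)], "c_r2": [iv(150, 250)]},
            {"c_r1": flat_coverage([iv(100, 200)]),
             "c_r2": flat_coverage([iv(150, 250)])},
            {"c_r1": "c", "c_r2": "c"},
        )
        assert [(p.interval.start, p.interval.end) for p in got] == [(100, 250)]

    def test_single_replicate_warns(self):
        with pytest.warns(RuntimeWarning):
            build_union_peaks({"c_r1": [iv(0, 10)]},
                              {"c_r1": flat_coverage([iv(0, 10)])},
                              {"c_r1": "c"})

    def test_enrichment_is_signal_minus_background(self):
        # 5 reads/bp inside the peak over a 1 read/bp baseline -> 4, up to
        # the per-million library normalization shared by both terms
        peaks = [iv(100, 200)]
        track = flat_coverage(peaks, value=5.0, baseline=1.0)
        got = build_union_peaks({"c_r1": peaks, "c_r2": peaks},
                                {"c_r1": track, "c_r2": track},
                                {"c_r1": "c", "c_r2": "c"})
        total = 5.0 * 100
        assert got[0].enrichment == pytest.approx(4.0 * 1e6 / total)


class TestTssScore:
    def _genes(self, n=50, spacing=50_000):
        return [Gene(f"g{k}", iv(10_000 + k * spacing, 12_000 + k * spacing),
                     "+") for k in range(n)]

    def _reads(self, positions):
        df = pd.DataFrame({"chrom": "chr1", "start": positions})
        df["end"] = df["start"] + 50
        df["strand"] = "+"
        return df

    def test_uniform_coverage_scores_one(self):
        genes = self._genes()
        rng = np.random.default_rng(0)
        reads = self._reads(rng.integers(0, 50_000 * 51, 200_000))
        assert tss_enrichment_score(reads, genes) == pytest.approx(1.0, abs=0.15)

    def test_tss_spike_scores_tenfold(self):
        genes = self._genes()
        rng = np.random.default_rng(1)
        n_flank, span = 100_000, 50_000 * 51
        flank = rng.integers(0, span, n_flank)
        # the TSS bin spans offsets [-200, 200); add 9x the flat per-bin
        # level there so the expected score is 10
        per_bin = n_flank * 400 / span
        spike = np.concatenate([
            g.tss + rng.integers(-200, 200, round(9 * per_bin)) for g in genes
        ])
        reads = self._reads(np.concatenate([flank, spike]))
        score = tss_enrichment_score(reads, genes)
        assert score == pytest.approx(10.0, rel=0.15)

    def test_zero_reads_scores_zero(self):
        genes = self._genes()
        reads = self._reads(np.array([], dtype=int))
        assert tss_enrichment_score(reads, genes) == 0.0

    def test_no_genes_rejected(self):
        with pytest.raises(ValueError):
            tss_enrichment_score(self._reads(np.array([1])), [])


def enumerate_conditional_p(s1, s2, n1, n2, alpha):
    """Independent oracle: direct enumeration of the conditional NB split."""
    total = s1 + s2
    mu = total / (n1 + n2)
    probs = []
    for k in range(total + 1):
        if alpha <= 1e-12:
            p1 = stats.poisson.pmf(k, n1 * mu)
            p2 = stats.poisson.pmf(total - k, n2 * mu)
        else:
            r1, r2 = n1 / alpha, n2 / alpha
            p1 = stats.nbinom.pmf(k, r1, r1 / (r1 + n1 * mu))
            p2 = stats.nbinom.pmf(total - k, r2, r2 / (r2 + n2 * mu))
        probs.append(p1 * p2)
    probs = np.array(probs)
    probs = probs / probs.sum()
    obs = probs[s1]
    return float(probs[probs <= obs * (1 + 1e-12)].sum())


class TestDifferentialCounts:
    def test_matches_exact_enumeration_oracle(self):
        # single features with tiny counts against the independent oracle
        from muscle3d.regulatory import _nb_exact_pvalue

        for s1, s2, n1, n2, alpha in [
            (0, 5, 3, 3, 0.0), (2, 9, 3, 4, 0.1), (7, 1, 5, 5, 0.3),
            (4, 4, 2, 2, 0.05), (0, 0, 3, 3, 0.1), (12, 3, 4, 2, 0.2),
        ]:
            got = _nb_exact_pvalue(s1, s2, n1, n2, alpha)
            want = enumerate_conditional_p(s1, s2, n1, n2, alpha) \
                if s1 + s2 else 1.0
            assert got == pytest.approx(want, rel=1e-9), (s1, s2, n1, n2, alpha)

    def test_null_type_one_error_in_band(self):
        rng = np.random.default_rng(0)
        n_feat = 2000
        mu = rng.uniform(20, 200, n_feat)
        disp = 0.05
        shape = 1 / disp
        counts = rng.poisson(rng.gamma(shape, mu[:, None] / shape,
                                       (n_feat, 10)))
        res = differential_counts(pd.DataFrame(counts),
                                  ["a"] * 5 + ["b"] * 5, alpha=0.05, mode="p")
        frac = (res.loc[res["tested"], "p_value"] < 0.05).mean()
        assert 0.025 <= frac <= 0.10

    def test_power_at_fourfold(self):
        # 4-fold effects planted in 10% of features; the rest are null so
        # median-of-ratios normalization stays anchored
        rng = np.random.default_rng(1)
        n_feat = 2000
        mu = rng.uniform(50, 200, n_feat)
        disp = 0.05
        shape = 1 / disp
        hit = np.zeros(n_feat, bool)
        hit[rng.choice(n_feat, n_feat // 10, replace=False)] = True
        mu_b = np.where(hit, 4 * mu, mu)
        a = rng.poisson(rng.gamma(shape, mu[:, None] / shape, (n_feat, 5)))
        b = rng.poisson(rng.gamma(shape, mu_b[:, None] / shape, (n_feat, 5)))
        res = differential_counts(pd.DataFrame(np.hstack([a, b])),
                                  ["a"] * 5 + ["b"] * 5, alpha=0.05, mode="q")
        assert res.loc[hit, "significant"].mean() >= 0.8

    def test_all_zero_feature_untested(self):
        counts = pd.DataFrame([[0, 0, 0, 0], [5, 6, 50, 60]])
        res = differential_counts(counts, ["a", "a", "b", "b"])
        assert not res.loc[0, "tested"]
        assert not res.loc[0, "significant"]

    def test_zero_total_group_rejected(self):
        counts = pd.DataFrame([[0, 0, 5, 6]])
        with pytest.raises(ValueError):
            differential_counts(counts, ["a", "a", "b", "b"])


class TestClassification:
    def _peaks(self, spans):
        from muscle3d.regulatory import UnionPeak

        return [UnionPeak(iv(s, e)) for s, e in spans]

    def _gene(self, tss, fpkm=2.0):
        return Gene(f"g{tss}", iv(tss, tss + 1000), "+",
                    {"fetal": fpkm, "adult": fpkm})

    def test_sequential_precedence_p_over_e(self):
        peaks = self._peaks([(9_000, 9_400)])
        genes = [self._gene(10_000)]  # promoter window 7k..13k
        cands = [iv(0, 25_000)]  # peak also inside an enhancer candidate
        classified, _ = classify_elements(peaks, genes, cands, [])
        assert classified[0].cls == "P"

    def test_unexpressed_gene_promoter_not_p(self):
        peaks = self._peaks([(9_000, 9_400)])
        genes = [self._gene(10_000, fpkm=0.0)]
        classified, _ = classify_elements(peaks, genes, [], [])
        assert classified[0].cls == "O"

    def test_anchor_priority_and_n(self):
        peaks = self._peaks([(9_000, 9_400), (9_600, 9_900), (50_000, 50_400)])
        genes = []
        cands = [iv(9_500, 10_000)]  # second peak becomes E, others O
        anchors = [iv(9_000, 10_000), iv(200_000, 210_000)]
        classified, anchor_elems = classify_elements(peaks, genes, cands,
                                                     anchors)
        assert [p.cls for p in classified] == ["O", "E", "O"]
        assert anchor_elems[0].cls == "E"  # E beats O among overlapping peaks
        assert anchor_elems[1].cls == "N"  # no peak at all

    def test_partition_exhaustive_and_disjoint_random(self):
        rng = np.random.default_rng(2)
        for _ in range(100):
            n = int(rng.integers(1, 40))
            starts = np.sort(rng.choice(10_000, n, replace=False)) * 100
            peaks = self._peaks([(s, s + 80) for s in starts])
            genes = [self._gene(int(t))
                     for t in rng.choice(1_000_000, 5, replace=False)]
            cands = [iv(int(c) * 100, int(c) * 100 + 5_000)
                     for c in rng.choice(9_000, 3, replace=False)]
            classified, _ = classify_elements(peaks, genes, cands, [])
            assert all(p.cls in ("P", "E", "O") for p in classified)
            assert len(classified) == n


class TestWireAndCensus:
    def _setup(self):
        res = 10_000
        lp = Loop(iv(100_000, 110_000), iv(500_000, 510_000), res, 5, 1)
        lp2 = Loop(iv(800_000, 810_000), iv(1_200_000, 1_210_000), res, 5, 1)
        anchors = [
            AnchorElement(lp.anchor1, "P"),
            AnchorElement(lp.anchor2, "E"),
            AnchorElement(lp2.anchor1, "N"),
            AnchorElement(lp2.anchor2, "N"),
        ]
        gene = Gene("target", iv(102_000, 103_000), "+", {"fetal": 3.0})
        return [lp, lp2], anchors, [gene]

    def test_pair_labels_and_wiring(self):
        loops, anchors, genes = self._setup()
        pairs, census = wire_and_census(loops, anchors, genes, "fetal")
        assert pairs["class_pair"].tolist() == ["E-P", "N-N"]
        assert pairs.loc[0, "gene_ids"] == "target"
        assert pairs.loc[1, "gene_ids"] == ""
        assert census["count"].sum() == len(loops)

    def test_unordered_census(self):
        loops, anchors, genes = self._setup()
        # swap classes: E on anchor1, P on anchor2 -> still an E-P row
        anchors[0].cls, anchors[1].cls = "E", "P"
        pairs, census = wire_and_census(loops, anchors, genes, "fetal")
        assert "E-P" in census["class_pair"].tolist()

    def test_unknown_anchor_rejected(self):
        loops, anchors, genes = self._setup()
        with pytest.raises(KeyError):
            wire_and_census(loops, anchors[:1], genes, "fetal")


class TestEnhancerCandidates:
    def test_no_tads_warns_and_empty(self):
        from muscle3d.hic import ContactMatrix
        import scipy.sparse as sp
        from muscle3d.tads import TadSet

        lay = GenomeLayout({"chr1": 1_000_000})
        m = ContactMatrix(lay, 25_000, {"chr1": sp.csr_matrix((40, 40))})
        with pytest.warns(RuntimeWarning):
            got = predict_enhancer_candidates(m, TadSet(40_000, [], [], []),
                                              [])
        assert got == []

    def test_uniform_decay_no_candidates_and_outside_tad_never(self):
        import scipy.sparse as sp
        from muscle3d.hic import ContactMatrix
        from muscle3d.tads import TadSet

        n, res = 200, 25_000
        d = np.abs(np.arange(n)[:, None] - np.arange(n)[None, :])
        rng = np.random.default_rng(3)
        lam = 400 * (d + 1.0) ** -1.0
        lam[40, 100] *= 5
        lam[100, 40] *= 5
        lam[40, 150] *= 5  # enriched but outside the TAD
        lam[150, 40] *= 5
        dense = np.triu(rng.poisson(lam)).astype(float)
        dense = dense + dense.T - np.diag(np.diag(dense))
        lay = GenomeLayout({"chr1": n * res})
        m = ContactMatrix(lay, res, {"chr1": sp.csr_matrix(dense)})
        m.weights = {"chr1": np.ones(n)}
        tads = TadSet(40_000, [GenomicInterval("chr1", 30 * res, 120 * res)],
                      [], [])
        proms = [iv(40 * res + 10_000, 40 * res + 12_000)]
        got = predict_enhancer_candidates(m, tads, proms)
        bins = {g.start // res for g in got}
        assert 100 in bins  # planted within-TAD enrichment found
        assert 150 not in bins  # outside every TAD: never emitted
        # uniform-decay control: nothing else called
        assert bins <= {99, 100, 101}
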