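# Methods and design notes

This note documents the models behind each stage, the parameters that
matter, what the synthetic generator does and does not emulate, and the
design choices made where the design was genuinely open. Nothing here
states an empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Coordinates and formats

All coordinates are 0-based, half-open internally (BED-native); VCF
positions are converted from 1-based on read, and regions are rendered
1-based inclusive for display. Chromosome names are matched by exact
string equality — no "chr" prefix normalization is attempted, a mismatch
between query and subject namespaces raises. "Merge peaks with overlap
≤ 10 bp" is implemented as the `bedtools merge -d 10` gap rule: intervals
merge when separated by at most the gap, including book-ended ones.

## Synthetic data: what it emulates

The generator is the package's study design: a two-stage (fetal vs adult)
muscle multi-omic experiment scaled down to a 2 × 20 Mb genome. Every
generator is a pure function of `(SimConfig, rng_seed)`; each one draws
from an independent stream seeded as `hash(seed, generator-name)` so
modules can be regenerated independently.

- **Hi-C.** Cis pair intensity at the finest resolution (10 kb) is
  `(d+1·bin)^γ` (γ = −1 by default) modulated by a planted compartment
  checkerboard (same-label bins × 1.6), a uniform within-TAD multiplier
  (× 3), and single-pixel loops (× 8). The structure factor (not the decay
  itself) is Sinkhorn-equalized so per-locus visibility is near-uniform —
  real contact maps have this property, and it is ICE's premise; chromosome
  ends keep their natural truncated-decay profile. Counts are Poisson;
  trans pairs are uniform. Default depth is 8 M pairs (20% trans),
  ~0.3 cis pairs per bp — the per-bp depth of a deeply sequenced tissue
  Hi-C study on a full genome. `expected_matrix` exposes the noise-free
  Poisson-mean surface for noise-free benchmarking, and `sample_matrix`
  draws counts directly without the pair-text round trip.
- **Compartments.** Alternating A/B blocks of 2–5 Mb; the adult condition
  flips ~25% of blocks, drawn from both labels, with guards keeping every
  chromosome an alternating mosaic (≥ 4 runs, both labels ≥ 15% of bins)
  and guaranteeing at least one A→B and one B→A transition genome-wide.
  An eigenvector cannot resolve a chromosome that is a single A block and
  a single B block; the guard encodes the biological observation that the
  two forms alternate along chromosomes.
- **TADs.** 0.8–2.4 Mb domains at 40 kb granularity separated by 80–320 kb
  gaps (boundaries) or occasionally 0.5–1 Mb gaps (unorganized). A
  fraction of domains is split in one condition by an internal 80 kb gap
  (the planted ucTAD/spTAD relations).
- **Loops.** Gene-centric: a promoter anchor wired to 1–3 enhancer anchors
  ≥ 200 kb away within one TAD; 20% of loops instead join two gene
  promoters (P-P, giving co-anchored gene pairs); 30% are planted in only
  one condition. Loops are placed preferentially in TADs lying in A
  compartments (weights 0.1 + 0.9·fracA), as active loops are in tissue.
- **Genes/expression.** 400 genes: promoter-anchor genes (planted
  category C), genes inside loop spans (B), and background genes placed
  with A-compartment bias (gene-dense open chromatin — this is also what
  lets gene density orient PC1). log2 mean FPKM = base + α·[compartment A]
  + β·(looped enhancers) + gene effect, α = 1, β = 0.5, NB-replicated
  counts. Setting α = β = 0 gives an exact null used for calibration.
- **ATAC.** Peaks at TSSs (~30% of the catalog), at planted enhancer
  anchors, and at random background; two replicates jittered ≤ 20 bp;
  NB counts with 4-fold changes planted in 20% of peaks (DAR truth);
  coverage is a flat baseline plus per-peak per-base rates, with
  signal-to-noise 8.
- **Genotypes.** 60 + 26 diploid samples (a high- vs low-production panel
  design), 20 k SNPs with shared background frequencies and five planted
  50 kb windows with symmetric divergence around 0.5 targeting Fst = 0.8
  (Fst = 1 gives alternately fixed differences); Hardy–Weinberg sampling
  within population.

What the generator does **not** emulate: restriction-fragment geometry and
ligation artifacts, read-level noise (alignment, duplicates), distance-
dependent loop "flares", linkage disequilibrium, mappability or GC biases.
Passing tests therefore demonstrate algorithmic correctness and
calibration under idealized noise, not robustness to every artifact of
real libraries.

## Hi-C core

ICE is the classic iterative row-sum correction: per chromosome, bins in
the lowest 2% of coverage (and empty bins) are masked, then weights are
updated by `w ← w / sqrt(rowsum/mean)` until the maximum relative row-sum
deviation is below 1e-4 (≤ 200 iterations; non-convergence warns and
flags the matrix). Matrix correlation is Pearson over the union of
non-zero, unmasked cells of the balanced matrices. The decay curve uses
raw counts normalized per bin-pair count and total cis pairs, averaged in
log-spaced distance bins, with an OLS log-log fit over 80 kb–8 Mb
(configurable; the fit window is a convention, not a measurement).
Resolution capability aggregates per-bin total pairs exactly from a finer
matrix and returns the smallest candidate with ≥ 80% of bins ≥ 1000 pairs.

## Compartments

The sign of an eigenvector is arbitrary, so orientation is explicit: PC1
is flipped per chromosome so its correlation with an activity track is
positive. Chromosomes with < 4 usable bins are masked wholesale. Gene →
bin assignment is by TSS; the stage comparison uses a two-sided Wilcoxon
signed-rank test pairing each gene's FPKM across stages (the paired
variant was chosen because the same genes are measured in both stages).

## TADs

The DI HMM uses anchored Gaussian emissions on the variance-stabilized
statistic `sign(DI)·log(1+|DI|)`, standardized: means fixed at
(−2, 0, +2) and variances at (0.5, 0.1, 0.5); EM fits only the start and
transition probabilities. Anchoring prevents the degenerate solutions a
free 3-Gaussian fit finds on heavy-tailed DI (a point-mass middle state,
or a wide state swallowing both tails, which breaks the state↔bias
mapping); it also makes confidently biased bins decode with posteriors
near 1 so the 0.99 threshold is meaningful. The "median probability 0.99
/ minimal size 2" pair is interpreted as: a domain is kept when the median
posterior over its *biased* runs (the DownstreamBias run opening it and
the UpstreamBias run closing it) is ≥ 0.99 and both runs span ≥ 2 bins —
interior NoBias bins are legitimately soft and are not counted against
the domain. On clean planted data this filter is what removes phantom
domains arising in long unorganized gaps. DI uses balanced counts by
default (raw by flag). Boundary comparison matches boundary midpoints
within ± 1 bin; the spTAD thresholds (containment 0.8, coverage 0.8 of
the ucTAD) are package conventions.

## Loops

The expectation model follows the distance-stratified philosophy: an
isotonic-decreasing fit of the mean bias-normalized count per distance,
with per-bin biases estimated iteratively as each bin's mean ratio to the
distance profile (three alternations, two outlier-removal refinement
passes). Estimating biases against the distance profile rather than raw
coverage matters at chromosome ends, where total coverage is low for
geometric reasons but short-range contacts are normal — a coverage-based
bias would systematically undershoot there and flood the Poisson test
with false calls. Candidate loops must (i) be BH-significant against the
global expectation, (ii) exceed fold thresholds (1.75 donut/lower-left,
1.5 stripes) against each local neighborhood, with pixels within w bins
of the diagonal skipped because their background windows would cross it,
and (iii) pass a Poisson test against the *weakest* local neighborhood,
BH-corrected against the full number of tested cells — the candidates
were selected from that search space, so correcting only across
candidates would be anti-conservative. Loops found at several resolutions
merge by anchor overlap keeping the finer coordinates. Stage-specific
loops are those whose pixel is not significantly enriched over the other
matrix's local expectation (a presence/absence rule standing in for a
dedicated differential caller). APA windows exclude loops within w bins
of the diagonal or matrix edge; loop length is measured midpoint to
midpoint.

## Regulatory elements and differential counts

Replicate consistency is a simple ≥ 1 bp-overlap-in-both-replicates
filter (a reproducibility-model step such as IDR is deliberately out of
scope). The enhancer predictor mirrors the within-TAD
promoter–enhancer-interaction idea: for each TAD, a local isotonic
distance profile of bias-normalized counts is fitted from the TAD's own
cells, and each promoter-bin × other-bin cell is Poisson-tested against
it (BH across all tested pairs, candidates must also exceed 1.5× their
expectation; cells closer than 3 bins are not tested, because the
steepest part of the decay cannot be fitted tightly enough for the large
counts there). Cells outside every TAD are never tested, so candidates
never fall outside TADs. Anchor classification priority P > E > O is a
package convention for multi-peak anchors. The enrichment value of a
union peak is per-base signal minus per-base background (the track's
baseline — median coverage outside peaks), each normalized per million
track reads.

`differential_counts` is a conditional exact negative-binomial test:
median-of-ratios size factors, one pooled method-of-moments dispersion
(median of per-feature `(var−mean)/mean²`), and for each feature the
two-sided exact p-value of the observed split of the normalized group
sums, computed by enumerating the conditional distribution (group sums of
i.i.d. NB(μ, α) samples are NB with size n/α). A Wald fallback handles
features whose totals exceed 50 k. Accessibility calls use raw p < 0.05;
expression calls use BH q < 0.05, matching the two conventions'
thresholds.

## Sweep scan

Weir–Cockerham (1984) per-site components for two populations of
diploids; negative components are retained in the window sums, so window
Fst can be slightly negative (the standard ratio-of-sums estimator).
Windows need ≥ 1 usable site; ZFst standardizes over all such windows and
a zero-variance scan raises. Sweep regions merge overlapping or
book-ended qualifying windows (the 5 kb step makes qualifying runs
overlap). Genotype PCA is a diagnostic eigen-decomposition of the
centered dosage covariance. Enrichment uses a 10 kb-bin universe, one
2 × 2 Fisher's exact per element class, BH across classes.

## Pipeline scale and determinism

The default end-to-end run (2 × 20 Mb, 8 M pairs, 400 genes, 20 k SNPs)
completes in a few minutes on one CPU; these sizes are the package's
benchmark conditions, chosen so that per-bp sequencing depth matches a
deep tissue study while the whole analysis stays interactive. All stages
are deterministic given the seed: reruns produce bit-identical artifacts,
recorded via a manifest with the seed and a configuration hash.

## Known limitations

- The HMM emission anchors are tuned for DI's signed-log scale; matrices
  with radically different depth may prefer re-anchoring (the emission
  family is pluggable).
- Single-pixel planted loops at 10 kb dilute ~2.2× when aggregated into
  25 kb enhancer-prediction bins, and pixels straddling bin edges dilute
  further, so enhancer-candidate recovery of planted anchors is partial
  by construction (the pipeline pools candidates over both stages into
  one element catalog, which recovers part of the loss).
- The differential-loop rule is presence/absence, not a joint test; weak
  shared loops near the detection threshold can be miscalled specific.
- With two ~20-bin chromosomes at 1 Mb, compartment calling operates near
  the minimum scale at which PC1 is meaningful; per-chromosome agreement
  a bin or two below 100% is expected at adverse flips.
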