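# Methods

This note documents the models, defaults, numerical choices and known
limitations behind each maturekit stage, in the spirit of a statistical
methods appendix. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Count model and normalization

Bulk counts are treated as negative binomial with the mean/dispersion
parameterization `var = mu + phi * mu^2` and a single common `phi` per
contrast. Size factors use the median-of-ratios estimator: the per-gene
reference is the geometric mean across samples, restricted to genes with a
nonzero count in every sample (the standard convention; genes with any zero
have an undefined log geometric mean). The median is taken on the ratio
scale, not the log scale — for an even number of reference genes these
differ (arithmetic vs geometric mean of the two middle ratios) and the
ratio-scale median is the estimator the field's tools compute. A
consequence worth knowing: scaling one sample's counts by `c` shifts every
gene's geometric mean by `c^(1/n)`, so all normalized values rescale by the
same global constant while relative expression is exactly preserved; the
test suite asserts this identity rather than a literal "unchanged".

The expressed-gene filter keeps genes with CPM ≥ threshold (default 5,
inclusive) in **all** replicates of at least one (condition, timepoint)
group. One filter is computed over all loaded conditions by default, with
the scope reducible via the `scope` argument.

## Differential test

The two-group test is an exact conditional NB test. Normalized counts are
summed within each group and rounded to integers; the sum of `n` i.i.d.
NB(mu, phi) variables is NB with size `n/phi`, so conditional on the total
`s = s_a + s_b`, the group-A sum follows a beta-binomial(s, n_a/phi,
n_b/phi) law that does not involve `mu`. The two-sided p-value is the total
conditional probability of outcomes whose probability does not exceed the
observed one — the same convention as the binomial exact test, which is
exactly the `phi -> 0` limit (asserted against `scipy.stats.binomtest` in
the suite). For totals above 50,000 a normal approximation with continuity
correction replaces the enumeration; p-values at that scale are far beyond
any calling threshold and the approximation error is immaterial.

The common dispersion is estimated by the method of moments: per-gene
pooled within-group variance, `phi_g = (var - mean) / mean^2`, averaged
over genes with positive mean and clipped below at 1e-8. Negative per-gene
estimates are deliberately not clipped before averaging, keeping the
estimator approximately unbiased. Tagwise (empirical-Bayes shrunk)
dispersions are out of scope; with thousands of genes the common estimate
is tight, and the suite verifies calibration directly: at p < 0.001 on a
2000-gene null (mean 200, phi 0.05, 3 vs 3) the rejection rate stays within
three binomial standard deviations of nominal, and power at 4-fold effects
under the same conditions exceeds 0.9.

Reported log2 fold changes use a pseudocount of 0.5 normalized units on the
group means; the p-value comes from the exact test, never from the
pseudocounted ratio. Calls use p < 0.001 strictly and |lfc| ≥ 1
inclusively (fold change "at least 2"). Genes with zero counts in both
groups are reported stable with p = 1.

## PCA

Genes with more than `min_reads` (default 10, strict) normalized units in
at least one sample are kept, transformed as log2(x + 1), and per-gene
mean-centered and scaled to unit variance (population SD); constant genes
are dropped. Samples are then projected with a full-SVD PCA and percent
variance per component is reported.

## Synthetic data

The generator exists to give every downstream stage inputs with known
truth; its defaults describe the study design it emulates:

- 7 ordered timepoints (E10.5 … 2 years), 3 replicates each, with
  per-transition dynamic fractions (0.4, 0.4, 0.2, 0.1, 0.01, 0.01) —
  strongly dynamic embryonically, nearly frozen after the third postnatal
  week. Default 2000 genes keeps desk-scale runs fast while leaving
  thousands of stable genes for the normalization reference.
- effect size 2.0 log2 units (4-fold), comfortably above the 2-fold calling
  threshold; base means log-uniform between 2^5 and 2^10 counts; dispersion
  0.05; library-size factors log-normal with CV 0.1 and unit mean.
- dynamic genes are assigned by exact counts `floor(fraction * n)`
  (half up, half down), not per-gene coin flips, so truth tallies are
  deterministic; the paired ("in vitro") series assigns exactly
  `floor(shared_frac * n_dynamic)` genes the same-direction net effect,
  spread evenly over its transitions.
- single-cell references draw class archetypes as independent log-normal
  profiles and perturb them per cluster so the expected within-class
  archetype correlation equals the configured value; cells are NB samples
  around the archetype with a log-normal depth factor.
- peak universes place fixed-width (200 bp) non-overlapping peaks by
  rejection sampling with a retry cap; exact counts of peaks are dropped
  and added per transition, and added peaks avoid **all** earlier peaks so
  whole-feature subtraction recovers the truth exactly. Proximal peaks are
  placed with midpoints within 2 kb of a sampled TSS.

What the generator does not emulate: per-gene dispersion variation, GC or
length bias, scRNA-seq dropout or ambient RNA, realistic genome sequence,
replicate-level peak noise, or correlated gene programs. Passing tests
therefore demonstrate correctness of the algorithms under the stated
stochastic model, not robustness to every artifact of real libraries.

## Deconvolution

Stage 1: downsample every cluster to the smallest cluster's size (seeded,
without replacement — the seed is a required, logged parameter), scale each
cell to the median depth, log1p, average within clusters, merge clusters
into classes, and fit the bulk profile by NNLS. Stage 2 repeats everything
on cholinergic-flagged clusters only, including recomputing the
top-variance gene subset within the stage.

Merging computes Pearson correlations between cluster profiles on the 1000
highest-variance genes and runs average-linkage hierarchical clustering on
distance 1 − r; the tree is cut at the coarsest level at which every
multi-member class keeps mean within-class pairwise correlation at or above
the threshold (default 0.8 — "highly correlated" has no canonical numeric
value, so the threshold is mandatory in run reports). All singletons always
satisfy the constraint, so a valid cut exists.

The fit runs in log space on the mean-log profiles; `linear_space=True`
exponentiates profiles first (expm1). Log space is the default because the
class profiles are defined as mean log expression and the bulk profile is
supplied on the same scale; the choice is surfaced as an option rather than
hidden. Proportions are `100 * w / sum(w)`; an all-zero solution is
flagged degenerate. Recovery is verified on seeded mixtures (4 classes,
2000 genes, noise ≤ 5% of signal): mean absolute proportion error stays
under 2 percentage points over 100 mixtures, and classes absent from a
mixture receive near-zero weight.

## Concordance

Category assignment reuses the DE calls (fold ≥ 2, p < 0.001) by default;
`quadrant_mode="lfc-only"` with a configurable cut reproduces the simpler
quadrant accounting used for perturbation scatters. Recapitulation percents
divide shared genes by all Y-dynamic genes of that direction **including**
opposite-regulated ones; the variant excluding them is also emitted since
the denominators differ only by the (usually small) opposite set. Genes
tested in one contrast but missing from the other are excluded by inner
join. Display percents round to the nearest integer; files keep full
precision.

## Peak operations

BED convention throughout: 0-based, half-open, enforced at parse time.
Overlap means at least one shared base and subtraction removes whole
features. "Most significant" ranks by the BED score column descending with
(chrom, start) tie-breaks for determinism. Peak-to-TSS distance is measured
from the peak midpoint, and proximal means distance ≤ 2000 bp (2000 is
proximal, 2001 distal). The gene-association window for per-gene peak
counts defaults to 50 kb and is mandatory in run reports, since no single
canonical window exists. Conservation averaging compares region means
against a seeded random background (default 49,896 intervals of 2 kb)
drawn uniformly from chromosomes that can hold them; uncovered bases score
0 by convention.

## Pipeline and provenance

Every written table starts with a `#`-prefixed provenance block (tool
version, seed, config hash); stripping comments yields clean TSV.
Timestamps are deliberately omitted so that reruns with identical inputs
and config are byte-identical. Missing inputs are enumerated before any
computation starts, and a stage failure leaves earlier artifacts intact.

## Problem sizes used in the checks

The packaged verification runs use 400–2000 genes, 3–7 timepoints with 3
replicates, references of 8 clusters × 30 cells × 2000 genes, and peak
universes of 300–1000 intervals — sizes chosen so the full suite and the
acceptance script each complete in well under a minute on one CPU while
keeping Monte-Carlo error small relative to the tolerances tested.

## Known limitations

- Common (not tagwise) dispersion; no GLM designs, batch correction, or
  FDR machinery (the calling thresholds here are raw-p based).
- Deconvolution assumes the reference classes span the bulk signal;
  signature-gene selection (CIBERSORT-style) is out of scope.
- Effector categorization is substring matching on free-text descriptions
  (case-insensitive, except the case-sensitive `Col` symbol prefix); it is
  deterministic but inherits any quirks of the catalog text. Whole-word
  tokenization was considered and rejected in favor of substrings for
  simplicity; the distinction only matters for words embedded in longer
  tokens.
- Interval operations are exact but assume peak sets fit in memory; no
  streaming/indexed (tabix-style) backend.
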