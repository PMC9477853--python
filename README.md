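# maturekit

Analysis toolkit for neuronal maturation time courses: bulk RNA-seq
normalization and differential calling across ordered developmental
timepoints, two-stage NNLS deconvolution of bulk profiles against clustered
single-cell references, in vivo / in vitro fold-change concordance
classification, rule-based effector-gene categorization, and interval-based
chromatin accessibility (peak set) dynamics — plus a seeded synthetic-data
generator so every stage can be exercised with known ground truth.

## The problem

Neurons born in the embryo keep changing their transcriptome for weeks:
spinal motor neurons in the mouse are specified around E10.5 but their gene
expression and chromatin accessibility keep shifting until about the third
postnatal week, after which they are remarkably stable. Quantifying that
maturation program — which genes move at which transition, which parts of
it a stem-cell-derived culture recapitulates, and which regulatory regions
open or close alongside it — requires a small set of bespoke computational
steps that this package implements as a tested, reusable library with a CLI.

## Methods at the core

- **Median-of-ratios normalization.** Size factor of sample *j* is
  `median_g( K_gj / (prod_j K_gj)^(1/n) )` over genes observed in every
  sample; normalized expression is `K_gj / s_j`.
- **NB exact test.** For a two-group contrast, counts are modeled as
  negative binomial with `var = mu + phi mu^2` and a common
  method-of-moments dispersion `phi`. The test conditions each gene's group
  sums on their total: the conditional law is beta-binomial and free of
  `mu`, and the two-sided p-value sums all conditional outcomes no more
  likely than the observed one (the binomial exact test is the `phi -> 0`
  limit). Genes are called up/down at fold change ≥ 2 and p < 0.001 by
  default.
- **Two-stage NNLS deconvolution.** Clusters of a labeled single-cell
  reference are balanced by downsampling, summarized as mean log profiles,
  merged into transcriptional classes by average-linkage clustering on
  correlation distance (top-1000-variance genes), and the bulk profile is
  fit as `argmin ||b - P^T w||, w >= 0`; the fit is repeated on
  cholinergic-flagged clusters only.
- **Concordance classification.** Genes tested in two contrasts (e.g.
  DIV0→DIV28 in vitro vs E10.5→P21 in vivo) fall into shared / opposite /
  X-specific / Y-specific / stable categories; the shared genes form the
  "core" program and recapitulation percents are reported per direction.
- **Peak set algebra.** Top-N selection by score, blacklist exclusion,
  gained/lost peaks by whole-feature subtraction (≥ 1 bp overlap),
  proximal/distal classification at 2 kb from the nearest TSS, per-gene
  peak counts with Welch t-tests, and mean conservation over regions vs a
  random genomic background.

## Worked example

Simulate a three-timepoint in vivo series with a paired culture series in
which 40% of upregulated and 30% of downregulated genes recapitulate, plus
a peak universe with 20% turnover, and run the pipeline:

```bash
cat > tc.yaml <<EOF
n_genes: 500
timepoints: [E10.5, E13.5, P21]
dynamic_fraction_per_transition: [0.3, 0.2]
EOF
maturekit simulate timecourse --config tc.yaml --seed 7 --outdir sim \
    --paired --shared-up-frac 0.4 --shared-down-frac 0.3

printf 'chr1\t2000000\nchr2\t1500000\n' > chrom.sizes
maturekit simulate peaks --chrom-sizes chrom.sizes --tss tss.tsv \
    --timepoints t0,t1,t2 --n-peaks 400 --seed 3 --outdir pk

cat > run.yaml <<EOF
counts: sim/counts.tsv
metadata: sim/metadata.tsv
outdir: out
seed: 5
thresholds: {top_n: 400}
concordance: {x_condition: in_vitro, y_condition: in_vivo}
peaks:
  beds: {t0: pk/peaks_t0.bed, t1: pk/peaks_t1.bed, t2: pk/peaks_t2.bed}
  order: [t0, t1, t2]
  tss: tss.tsv
EOF
maturekit run --config run.yaml
```

`out/summary.json` then contains (among other stages):

```
recap_up_pct   39.6   # configured truth: 40% of up genes recapitulated
recap_down_pct 29.1   # configured truth: 30%
pct_gained     20.0   # configured truth: 20% peak turnover, recovered exactly
pct_lost       20.0
gained_pct_distal 95.0
```

The recapitulation percents land within the differential test's power
envelope of the configured fractions, and the interval results are exact
because peaks carry no noise.

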