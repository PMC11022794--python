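# Methods

## The problem

Seed colour in quinoa (and categorical traits in crops generally) is a
multi-locus phenotype: no single variant predicts it, but combinations of
SNPs do.  `boostsel` implements a consensus feature-selection workflow for
this setting: many gradient-boosted multi-class classifiers are trained on
random stratified train/test splits of a samples x SNPs dosage matrix, and
the SNPs that repeatedly carry positive gain importance across replicate
models form a consensus set of candidate variants.  The package also
implements the classical comparisons around that core — a univariate
linear-mixed-model (LMM) Wald GWAS, PCA/LDA ordination, hierarchical
clustering of genotypes, and SNP-to-gene flanking annotation — plus a
synthetic cohort generator with planted causal SNPs so the whole chain can
be validated end to end.

## Genotype encoding and filters

Variants are read from VCF and encoded as alternate-allele dosage: 0
homozygous reference, 1 heterozygous, 2 homozygous alternate, -1 missing
(the vcftools 012 dialect; `write_012`/`read_012` round-trip it exactly).
Site-level hard filters follow GATK-style conventions (MQ > 30,
MLEAF > 0.01, 300 < DP < 1500 as per-site totals, FS < 60, |MQRankSum| <=
12.5, |ReadPosRankSum| <= 8, |BaseQRankSum| <= 12.5, biallelic only,
missing-call fraction <= 0.1).  A site lacking an annotation passes that
single criterion — filters constrain only what the caller emitted.  Minor
allele frequency is computed over called genotypes only; sites with no
calls are removed.

## The boosted ensemble

One replicate = one stratified split + an independent hyperparameter
search + one fitted model:

- **Splits.** Per-class test counts come from largest-remainder
  apportionment of `n_test` (ties broken by class order), so a 45:27:23
  cohort with 24 held out always yields test supports 11/7/6 and train
  counts 34/20/17.  Membership within a class is uniform given the seed.
- **Weights.** Balanced class weights `w_c = n/(k * n_c)` equalize each
  class's total weight, counteracting the cohort imbalance.
- **Tuning.** A seeded random search over max_depth in [2, 10],
  min_child_weight in [0, 10], gamma in [0, 5], colsample_bytree in
  [0.3, 1], subsample in [0.5, 1] and log-uniform learning_rate in
  [0.01, 0.3].  Each trial is scored by mean k-fold cross-validated
  one-vs-rest macro AUC with early stopping (35 rounds patience on
  validation multi-class log-loss) inside every fold; the winning
  configuration's boosting-round count is the mean early-stopped round
  across folds, and the final model trains exactly that many rounds on
  the full training side.  This keeps the procedure fully reproducible
  from its seed — a property a Bayesian optimizer does not provide.
- **Importance.** Total gain per feature from the fitted booster; only
  strictly positive entries are kept.  Missing dosages enter the trees
  as NaN and are routed by the learner's default-direction mechanism.

The consensus set collects SNPs with positive gain in at least
`min_models` of the replicates (full-scale defaults 9 of 100).  It is
then expanded with collinear SNPs: any non-selected site whose genotype
column has |Pearson r| >= 0.97 with a selected anchor joins the combined
set (pairwise-complete over called genotypes, at least 10 shared
samples; constant columns never match; expansion is anchored on selected
sites only, not transitive).  Absolute correlation is the default since
allele coding makes the sign arbitrary; `signed=True` is available.
Retraining the identical replicate seeds on the column-restricted matrix
quantifies the noise-removal improvement.

## Mixed-model GWAS baseline

For each unordered pair of classes, per-SNP LMMs

    y = 1*alpha + x*beta + u + eps,  u ~ N(0, sg2*K),  eps ~ N(0, se2*I)

are fitted on the pair's samples with the centred relatedness matrix
K = (1/p) sum_j c_j c_j' recomputed on that subset (missing dosages
imputed to site means).  K is eigendecomposed once; the variance ratio
delta = se2/sg2 is estimated per site by REML over 60 log-spaced grid
points in [1e-5, 1e5] with bounded local refinement, and the Wald
statistic (beta/se)^2 is referred to chi-square(1).  With K = I the fit
reduces exactly to OLS; the implementation is verified against a
brute-force full-covariance likelihood search and against the uniform
null distribution of p-values.  Significance uses a fixed genome-wide
threshold (default 1e-8) rather than alpha/m recomputation, matching the
common reporting convention for Bonferroni-style control.

## Ordination and structure check

PCA operates on mean-imputed, column-centred dosages (deterministic SVD;
axis signs fixed by making each axis's largest-|loading| positive).  LDA
is a Fisher discriminant with ridge `1e-6 * trace(Sw)/d` on the
within-class scatter because the SNP count typically dwarfs the sample
count.  Class separation in a projection is scored by the mean
silhouette (singleton classes and degenerate geometry contribute 0).

The population-structure check appends the top 10 PC coordinates as
extra features and re-runs the ensemble.  PC coordinates are continuous
and therefore collect small chance gains in almost every tree model, so
a PC counts as "important" in a replicate only when it captures at least
5% of that replicate's total gain (`pc_gain_share_min`); with that
criterion structure-driven phenotypes put 10-40% of the gain on PCs
while SNP-driven phenotypes leave them below 3%.  The run is flagged
confounded when any PC reaches `min_models` replicates.

Genotype heatmaps use average-linkage hierarchical clustering with
Euclidean distance on imputed dosages, for both samples and sites.

## The synthetic cohort generator

Genotypes follow the Balding-Nichols model: ancestral frequency
p_j ~ Uniform(0.1, 0.9), subpopulation frequency Beta(p(1-F)/F,
(1-p)(1-F)/F) at F = 0.05 across 3 subpopulations, dosage
Binomial(2, subpop frequency).  LD is intra-block template copying:
within each block of 5 consecutive sites, sites 2..5 copy site 1's
column with a 1% per-entry re-draw, giving |r| ~ 0.98-0.99 proxies
without simulating recombination.  2% of entries are set missing.

Phenotypes come from a multinomial-logit liability over 8 causal SNPs,
`score_c = intercept_c + sum_j effects[c][j] * dosage_j` with missing
dosages counted as 0 (missingness must not leak labels); labels are the
argmax by default.  Design choices behind the defaults:

- Causal sites sit at LD-block template positions with their ancestral
  frequency pinned to 0.5.  Templates propagate into their block, so
  every causal SNP has collinear proxies (as in real LD), and the fixed
  frequency keeps the liability-score distribution — hence the class
  proportions — stable across seeds.
- The white class is the zero-effect reference; beige and orange each
  load on four causal SNPs with signed mixed-magnitude effects
  (±2.0, ±1.2) so scores live on a fine lattice, and the intercepts
  (1.2, 0.1, 0.0) were solved by exact enumeration of the dosage
  distribution to give approximately the 45:27:23 white:beige:orange
  imbalance of the motivating cohort (realized proportions vary a few
  percent with the structure draw).

What the generator does *not* emulate: realistic recombination maps and
LD decay, allele-frequency spectra from demography, genotype-calling
error structure, linked selection, or any pleiotropy between structure
and phenotype.  Passing tests on this generator therefore demonstrate
that the machinery recovers planted multi-SNP signal under mild
structure and LD — not that it would resolve causal variants in any
particular real cohort.

## Desk-scale defaults and runtime

The full-scale configuration (100 replicates, consensus threshold 9,
250 search trials, 4-fold CV) mirrors the motivating study and is the
`EnsembleConfig` default.  The demo configuration
(`pipeline.demo_ensemble_config`) runs 25 replicates with threshold 3 on
the 300 x 5000 cohort, with 6 search trials per replicate scored by
2-fold CV and boosting capped at 60 rounds; this completes in roughly
6-9 minutes on one CPU core and recovers >= 6 of the 8 planted causal
SNPs in the combined consensus set while the consensus-restricted
retraining strictly improves mean ensemble accuracy and AUC.

## Numerical conventions

- Missing sentinel: -1 in memory and on disk; NaN only at the boosting
  and imputation boundaries.
- Largest-remainder ties break by class order; all random draws descend
  from explicit integer seeds (replicate r of an ensemble uses split
  seed `base_seed + r` and a tuning seed derived via SeedSequence).
- Pearson correlations for collinearity use pairwise-complete
  observations with a 10-shared-sample minimum.
- PCA on very wide matrices may subsample sites (default cap 200 000,
  seeded; the cap is recorded in the axis labels).
- LMM delta grid [1e-5, 1e5] with 60 points + bounded refinement; REML
  scale estimates; zero-variance sites are skipped with a recorded
  reason.

## Known limitations

- **Null behaviour of the consensus rule.**  Replicate models share ~80%
  of the cohort, so a SNP whose genotypes correlate with the labels at
  cohort level — even by pure chance — tends to recur across replicates.
  With a desk-scale site pool (thousands of sites), label-free cohorts
  still yield tens of sites at `min_models = 3` of 10 replicates; the
  resampled-split consensus controls split-specific noise, not
  cohort-level chance association.  Selectivity improves with the
  pool-to-model-size ratio (the motivating regime is ~120 used features
  out of 3.9 million sites) and with higher `min_models`.  Treat the
  consensus as candidate ranking, not an error-controlled selection.
- In-sample LDA separates any labelling perfectly once the feature count
  approaches the sample count (singular within-class scatter); judge
  feature sets by comparative or held-out separation
  (`Projection.transform`), not by the absolute in-sample silhouette.
- The LMM treats a binary class contrast as a Gaussian response, as is
  conventional for case-control GWAS at these sample sizes.
- Hyperparameter search is random, not adaptive; with a small trial
  budget the per-replicate optimum is noisy (by design, each replicate
  searches independently).
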