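# boostsel

Consensus SNP selection for categorical plant phenotypes with ensembles of
gradient-boosted classifiers — plus the classical baselines needed to judge
the result: a linear-mixed-model GWAS, PCA/LDA ordination, genotype
clustering, and SNP-to-gene annotation.

## Who this is for

Groups with a re-sequenced crop panel (hundreds of accessions, a VCF with
10⁴–10⁶ biallelic SNPs) and a categorical phenotype such as seed colour,
where no single variant explains the trait and a univariate GWAS either
floods the candidate list or misses multi-locus signal.  The workflow was
designed around quinoa seed-colour genetics (white/beige/orange classes
driven by betalain pigmentation), but nothing in it is quinoa-specific.

## The method

Genotypes are encoded as alternate-allele dosage *x<sub>ij</sub>* ∈
{0, 1, 2} (vcftools 012 convention, −1 for missing).  The core procedure:

1. Train *R* multi-class XGBoost models, each on its own stratified
   train/test split (per-class test counts by largest-remainder
   allocation), with balanced class weights *w<sub>c</sub> = n/(k·n<sub>c</sub>)*
   and an independent seeded hyperparameter search scored by *k*-fold
   cross-validated one-vs-rest AUC with early stopping.
2. A SNP is *important* in a model when its total split gain is positive;
   the **consensus set** is every SNP important in ≥ *m* of the *R* models
   (defaults 9 of 100).
3. Expand the consensus with **collinear SNPs**: all sites with
   |Pearson r| ≥ 0.97 against a selected anchor (LD proxies).
4. Retrain the same *R* splits on the reduced feature space; an increase in
   mean accuracy/AUC confirms the selection removed noise rather than
   signal.
5. Cross-examine: per-SNP LMM Wald tests *y = α + xβ + u + ε*,
   cov(*u*) = σ²<sub>g</sub>*K* with the centred kinship
   *K = (1/p)Σ<sub>j</sub> c<sub>j</sub>c<sub>j</sub>ᵀ* on every class pair
   (fixed p < 10⁻⁸ threshold); PCA/LDA separation of the classes on the
   selected SNPs; a population-structure check that feeds the top 10 PCs
   to the ensemble as decoy features; and gene mapping with 1-kb flanks
   from GFF3.

A synthetic cohort generator (Balding–Nichols structure, LD blocks,
planted causal SNPs behind a multinomial-logit liability) provides ground
truth for end-to-end validation.  See `docs/methods.md` for the model
details and design choices.

## Worked example

```python
from boostsel.pipeline import run_synthetic_demo

report = run_synthetic_demo(seed=1, output_dir="demo_out")
print(report["ensemble_full"]["mean_accuracy"],
      report["ensemble_subset"]["mean_accuracy"],
      report["recovery"]["n_recovered"])
```

On the default synthetic cohort (300 accessions × 5000 SNPs, three colour
classes at ≈45:27:23 imbalance, 8 planted causal SNPs; 25 replicate
models, consensus threshold 3) this prints, for seed 1:

```
0.754 0.781 8
```

meaning: the full-matrix ensemble averaged 75.4% test accuracy (mean
one-vs-rest AUC 0.90), retraining on the combined consensus set raised it
to 78.1% (AUC 0.92), and all 8 planted causal SNPs were recovered in the
combined consensus set.  The output directory holds the consensus table,
projections, the run log, and `metrics.json` with every stage's numbers;
LDA on the consensus SNPs separates the three classes essentially
perfectly (silhouette ≈ 1.0).

The `examples/` scripts walk through each capability one at a time
(simulation, a single tuned model, the consensus pipeline, the LMM GWAS,
gene annotation).  A thin CLI wraps the pipeline:

```bash
boostsel simulate --seed 42 --out-prefix cohort
boostsel encode cohort.vcf --out-prefix cohort_genotypes
boostsel demo --seed 1 --out-dir demo_out
boostsel run-all --vcf my.vcf --phenotypes my_phenos.tsv --gff genes.gff3
```

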