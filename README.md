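# huberlasso

Robust Huber-LASSO versus standard LASSO for predicting molecular
phenotypes (protein / metabolite / expression residuals) from individual
SNP genotypes. The package provides:

- **losses** — squared, Huber and quantile loss families (ρ, influence ψ,
  weight w) plus the Gaussian-efficiency calculator for the Huber tuning
  constant (c = 1.345 → 95%).
- **solver** — L1-penalized regression for all three losses: warm-started
  λ-path fitting by iteratively reweighted coordinate descent (numba-
  accelerated), k-fold cross-validated λ selection, prediction and variable
  selection. Correctness is defined (and tested) via explicit
  KKT/subgradient checks.
- **depth** — eigenstrat-convention genotype PCA and trivariate halfspace
  (Tukey) depth, exact plane-enumeration up to n ≈ 600 plus a seeded
  random-projection bound, used to classify individuals as average
  (low-leverage) or divergent (high-leverage) genotypes.
- **metrics** — additive-locus explained variance (2·MAF(1−MAF)·a²),
  Jaccard model concordance, false/true-positive rates, Fisher-consistent
  Kendall/Spearman correlations (sin-transforms), percentile CIs.
- **synthetic_data** — seeded genotype/phenotype simulation: HWE dosages,
  Balding–Nichols population substructure, unit-variance phenotypes with a
  specified genetic architecture, outlier injection. The bundled
  "DEFB119" preset (3 causal SNPs explaining 10% of variance + 1000 null
  SNPs) emulates the restricted study data at the published MAFs/effects.
- **experiment** — the study protocols: repeated 500-individual
  subsamples with an artificial residual (−5…5) assigned to the depth
  extremes, paired CV fits of every loss variant, λ-stability / Jaccard /
  FPR / TPR / coefficient-CI aggregation, 5-fold out-of-sample prediction
  accuracy (squared Fisher-consistent Kendall correlation) and the λ/β̂
  sensitivity profiles.

## CLI

```bash
# synthetic dataset emulating the study preset
huberlasso simulate-data --n 3301 --n-null 1000 --seed 1 --out-prefix sim

# one model with 10-fold-CV lambda
huberlasso fit --genotypes sim.genotypes.tsv --phenotype sim.phenotype.tsv \
    --loss huber --c 1.345

# PCA + trivariate depth table
huberlasso depth --genotypes sim.genotypes.tsv --method projection --out depth.tsv

# repeated-subsample comparison (Tables-1/2-style outputs)
huberlasso run-experiment --genotypes sim.genotypes.tsv \
    --phenotype sim.phenotype.tsv --snp-meta sim.snps.tsv \
    --outlier-value 5 --leverage-target low --iterations 100 \
    --seed 1 --out-prefix results/exp

# 5-fold prediction accuracy, paired against the standard LASSO
huberlasso predict-accuracy --genotypes sim.genotypes.tsv \
    --phenotype sim.phenotype.tsv --loss huber --compare-with squared

# Gaussian efficiency of a Huber tuning constant
huberlasso efficiency --c 1.345
```

Genotype input is either a tab-delimited individuals×SNPs dosage matrix
(header = SNP ids, first column = individual id, values in [0,2]) or a
VCF (DS field preferred, GT otherwise); phenotypes are two-column
tab-delimited (id, value); ids are joined strictly.

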