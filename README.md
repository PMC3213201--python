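# polyfrs

Polygenic analysis of a quantitative cardiovascular-risk phenotype — the
Framingham Risk Score — from SNP genotype data. The package implements
three complementary genome-wide analyses plus the plumbing around them:

1. **Traditional GWAS** — per-SNP additive linear regression of the (log)
   risk score on allele dosage, adjusted for age, sex, genotyping batch
   and the leading principal components of the genotype matrix, with
   genomic-inflation (λ) and Q-Q summaries.
2. **Cross-validated polygenic scores** — K-fold (default 10-fold)
   discovery/test splits; SNPs grouped into the ten discovery p-value
   bins (0, .1], (.1, .2], …, (.9, 1]; per-bin allele-weighted scores
   for held-out samples; pooled regression of phenotype on score with
   per-bin adjusted R².
3. **SNP heritability** — an allele-frequency-weighted genetic
   relationship matrix (GRM) feeding (a) GREML variance components
   under y = Xb + g + e, Var(y) = σ²_g·A + σ²_e·I, fitted by three
   REML schemes (average-information Newton, Fisher scoring, EM), and
   (b) Haseman–Elston regression of the pairwise phenotype
   cross-product z_i·z_j on the GRM entry A_ij, with close-relative
   *pairs* (A_ij above a cutoff, default 0.025) excluded instead of
   whole subjects, and a subject-resampling bootstrap for inference.

Supporting modules provide the Framingham Risk Score engine (sex-specific
published coefficients over ln age, ln total cholesterol, ln HDL, ln SBP
with separate treated/untreated weights, smoking and diabetes
indicators), two quality-control regimes (an association regime — 95%
call rates, MAF ≥ 0.01, Hardy–Weinberg exact p ≥ 1e-4 — and a stricter
variance-component regime — 99% sample call rate, HWE p ≥ 0.05,
relatedness cutoff 0.025), PLINK bed/bim/fam and GCTA binary-GRM I/O,
and a synthetic-data generator with known ground truth (HWE genotypes,
Balding–Nichols two-population structure, duplicate/sib pairs,
batch-structured missingness, an additive polygenic trait with chosen
h², and a clinical covariate panel).

Intended users: statistical geneticists and methods students who want a
small, fully tested, pure-Python reference implementation of the
GWAS → polygenic score → GREML/H-E pipeline whose every stage can be
checked against brute-force oracles and parameter-recovery simulations.

## Worked example

```python
import numpy as np
from polyfrs import (SimConfig, simulate_dataset, compute_grm, GREML,
                     HasemanElston, PRSCrossValidation)

cfg = SimConfig(n_samples=800, n_snps=1500, h2_true=0.5, n_causal=300,
                maf_range=(0.05, 0.5), seed=11)
panel, y, truth = simulate_dataset(cfg)
panel = panel.subset(snp_ids=panel.snp_ids[panel.minor_allele_frequency() > 0])
print("h2_realized:", round(truth.h2_realized, 3))

grm = compute_grm(panel)
for algo in ("ai", "fisher", "em"):
    f = GREML(algorithm=algo).fit(grm, y)
    print(f"{algo:6s} sigma2_g={f.sigma2_g_:.4f} vp={f.vp_:.4f} "
          f"h2={f.h2_:.3f} (se {f.se_h2_:.3f}) logL={f.logL_:.3f}")

he = HasemanElston(pair_threshold=0.05, n_bootstrap=500, seed=0).fit(grm, y)
b = he.bootstrap_
print(f"HE     h2={he.h2_:.3f} se={b['se_h2']:.3f} "
      f"CI=({b['ci_low']:.3f},{b['ci_high']:.3f}) p={b['p_value']:.4f}")

cv = PRSCrossValidation(n_folds=10, seed=0).fit(panel, y)
print(cv.report_[["bin", "n_snps_mean", "p_value", "adj_r2"]])
```

Output:

```
h2_realized: 0.461
ai     sigma2_g=0.4524 vp=1.0052 h2=0.450 (se 0.068) logL=-384.818
fisher sigma2_g=0.4524 vp=1.0052 h2=0.450 (se 0.068) logL=-384.818
em     sigma2_g=0.4525 vp=1.0052 h2=0.450 (se 0.068) logL=-384.818
HE     h2=0.467 se=0.141 CI=(0.181,0.714) p=0.0000
      bin  n_snps_mean      p_value   adj_r2
  (0,0.1]        201.5 5.265045e-13 0.062071
(0.1,0.2]        155.8 4.722961e-03 0.008719
(0.2,0.3]        144.0 4.128882e-01 0.000000
...
  (0.9,1]        142.3 2.242380e-01 0.000600
```

Reading the numbers: the simulated trait realizes h² ≈ 0.46 in this
sample; all three REML algorithms converge to the same optimum
(ĥ² = 0.450, identical restricted log-likelihoods — they differ only in
path), and the pair-filtered Haseman–Elston slope gives a compatible but
noisier estimate with its bootstrap CI. In the cross-validated score
report the lowest p-value bin carries by far the most held-out
predictive power (adjusted R² 0.062), the next bin a little, and the
remaining bins essentially none — the expected signature of a polygenic
trait, where low discovery p-values enrich true associations relative
to type-I errors.

## Command line

Each stage is also a `polyfrs` subcommand operating on PLINK filesets:

```bash
polyfrs simulate --n 800 --m 1500 --h2 0.5 --n-causal 300 --seed 11 --out cohort
polyfrs frs --covar cohort.covar.tsv --out pheno.tsv
polyfrs qc --bfile cohort --preset gwas --out clean
polyfrs gwas --bfile clean --pheno cohort.pheno.tsv --n-pcs 20 --out assoc.tsv
polyfrs prs --bfile clean --pheno cohort.pheno.tsv --k 10 --out prs.tsv
polyfrs h2 reml --bfile clean --pheno cohort.pheno.tsv --algo ai
polyfrs h2 he   --bfile clean --pheno cohort.pheno.tsv --pair-max 0.025 --boot 1000
```

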