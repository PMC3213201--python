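# Methods

## Phenotype: the Framingham Risk Score

The analysis phenotype is the sex-specific Cox linear predictor for
10-year general cardiovascular disease risk,

    LP = β₁·ln(age) + β₂·ln(TC) + β₃·ln(HDL) + β₄·ln(SBP) + β₅·smoker + β₆·diabetic,

with distinct SBP weights for treated and untreated hypertension
(exactly one applies per subject) and the published general-CVD
coefficient sets for men and women as defaults. Units: age in years,
total cholesterol (TC) and HDL in mg/dL, systolic blood pressure (SBP)
in mmHg; smoking and diabetes are 0/1 indicators; diabetes is defined
as treatment for diabetes or blood glucose ≥ 200 mg/dL. Natural
logarithms throughout (the Framingham convention).

Downstream analyses use the linear predictor or its logarithm. Because
the LP can in principle be non-positive at extreme covariates, the log
transform uses ln(LP) when all values are positive and otherwise
ln(LP − min(LP) + 1), recording the shift in the output metadata.
Conversion to a 10-year probability 1 − S₀^exp(LP − LP̄) requires the
cohort-specific baseline-survival constants S₀ and mean linear
predictor LP̄; these are accepted as configuration, never defaulted,
since they are not portable across cohorts. Mean imputation of HDL from
a donor exam is supported for cohorts whose baseline exam lacked HDL;
subjects otherwise missing any predictor are ineligible.

## Quality control

Two regimes, applied in a fixed logged order — sample call rate →
marker filters (call rate, then MAF, then HWE, each marker attributed
to the first criterion it fails) → heterozygosity outliers →
relatedness → ancestry outliers:

| parameter | association regime | variance-component regime |
|---|---|---|
| sample call rate min | 0.95 | 0.99 |
| marker call rate min | 0.95 | 0.95 |
| MAF min (strict <) | 0.01 | 0.01 |
| HWE exact-test p min | 1e-4 | 0.05 |
| heterozygosity outlier | \|z\| > 3 (two-sided) | same |
| IBS ancestry outlier | z > 3 (one-sided) | same |
| relatedness, subject-wise | PIHAT > 0.25 | > 0.025 |
| relatedness, pair-wise (H-E) | — | A_ij > 0.025 |

The HWE test is the exact conditional (Levene–Haldane) test: the
p-value sums the probabilities of all heterozygote counts, given the
allele counts, whose probability does not exceed the observed one.
Computed in log space via log-gamma; verified against a
rational-arithmetic enumeration oracle.

PIHAT uses method-of-moments IBD estimation: per-pair IBS-state counts
over jointly non-missing SNPs are equated to their expectations given
allele frequencies under IBD states 0/1/2, the solved (Z0, Z1, Z2) are
clamped to the probability simplex, and PIHAT = Z1/2 + Z2. Clamping
makes unrelated-pair estimates non-negative on average (a few
hundredths at 2000 markers); estimates need ≥ 50 jointly observed SNPs
by default (configurable) and carry large noise below a few hundred.
Subject-wise relative pruning is greedy: repeatedly drop the individual
in the most over-threshold pairs, ties broken by smallest id, until no
pair exceeds the threshold.

Heterozygosity outliers are two-sided (excess heterozygosity signals
contamination, deficit signals inbreeding or genotyping failure);
ancestry outliers one-sided (outliers are IBS-*distant*, never too
close). When the outlier statistic has zero standard deviation, or
fewer than three samples remain, nothing is flagged — a constant
statistic carries no outlier information.

## GWAS

Per SNP, ordinary least squares of the phenotype on the A1-allele
dosage plus covariates; additive coding; two-sided p from the t
distribution with n_used − (#covariates + 2) degrees of freedom.
Genotype missingness is handled by casewise deletion per SNP (the
convention of standard association tools); SNPs fully observed are
batch-processed through a Frisch–Waugh residualization, which is
algebraically identical to the full regression. Mean imputation is used
only inside the PCA. Batch enters as one-hot dummies with the first
level dropped. PCs come from the SVD of the mean-imputed,
frequency-standardized (√(2p(1−p))) genotype matrix, scores scaled by
singular values, sign fixed so each component's largest-magnitude
coordinate is positive; constant SNPs are excluded with a warning.
An optional max-T permutation mode (permuting the covariate-residualized
phenotype) provides family-wise empirical p-values; the asymptotic
p-values are the default. The genomic inflation factor is the median
1-df chi-square quantile of the p-values divided by 0.45494.

## Cross-validated polygenic scores

Samples are partitioned into K folds (default 10, sizes within one,
seeded). Per fold, a GWAS on the other K−1 folds supplies betas and
p-values; SNPs fall into ten half-open bins (0, .1], …, (.9, 1] (the
upper edge belongs to its bin; p = 1 lands in (.9, 1]). Held-out
samples receive, per bin, the PLINK-style per-allele average score
Σ β_j·dosage_ij / (2·#SNPs observed); missing genotypes are filled with
twice the discovery allele frequency by default (a skip-missing mode
and a raw-sum mode exist). Held-out scores are pooled across folds and
each bin's score is regressed on the phenotype (covariate adjustment
optional, off by default); the report gives the per-bin SNP counts
(mean/min/max across folds), the pooled p for the score term, and the
adjusted R² attributable to the score, floored at zero.

A calibration caveat, established empirically during development: the
pooled regression is mildly anti-conservative under the null, because
every sample's phenotype also shapes the discovery betas of the other
folds, correlating the pooled rows. At n = 1000 the probability that
the reported (floored) adjusted R² exceeds zero under a null trait is
≈ 0.5 rather than the 0.32 of an exact t test, though the magnitudes
stay at the chance scale ~1/n. Fold fixed effects do not remove the
effect (the leak is cross-fold, not a fold-mean artifact), so the
simple pooled regression is retained and per-bin p-values should be
read as descriptive rather than strictly calibrated. Between-bin
contrasts (the low-p bin outperforming the high-p bin) are unaffected.

## GRM

For SNP j with sample A1 frequency p_j, standardized dosage
w_ij = (x_ij − 2p_j)/√(2p_j(1−p_j)). Off-diagonals average w_ij·w_kj
over jointly non-missing SNPs; diagonals use the unbiased single-sample
form 1 + (x² − (1+2p)x + 2p²)/(2p(1−p)) averaged over the sample's
non-missing SNPs (the GCTA convention). Per-pair non-missing SNP counts
are retained and serialized in the binary GRM triple. Monomorphic SNPs
are rejected — filter first. Two finite-sample facts the tests encode:
centering on *sample* frequencies makes the expected off-diagonal
−1/n (not 0), and a duplicated sample's off-diagonal equals mean(w²),
which matches the unbiased diagonal only to O(1/√m).

## GREML

Model: y = Xb + g + e with Var(y) = σ²_g·A + σ²_e·I; REML maximizes
−½[ln|V| + ln|XᵀV⁻¹X| + yᵀPy] with P = V⁻¹ − V⁻¹X(XᵀV⁻¹X)⁻¹XᵀV⁻¹.
All linear algebra runs in the eigenbasis of A, where V is diagonal
(d_i = σ²_g·λ_i + σ²_e): one symmetric eigendecomposition per fit, then
O(n·p²) per iteration for every trace and quadratic form. This is
exact, not an approximation, and makes the three algorithms cheap at
n in the low thousands.

Updates per iteration: EM, σ²_i ← σ²_i + σ⁴_i(yᵀPV_iPy − tr(PV_i))/n;
Fisher scoring, a Newton step with expected information
½tr(PV_iPV_j); AI, a Newton step with average information
½yᵀPV_iPV_jPy. The first iteration of the Newton schemes is one EM
step (standard stabilization). Defaults: start at σ²_g = σ²_e = Vp/2,
max_iter 200, convergence when |Δ logL| < 1e-8. Step halving (up to 10
times) guards against losing positive definiteness; negative components
are projected to 1e-6·Vp with a constraint flag (an unconstrained mode
is the flag's complement). Standard errors come from the inverse
average-information matrix at the optimum for all three algorithms —
so the algorithm columns differ only via the path — and se(ĥ²) by the
delta method. EM's log-likelihood is monotone (asserted per iteration
in tests); near the σ²_g = 0 boundary EM converges slowly and can stop
a few hundredths above zero at the default tolerance, a known property
of multiplicative EM updates, visible in the recovery means at true
h² = 0.

Degenerate input: with A = I the likelihood is flat in the σ²_g/σ²_e
split (only Vp = σ²_g + σ²_e is identified); the information matrix is
singular and is pseudo-inverted, and the tests check the identified
quantities (Vp = RSS/(n−1) and the closed-form iid restricted
likelihood) rather than the meaningless split.

## Haseman–Elston regression with subject bootstrap

The phenotype is residualized on the covariates and standardized; for
every pair i < j with A_ij ≤ the pair threshold (default 0.025), the
cross-product z_i·z_j (default; the classical squared-difference form
(z_i − z_j)² is an option with ĥ² = −slope/2) is regressed on A_ij by
OLS with intercept. The slope is the h² estimate. Excluding related
*pairs* rather than subjects keeps the whole sample; note that
selection on the regressor does not bias OLS, it only trades variance.

Inference: subjects are resampled with replacement; pairs among draws
whose members descend from distinct original subjects are kept; the
regression (including re-residualization on the resampled covariates)
is rerun. SE = SD of bootstrap slopes, CI = 2.5/97.5 percentiles, p =
two-sided percentile sign test. Degenerate resamples (a single distinct
subject, or zero residual variance) are redrawn and counted.

A deliberate limitation, quantified in the test suite: with unrelated
samples the H-E slope is dominated by pair-level GRM noise, making it a
(first-order) degenerate U-statistic, for which the with-replacement
subject bootstrap is classically inconsistent — the bootstrap SE
converges to about √3 times the true sampling SD (the variance of the
near-Poisson pair multiplicities k_i·k_j). The measured inflation is
1.6–1.7. Inference is therefore conservative: CIs over-cover and the
null rejection rate at α = 0.05 is below 1% rather than 5%. A property
test pins the measured inflation factor so any change in this behaviour
is caught. In designs where relatedness varies at the subject level
(pedigree structure), the subject projection dominates and the same
bootstrap is asymptotically correct.

## Synthetic data

The generator emulates what the analyses assume and nothing more:
biallelic autosomal SNPs with frequencies uniform on a configurable MAF
range, genotypes Binomial(2, p) in Hardy–Weinberg equilibrium and
linkage equilibrium; optional two-population structure via
Balding–Nichols Beta-distributed subpopulation frequencies at a given
Fst; duplicate pairs (copied genotypes) and sib-like pairs sharing each
allele with probability 1/2 per locus independently (expected
relatedness exactly 1/2, but no Mendelian segregation or LD); entrywise
Bernoulli missingness with an additive boost for batch "B"; an additive
polygenic trait with effects N(0, h²/n_causal) on standardized dosages
(so per-SNP variance contributions are frequency-independent, matching
the GRM weighting) and N(0, 1−h²) residuals, with the realized
Var(g)/Var(y) recorded; and a clinical covariate panel (age uniform
30–74; TC ~ N(200, 35²) mg/dL truncated above 100; HDL ~ N(50, 13²)
above 20; SBP ~ N(125, 17²) mmHg above 90; 20% treated, 20% smokers,
8% diabetic; balanced sexes) that is genetically inert unless a genetic
component is explicitly mixed into TC/HDL/SBP.

What passing tests therefore show: correctness of the estimators under
their own assumptions (independent loci, random mating, Gaussian
residuals) and exact agreement with brute-force oracles. What they do
not show: behaviour under linkage disequilibrium, assortative mating,
non-Gaussian traits, genotyping error correlated with phenotype, or
real pedigree structure — none of which the generator produces.

A separate deterministic 20-sample × 30-SNP fixture with planted QC
violations exercises the filter bookkeeping; its expected removals are
regime-dependent (at a 99% call-rate threshold a 30-marker sample fails
with a single missing genotype, so the low-call marker's carrier
samples fall to the sample filter first). At this scale relatedness
estimates from ~27 SNPs are far too noisy for exact relatedness
removal counts; the planted duplicate pair is instead verified directly
(PIHAT ≈ 1, one of the two removed). The relatedness machinery itself
is validated at realistic marker counts elsewhere in the suite.

## Problem sizes

The test suite and the acceptance script run oracle checks at n ≤ 120,
parameter recovery at n = 1000, m = 2000 with 20 replicates per true
h² ∈ {0, 0.25, 0.5}, GWAS calibration on 10,000 null SNPs at n = 500,
bootstrap calibration on 200 datasets at n = 250, and the score-bin
contrast at n = 2000, m = 3000 over 5 seeds — sizes at which each
stage's sampling error is small against the tolerances being asserted
while a full run stays within a few minutes on one CPU.

## Known limitations

No linkage disequilibrium anywhere (simulation, clumping, LD-aware
scoring); no X chromosome; no dominance or mixed-model association; no
multi-component or bivariate GREML; hard-call genotypes only (dosage
files with fractional values are out of scope); the pooled
cross-validation p-values and the subject-bootstrap null rejection rate
carry the calibration caveats described above.
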