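# Methods

This note documents the statistical models implemented in gccscan, the
numerical choices behind them, what the simulator does and does not emulate,
and the known limitations.

## The generalized correlation coefficient

### Model

Given paired observations (xᵢ, yᵢ), i = 1…n, the GCC contrasts an
independence model with a dependence-admitting alternative:

- Null: f₀(x, y) = f̂(x) · f̂(y), the product of univariate Gaussian-kernel
  density estimates.
- Alternative: f_w(x, y) = w · f̂(x, y) + (1 − w) · f₀(x, y), where
  f̂(x, y) is a bivariate Gaussian product-kernel (diagonal-bandwidth)
  estimate and w ∈ [0, 1] is the mixture weight.

All likelihoods are evaluated **held out** under k-fold cross-validation
(default k = 10, seeded shuffle, contiguous folds): the densities are
anchored on the training folds and evaluated on the held-out fold, so the
alternative gains nothing from overfitting. The weight w is chosen by grid
search over {0, 0.1, …, 1.0} on the summed held-out log-likelihood, ties to
the smaller weight. Because the grid contains 0, the alternative's held-out
log-likelihood never falls below the null's.

The association strength is the density-ratio generalized R²,

    A = 1 − ∏ᵢ [ f₀(xᵢ, yᵢ) / f_w(xᵢ, yᵢ) ]^(2/n) = 1 − exp(−CVLRS / n),

with CVLRS = −2·(log Lcv(Null) − log Lcv(Alt)). Independence gives w = 0,
CVLRS = 0, A = 0 exactly; a deterministic relationship drives A toward 1.
For bivariate Gaussian data A converges to ρ²: the measured gap |A − ρ²| is
at most ≈ 0.03 at n = 2,000 across ρ ∈ {0, 0.3, 0.6, 0.9}.

### Variable preprocessing

- **Continuous variables** are mapped to Blom rank-based normal scores,
  Φ⁻¹((rank − 3/8)/(n + 1/4)), before density estimation. This makes A
  exactly invariant under strictly monotone rescaling of either variable
  (the equitability property — a raw KDE is not even approximately
  invariant under tail-stretching transforms such as y ↦ y³) and renders
  the statistic insensitive to outliers and extreme phenotype values. For
  Gaussian data the scores are essentially the data, so the Gaussian-limit
  property is unaffected.
- **Discrete variables** (≤ 10 distinct values — hard-call genotypes and
  near-hard dosages) instead receive a seeded deterministic jitter of
  amplitude 0.05, which breaks the degeneracy of the kernel estimate while
  keeping the genotype classes as separated modes. Normal scores are *not*
  applied to discrete variables: they would stretch each genotype class
  over a contiguous interval of scores, erasing the class contrast that
  carries the signal (empirically this halves power against
  genotype-class mean shifts).

### Bandwidths

Univariate (marginal) bandwidths follow Silverman's rule,
0.9 · min(sd, IQR/1.349) · n^(−1/5). The joint estimate uses the same
univariate value per dimension shrunk by a fixed factor 0.85. Rationale: the
canonical d = 2 rate n^(−1/6) oversmooths the dependent component relative
to the marginals, biasing the likelihood ratio toward the null and capping A
near 0.91 even for y = x at n = 500; the shrunk univariate rate removes that
saturation (A ≈ 0.96 for y = x, n = 500) while leaving the Gaussian
equitability gap within 0.03. Overfitting under independence is not a
concern because the cross-validated weight search simply selects w = 0. A
`scott` rule is available as an alternative (`bandwidth_rule`).

### The permutation statistic and p-values

The *reported* CVLRS has a point mass at 0 under independence (the weight
grid contains 0), which would make permutation p-values non-uniform
(conservative, piling up at 1). Testing therefore uses a continuous variant,
`cvlrs_test`: the likelihood ratio against the best strictly *positive*
mixture weight, which can be negative under the null and coincides with
CVLRS whenever there is evidence of dependence. P-values are

    p = (1 + #{null statistics ≥ observed}) / (n_perm + 1).

**Permutation unit.** When family structure is supplied, the phenotype is
permuted in whole family blocks across families of equal size, with a random
within-pair flip (co-twins are exchangeable). This preserves both marginals
*and* the within-family clustering of the phenotype — the correct
exchangeability unit for twin data. Individual-level permutation is used
when no structure is given, and is measurably anti-conservative on twin
data: co-twins share both genotype (MZ r = 1, DZ r = 0.5) and phenotype, so
the held-out joint density at a twin is boosted by its co-twin's training
point even under the null; destroying that clustering in the permutation
null inflated the type-I error to ≈ 0.4 at nominal 0.05 in the default
simulation design.

**Tail extrapolation.** When the observed statistic exceeds every
permutation, a generalized Pareto distribution fitted to the exceedances
over the 90th percentile of the null statistics extrapolates the p-value
below 1/(n_perm + 1) (and, symmetrically, extreme null quantiles for power
studies). Against a 6,000-draw empirical null, 999-draw GPD estimates of the
99.9th percentile were unbiased with ≈ 2% scatter.

**Shared null calibration.** Simulation studies re-test thousands of
datasets with identical marginal structure. `shared_null_calibration` builds
one null distribution from fresh genotype draws paired with *independent
phenotype draws* (`y_sampler`) and reuses it across replications. Permuting
one fixed phenotype vector instead is exact for repeated tests against that
same vector (the per-SNP scan case) but miscalibrates across fresh phenotype
realizations: the CVLRS level shifts by about one null standard deviation
between phenotype vectors.

### Genome-scan defaults

Per-SNP permutation with a two-stage scheme: a coarse 99-permutation screen,
then the full n_perm = 999 with GPD tail only for SNPs with screen p ≤ 0.01.
This leaves top hits untouched and cuts scan cost by roughly 10×.

## Linear comparators

**Kinship GLS.** Phenotypic covariance σ²g·K + σ²e·I with K the expected
additive relationship matrix (diagonal 1; MZ co-twin 1; DZ co-twin 0.5;
unrelated 0 — i.e., twice the kinship coefficient, so σ²g reads as additive
genetic variance; rescaling K does not change the Wald test). Estimation
rotates into the eigenbasis of K (the decomposition is computed once per
matrix and cached), reducing REML to a one-dimensional bounded profile over
h² = σ²g/(σ²g + σ²e). By default (`varcomp_mode="null_once"`) variance
components are estimated under the covariate-only model and reused across
SNPs — the standard two-step GWAS practice; `per_snp` refits them with the
SNP in the design. The residual scale is re-estimated from full-model GLS
residuals with denominator n − p, so with K = I the fit reproduces OLS
coefficients *and* standard errors exactly.

**Pair LME.** A random intercept per twin pair, maximum likelihood. The
exchangeable 2×2 within-pair covariance is diagonalized analytically by the
within-pair sum/difference rotation, leaving a one-dimensional profile over
the intraclass correlation. This is the same model and objective as a
generic mixed-model fit (it matches statsmodels MixedLM to optimizer
tolerance, which the test suite asserts) at well under a hundredth of the
cost — necessary because the studies fit it tens of thousands of times.
Both models report a Wald z = β/se with a two-sided normal p-value.

**Covariate handling.** The scan adjusts the phenotype once — Box-Cox first
if requested, then least-squares residualization on age and sex — and all
three models test the residual. For the GCC, residualization is the only
coherent way to adjust a bivariate dependence measure; applying the same
residual to the linear models keeps the three scans comparable on identical
inputs.

**Box-Cox.** λ is chosen by profile likelihood over the grid [−2, 2] in
steps of 0.01 (natural log at λ = 0); non-positive phenotypes are first
shifted by 1 − min(y), and the shift is reported.

## The twin simulator

Genotypes: per family, two parental genotypes are drawn under
Hardy–Weinberg equilibrium at the configured MAF; MZ twins receive one
Mendelian transmission duplicated, DZ twins two independent transmissions
from the same parents (expected within-pair dosage correlation 0.5);
singletons are drawn from HWE directly. Phenotypes:
y = β·f(g) + c_family + e, with the environmental part c + e standard
normal and within-pair correlation ρ; f is the coded genetic score
(additive g, dominance/recessive indicators, or the centered quadratic
(g − ḡ)²). A skewed variant exponentiates and restandardizes.

Deliberate simplifications: the pair component has the same variance for MZ
and DZ pairs (purely environmental sharing), isolating how each model copes
with correlated samples without conflating it with heritability; SNPs are
simulated without LD; no genotyping error, missingness, imputation noise, or
ascertainment. Consequently, passing simulations demonstrate calibration and
relative power under clean twin sharing, not robustness to those real-data
features. Because MZ phenotype correlation equals DZ correlation here, the
kinship model's implied 2:1 MZ:DZ covariance ratio is mildly misspecified —
its observed calibration (≈ 0.05) shows the Wald test is robust to this, as
in the equivalent published design.

**Study defaults.** The type-I-error study uses 300 DZ + 100 MZ pairs,
MAF 0.3, pair correlation 0.3, 1,000 replications — a desk-scale twin-cohort
design; the target (nominal 5% rejection) is structure-invariant for a
calibrated test, and all parameters are overridable. The GCC uses the shared
null (999 draws) by default; `per_replication` runs a full permutation test
per replication and agrees within joint binomial noise (asserted at 200
replications in the suite). The power study uses MAF 0.5 for the quadratic
(non-additive) cell, where the quadratic score is exactly orthogonal to the
additive score — at asymmetric MAFs (g − ḡ)² correlates substantially with g
(ρ ≈ 0.53 at MAF 0.3) and the scenario becomes a mixed additive/non-additive
one rather than a pure non-linearity probe.

## Numerical details

- Kernel matrices for the GCC workspace are float32 (sums accumulated in
  float64); a permutation re-fit costs ~2–3 ms at n = 600-800. Memory is
  O(n²) per fitted pair; pairs beyond n ≈ 10⁴ should be subsampled.
- Density values are floored at 1e-300 before logs (Gaussian kernels are
  strictly positive analytically; float64 underflows beyond ~38 bandwidths).
- Degenerate inputs (zero variance) raise immediately; monomorphic SNPs are
  skipped by the scan with a logged reason; missing dosages are dropped
  pairwise per SNP (n_used recorded), not imputed.
- Fold assignment, jitter, permutations, and simulations all derive from
  explicit integer seeds; identical (config, seed) pairs are
  bit-reproducible.
- λ_GC = median(χ²₁ quantiles of p) / 0.4549364 for all three models alike,
  so inflation factors are directly comparable across models.

## Known limitations

- The GCC is bivariate only; covariates enter by residualization, not
  within the density model.
- A is reported without direction; examine the genotype-class density table
  (`genotype_density_table`) to characterize the relationship's shape.
- The GPD tail extrapolates smoothly but cannot certify p-values many
  orders of magnitude below permutation resolution; at genome-wide
  stringency, treat extrapolated p as a ranking device and confirm top hits
  with a larger dedicated permutation run.
- Kinship and LME handle twin families (size ≤ 2) only; extended pedigrees
  are out of scope.
- Autosomal analysis convention; no X-chromosome dosage compensation model.
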