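# gccscan

Association testing for genome-wide scans with the **generalized correlation
coefficient (GCC)** — a nonparametric, assumption-free measure of
genotype–phenotype dependence — alongside the two conventional twin-aware
linear comparators (kinship-matrix GLS and a random-intercept mixed model),
and a twin simulation harness for validating type-I error and power.

## Who this is for

Statistical geneticists analyzing quantitative phenotypes in family- or
twin-structured cohorts who want to detect variants whose effects are not
additive (dominant, recessive, or non-linear patterns that a linear dosage
model cannot represent), without assuming normal phenotypes or uncorrelated
samples.

## The statistic

For a dosage vector *x* and phenotype *y*, two density models are compared
on held-out data under *k*-fold cross-validation:

- **null** (independence): P(x, y) = P(x) P(y), the product of
  Gaussian-kernel marginal estimates;
- **alternative**: a mixture w · P(x, y) + (1 − w) · P(x) P(y) of a kernel
  joint estimate and the independence model, with w chosen on the held-out
  likelihood.

The association strength is the generalized R²

    A = 1 − ∏ᵢ [ P(xᵢ, yᵢ | null) / P(xᵢ, yᵢ | alt) ]^(2/n)  ∈ [0, 1],

which is 0 for independent variables, approaches 1 under a deterministic
relationship, and approximates the squared Pearson correlation ρ² for
bivariate Gaussian data — while also capturing non-linear and non-monotone
dependence. Significance uses the cross-validation likelihood-ratio
statistic

    CVLRS = −2 log( Lcv(Null) / Lcv(Alt) ),

calibrated by permutation: the phenotype is permuted in whole family blocks,
so both marginals *and* the within-pair correlation of twins are preserved
under the null. P-values below permutation resolution are extrapolated with
a generalized-Pareto fit to the permutation tail. A has no sign — direction
of effect is not meaningful for non-linear relationships — so only the
linear models report beta and its standard error.

The comparators model the twin correlation explicitly: kinship GLS uses the
phenotypic covariance σ²g·K + σ²e·I with K the expected additive
relationship matrix (MZ co-twins 1, DZ co-twins 0.5), variance components by
REML; the LME puts a random intercept on every twin pair (maximum
likelihood). Both test the dosage coefficient with a Wald test.

## Worked example

A non-linear relationship that the linear model cannot see:

```python
import numpy as np
import gccscan as gs

r = np.random.default_rng(0)
x = r.standard_normal(1000)
y = x**2 + 0.5 * r.standard_normal(1000)

fit = gs.fit_gcc(x, y, seed=1)
print(fit.A, fit.mixture_weight)          # 0.735  1.0
print(np.corrcoef(x, y)[0, 1] ** 2)       # 0.0076

res = gs.gcc_pvalue(x, y, n_perm=999, tail_method="empirical", seed=1)
print(res.pvalue)                         # 0.001  (= 1/1000, beats all permutations)
```

The GCC assigns the parabola an association strength A = 0.735 — the
dependence is strong — while the squared Pearson correlation is 0.0076,
invisible to a linear test. With `tail_method="gpd_tail"` (the default) the
p-value is extrapolated below the 1/(n_perm+1) resolution.

From the shell, simulate a twin cohort and scan it:

```
gccscan simulate --n-mz-pairs 100 --n-dz-pairs 300 --n-snps 200 --seed 1 --out demo
gccscan scan --matrix demo.dosage.tsv --pheno demo.pheno.tsv \
             --model gcc --perm 999 --seed 1 --out demo_gcc
# tested 200 SNPs; lambda_GC=1.047; 0 genome-wide, 0 suggestive
```

The phenotype here is null, so the scan reports a genomic inflation factor
near 1 (the test is calibrated despite the twin correlation) and no SNP
below the genome-wide (5e-8) or suggestive (1e-5) thresholds. `scan` also
accepts `--vcf` with a per-sample dosage FORMAT field (default `DS`), applies
the post-imputation filters (MAF ≥ 5%, INFO > 0.6), adjusts the phenotype
for age and sex, and optionally Box-Cox-normalizes it (`--boxcox`).

The validation studies run from the CLI as well:

```
gccscan study type1 --reps 1000 --alpha 0.05 --models gcc,kinship,lme --seed 7 --out rates.tsv
```

## Layout

- `gccscan.io_gwas` — VCF/matrix dosage readers, phenotype tables, variant filters, result I/O
- `gccscan.gcc_core` — the GCC: density models, A, CVLRS, permutation p-values, shared null calibration
- `gccscan.linear_models` — kinship matrix, REML GLS, pair mixed model
- `gccscan.scan_engine` — covariate adjustment, Box-Cox, the scan loop, λ_GC, QQ/Manhattan tables
- `gccscan.twin_sim` — twin genotype/phenotype simulator, type-I-error and power studies
- `gccscan.cli` — `gccscan scan|simulate|study|fixtures|plot`

See `docs/methods.md` for the modeling choices and their rationale.
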