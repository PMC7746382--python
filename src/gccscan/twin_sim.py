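"""Twin-structured genotype/phenotype simulator and the validation studies.

Genotypes: for each twin family two parental genotypes are drawn under
Hardy-Weinberg equilibrium at the configured minor allele frequency;
monozygotic (MZ) twins receive one identical Mendelian transmission,
dizygotic (DZ) twins two independent transmissions from the same parents
(expected within-pair dosage correlation 0.5), and singletons are drawn
directly from HWE.

Phenotypes: y = effect_size * f(g) + pair component + unique noise, where f
is the coded genetic score (additive g, dominance/recessive indicators, or a
centered quadratic) and the environmental part has unit variance with
within-pair correlation ``pair_phenotype_correlation`` — identical for MZ and
DZ pairs, i.e. purely environmental sharing, which isolates how each
association model copes with correlated samples without conflating it with
heritability. A skewed variant exponentiates the normal phenotype and
restandardizes.

The type-I-error study mirrors the standard validation: replications of one
simulated SNP against an independent standard-normal phenotype, each tested
at nominal alpha; the power study crosses effect models and sizes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, MisuseError
from .gcc_core import (
    NullCalibration,
    _GccWorkspace,
    _check_weight_grid,
    gcc_pvalue,
    shared_null_calibration,
)
from .io_gwas import DosageMatrix, PhenoTable, SnpMeta
from .linear_models import KinshipMatrix, build_kinship, fit_kinship_gls, fit_lme_pair

__all__ = [
    "TwinSimConfig",
    "SimStudyResult",
    "simulate_twin_genotypes",
    "simulate_phenotype",
    "effect_size_for_variance_explained",
    "type1_error_study",
    "power_study",
]

EFFECT_MODELS = ("null", "additive", "dominant", "recessive", "quadratic")


@dataclass(frozen=True)
class TwinSimConfig:
    """Simulation design. Defaults reflect a desk-scale twin cohort: 300 DZ
    and 100 MZ pairs, MAF 0.3, within-pair phenotype correlation 0.3."""

    n_mz_pairs: int = 100
    n_dz_pairs: int = 300
    n_singletons: int = 0
    maf: float = 0.3
    n_snps: int = 1
    effect_model: str = "null"
    effect_size: float = 0.0
    pair_phenotype_correlation: float = 0.3
    phenotype_family: str = "normal"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.maf <= 0.5):
            raise ConfigError(f"maf must lie in (0, 0.5], got {self.maf}")
        if min(self.n_mz_pairs, self.n_dz_pairs, self.n_singletons) < 0:
            raise ConfigError("pair/singleton counts must be nonnegative")
        if self.n_total < 20:
            raise ConfigError(f"total sample size {self.n_total} < 20")
        if self.effect_model not in EFFECT_MODELS:
            raise ConfigError(f"unknown effect_model {self.effect_model!r}")
        if not (0.0 <= self.pair_phenotype_correlation < 1.0):
            raise ConfigError("pair_phenotype_correlation must lie in [0, 1)")
        if self.phenotype_family not in ("normal", "skewed"):
            raise ConfigError(f"unknown phenotype_family {self.phenotype_family!r}")
        if self.n_snps < 1:
            raise ConfigError("n_snps must be positive")

    @property
    def n_total(self) -> int:
        return 2 * (self.n_mz_pairs + self.n_dz_pairs) + self.n_singletons


def _family_layout(cfg: TwinSimConfig) -> pd.DataFrame:
    rows = []
    fam = 0
    for _ in range(cfg.n_mz_pairs):
        for k in (1, 2):
            rows.append((f"fam{fam:05d}_{k}", f"fam{fam:05d}", "MZ"))
        fam += 1
    for _ in range(cfg.n_dz_pairs):
        for k in (1, 2):
            rows.append((f"fam{fam:05d}_{k}", f"fam{fam:05d}", "DZ"))
        fam += 1
    for _ in range(cfg.n_singletons):
        rows.append((f"fam{fam:05d}_1", f"fam{fam:05d}", "singleton"))
        fam += 1
    return pd.DataFrame(rows, columns=["sample_id", "family_id", "zygosity"])


def _simulate_genotype_columns(cfg: TwinSimConfig, rng: np.random.Generator) -> np.ndarray:
    """One HWE/Mendelian genotype column per SNP for the family layout."""
    q = cfg.maf
    n_pairs = cfg.n_mz_pairs + cfg.n_dz_pairs
    cols = np.empty((cfg.n_total, cfg.n_snps))
    for j in range(cfg.n_snps):
        # parental allele pairs for every twin family
        pat = rng.random((n_pairs, 2)) < q
        mat = rng.random((n_pairs, 2)) < q
        # Mendelian transmission: pick one allele from each parent
        def transmit() -> np.ndarray:
            pa = pat[np.arange(n_pairs), rng.integers(0, 2, n_pairs)]
            ma = mat[np.arange(n_pairs), rng.integers(0, 2, n_pairs)]
            return (pa.astype(int) + ma.astype(int)).astype(float)
        t1 = transmit()
        t2 = transmit()
        g = np.empty(cfg.n_total)
        mz = cfg.n_mz_pairs
        # MZ pairs: one transmission, duplicated
        g[0 : 2 * mz : 2] = t1[:mz]
        g[1 : 2 * mz : 2] = t1[:mz]
        # DZ pairs: two independent transmissions
        g[2 * mz : 2 * n_pairs : 2] = t1[mz:]
        g[2 * mz + 1 : 2 * n_pairs : 2] = t2[mz:]
        # singletons straight from HWE
        g[2 * n_pairs :] = rng.binomial(2, q, cfg.n_singletons).astype(float)
        cols[:, j] = g
    return cols


def simulate_twin_genotypes(cfg: TwinSimConfig) -> tuple[DosageMatrix, PhenoTable]:
    """Simulate genotypes for the configured twin structure.

    Returns the dosage matrix and a phenotype-table skeleton (family and
    zygosity structure, twin-shared ages, sexes, phenotype NaN until
    :func:`simulate_phenotype` fills it).
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed % (2**31), 0x617]))
    layout = _family_layout(cfg)
    values = _simulate_genotype_columns(cfg, rng)
    snps = [
        SnpMeta(
            snp_id=f"sim{j + 1}",
            chrom=str((j % 22) + 1),
            pos=10_000 + j,
            ref_allele="A",
            alt_allele="G",
            maf=float(min(values[:, j].mean() / 2.0, 1.0 - values[:, j].mean() / 2.0)),
        )
        for j in range(cfg.n_snps)
    ]
    dm = DosageMatrix(samples=layout["sample_id"].tolist(), snps=snps, values=values)

    fam_codes = pd.factorize(layout["family_id"])[0]
    fam_age = rng.uniform(45.0, 75.0, fam_codes.max() + 1)
    age = fam_age[fam_codes]  # co-twins share birth year
    fam_sex = rng.integers(0, 2, fam_codes.max() + 1)
    sex = np.where(fam_sex[fam_codes] == 1, "female", "male").astype(object)
    is_dz = layout["zygosity"].to_numpy() == "DZ"
    # DZ co-twins may be opposite sex; re-draw independently
    sex[is_dz] = np.where(rng.integers(0, 2, int(is_dz.sum())) == 1, "female", "male")
    pheno = PhenoTable(
        pd.DataFrame(
            {
                "sample_id": layout["sample_id"],
                "phenotype": np.nan,
                "age": age,
                "sex": sex,
                "family_id": layout["family_id"],
                "zygosity": layout["zygosity"],
            }
        )
    )
    return dm, pheno


def _genetic_score(g: np.ndarray, effect_model: str) -> np.ndarray:
    if effect_model == "additive":
        return g.astype(float)
    if effect_model == "dominant":
        return (g >= 1).astype(float)
    if effect_model == "recessive":
        return (g == 2).astype(float)
    if effect_model == "quadratic":
        return (g - g.mean()) ** 2
    raise ConfigError(f"no genetic score for effect_model {effect_model!r}")


def effect_size_for_variance_explained(
    frac: float, g: np.ndarray, effect_model: str
) -> float:
    """Effect size beta such that beta * f(g) explains ``frac`` of the total
    phenotype variance when the environmental part has unit variance."""
    if not 0.0 < frac < 1.0:
        raise ConfigError(f"variance fraction must lie in (0, 1), got {frac}")
    var_f = float(np.var(_genetic_score(np.asarray(g, dtype=float), effect_model)))
    if var_f <= 0.0:
        raise ConfigError("genetic score has zero variance (monomorphic genotypes?)")
    return math.sqrt(frac / (1.0 - frac) / var_f)


def simulate_phenotype(
    genotypes: np.ndarray,
    pheno_skeleton: PhenoTable,
    cfg: TwinSimConfig,
    rng: Optional[np.random.Generator] = None,
) -> PhenoTable:
    """Fill the skeleton's phenotype column.

    y = effect_size * f(g) + c_family + e, with the environmental part
    (c + e) standard normal and within-pair correlation
    ``pair_phenotype_correlation`` for MZ and DZ alike. ``phenotype_family =
    "skewed"`` exponentiates and restandardizes.
    """
    g = np.asarray(genotypes, dtype=float).ravel()
    n = pheno_skeleton.n
    if g.size != n:
        raise ConfigError(f"genotype length {g.size} != sample count {n}")
    if rng is None:
        rng = np.random.default_rng(
            np.random.SeedSequence([cfg.seed % (2**31), 0x9EE])
        )
    rho = cfg.pair_phenotype_correlation
    fam_codes = pd.factorize(pheno_skeleton.family_ids)[0]
    shared = rng.standard_normal(fam_codes.max() + 1)[fam_codes] * math.sqrt(rho)
    unique = rng.standard_normal(n) * math.sqrt(1.0 - rho)
    y = shared + unique
    if cfg.effect_model != "null":
        y = cfg.effect_size * _genetic_score(g, cfg.effect_model) + y
    if cfg.phenotype_family == "skewed":
        y = np.exp(y)
        y = (y - y.mean()) / y.std(ddof=1)
    df = pheno_skeleton.data.copy()
    df["phenotype"] = y
    return PhenoTable(df)


# ---------------------------------------------------------------------------
# Studies
# ---------------------------------------------------------------------------

VALID_MODELS = ("gcc", "kinship", "lme")


@dataclass
class SimStudyResult:
    """Per-model rejection rates with exact (Clopper-Pearson) 95% intervals."""

    alpha: float
    n_replications: int
    rejection_rate: dict[str, float]
    ci95: dict[str, tuple[float, float]]
    calibration: str = "shared_null"

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "model": m,
                "rejection_rate": self.rejection_rate[m],
                "ci95_low": self.ci95[m][0],
                "ci95_high": self.ci95[m][1],
                "n_replications": self.n_replications,
                "alpha": self.alpha,
            }
            for m in self.rejection_rate
        ]
        return pd.DataFrame(rows)


def _binom_ci95(k: int, n: int) -> tuple[float, float]:
    lo = 0.0 if k == 0 else float(stats.beta.ppf(0.025, k, n - k + 1))
    hi = 1.0 if k == n else float(stats.beta.ppf(0.975, k + 1, n - k))
    return lo, hi


def _check_models(models: Sequence[str]) -> list[str]:
    models = list(models)
    bad = [m for m in models if m not in VALID_MODELS]
    if bad:
        raise ConfigError(f"unknown models: {bad}")
    return models


def _genotype_sampler(cfg: TwinSimConfig) -> Callable[[np.random.Generator], np.ndarray]:
    one = replace(cfg, n_snps=1)

    def sampler(rng: np.random.Generator) -> np.ndarray:
        return _simulate_genotype_columns(one, rng)[:, 0]

    return sampler


def type1_error_study(
    cfg: TwinSimConfig,
    models: Sequence[str] = VALID_MODELS,
    n_replications: int = 1000,
    alpha: float = 0.05,
    calibration: str = "shared_null",
    seed: Optional[int] = None,
    gcc_folds: int = 10,
    gcc_weight_grid: Optional[Sequence[float]] = None,
    gcc_n_perm: Optional[int] = None,
) -> SimStudyResult:
    """Estimate empirical type-I error: replications of one null SNP against
    an independent phenotype, each tested at nominal ``alpha``.

    With ``calibration="shared_null"`` the GCC null distribution is built
    once (fresh genotype draws paired with permuted phenotypes) and reused
    across replications — valid because all replications share the same
    marginal structure; ``per_replication`` runs a full permutation test in
    every replication instead.
    """
    if cfg.effect_model != "null":
        raise MisuseError("type1_error_study requires effect_model='null'")
    if n_replications < 100:
        raise MisuseError(
            f"n_replications={n_replications} too small for a stable rate (need >= 100)"
        )
    if calibration not in ("shared_null", "per_replication"):
        raise ConfigError(f"unknown calibration {calibration!r}")
    models = _check_models(models)
    seed = cfg.seed if seed is None else seed
    grid = _check_weight_grid(gcc_weight_grid)

    _, skeleton = simulate_twin_genotypes(cfg)
    fam = skeleton.family_ids
    need_k = "kinship" in models
    K: Optional[KinshipMatrix] = build_kinship(skeleton) if need_k else None

    sampler = _genotype_sampler(cfg)
    root = np.random.default_rng(np.random.SeedSequence([seed % (2**31), 0x7E1]))

    def y_sampler(rng: np.random.Generator) -> np.ndarray:
        # independent phenotype draw with the replications' marginal structure
        return simulate_phenotype(sampler(rng), skeleton, cfg, rng=rng).phenotype

    calib: Optional[NullCalibration] = None
    if "gcc" in models and calibration == "shared_null":
        calib = shared_null_calibration(
            sampler,
            y_sampler(root),
            n_perm=gcc_n_perm or 999,
            folds=gcc_folds,
            weight_grid=grid,
            seed=int(root.integers(2**31)),
            family=fam,
            y_sampler=y_sampler,
        )

    rejections = {m: 0 for m in models}
    for rep in range(n_replications):
        g = sampler(root)
        y = simulate_phenotype(g, skeleton, cfg, rng=root).phenotype
        for m in models:
            if m == "gcc":
                if calibration == "shared_null":
                    ws = _GccWorkspace(g, y, gcc_folds, seed=int(root.integers(2**31)))
                    p = calib.pvalue(ws.fit(grid).cvlrs_test)
                else:
                    p = gcc_pvalue(
                        g, y, folds=gcc_folds, weight_grid=grid,
                        n_perm=gcc_n_perm or 99, seed=int(root.integers(2**31)),
                        family=fam,
                    ).pvalue
            elif m == "kinship":
                p = fit_kinship_gls(y, g, None, K).pvalue
            else:
                p = fit_lme_pair(y, g, None, fam).pvalue
            if p < alpha:
                rejections[m] += 1

    return SimStudyResult(
        alpha=alpha,
        n_replications=n_replications,
        rejection_rate={m: rejections[m] / n_replications for m in models},
        ci95={m: _binom_ci95(rejections[m], n_replications) for m in models},
        calibration=calibration,
    )


def power_study(
    cfgs: Sequence[TwinSimConfig],
    models: Sequence[str] = VALID_MODELS,
    n_replications: int = 200,
    alpha: float = 1e-3,
    seed: int = 0,
    gcc_folds: int = 10,
    gcc_weight_grid: Optional[Sequence[float]] = None,
    gcc_n_perm: int = 999,
) -> pd.DataFrame:
    """Rejection rates across a grid of non-null simulation configurations.

    GCC uses a shared permutation null per grid cell (genotype redraws paired
    with permutations of a representative phenotype — permutation destroys
    the genotype-phenotype dependence while preserving both marginals), with
    generalized-Pareto tail quantiles when ``alpha`` is below empirical
    resolution.
    """
    cfgs = list(cfgs)
    if not cfgs:
        raise ConfigError("empty configuration grid")
    for c in cfgs:
        if c.effect_model == "null" or c.effect_size == 0.0:
            raise MisuseError(
                "power_study cells must have a non-null effect "
                "(use type1_error_study for the null)"
            )
    models = _check_models(models)
    grid = _check_weight_grid(gcc_weight_grid)
    rows = []
    root = np.random.default_rng(np.random.SeedSequence([seed % (2**31), 0x90E]))
    for cfg in cfgs:
        _, skeleton = simulate_twin_genotypes(cfg)
        fam = skeleton.family_ids
        K = build_kinship(skeleton) if "kinship" in models else None
        sampler = _genotype_sampler(cfg)

        threshold = None
        if "gcc" in models:
            def y_sampler(rng: np.random.Generator, _cfg=cfg) -> np.ndarray:
                # phenotype from an independent genotype draw: preserves the
                # alternative's y marginal and clustering, breaks dependence
                return simulate_phenotype(
                    sampler(rng), skeleton, _cfg, rng=rng
                ).phenotype

            calib = shared_null_calibration(
                sampler, y_sampler(root), n_perm=gcc_n_perm, folds=gcc_folds,
                weight_grid=grid, seed=int(root.integers(2**31)), family=fam,
                y_sampler=y_sampler,
            )
            method = (
                "empirical" if (alpha >= 1.0 / (gcc_n_perm + 1.0)) else "gpd_tail"
            )
            threshold = calib.quantile(1.0 - alpha, method=method)

        rejections = {m: 0 for m in models}
        for rep in range(n_replications):
            g = sampler(root)
            y = simulate_phenotype(g, skeleton, cfg, rng=root).phenotype
            for m in models:
                if m == "gcc":
                    ws = _GccWorkspace(g, y, gcc_folds, seed=int(root.integers(2**31)))
                    hit = ws.fit(grid).cvlrs_test > threshold
                elif m == "kinship":
                    hit = fit_kinship_gls(y, g, None, K).pvalue < alpha
                else:
                    hit = fit_lme_pair(y, g, None, fam).pvalue < alpha
                rejections[m] += bool(hit)
        for m in models:
            lo, hi = _binom_ci95(rejections[m], n_replications)
            rows.append(
                {
                    "effect_model": cfg.effect_model,
                    "effect_size": cfg.effect_size,
                    "model": m,
                    "rejection_rate": rejections[m] / n_replications,
                    "ci95_low": lo,
                    "ci95_high": hi,
                    "n_replications": n_replications,
                    "alpha": alpha,
                }
            )
    return pd.DataFrame(rows)
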