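"""Genome-wide scan orchestration: covariate adjustment, optional Box-Cox
normalization, per-SNP testing under any of the three models, genomic
inflation, and plotting tables.

The phenotype is adjusted once per scan — Box-Cox first when requested, then
least-squares residualization on the covariates (age and sex by default) —
and the residual is tested against every retained SNP. The GCC, being a
bivariate dependence measure, takes the residual directly; the linear models
test the residual against dosage with the twin covariance. GCC p-values use
per-SNP permutation with a two-stage scheme at scan scale: a coarse screen,
then full calibration with a generalized-Pareto tail for SNPs passing it.

Genomic inflation is the usual lambda_GC: the median of the chi-square(1)
quantiles of the observed p-values over the null median 0.4549364.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    ConfigError,
    DegenerateInputError,
    JoinError,
    RankError,
    SampleSizeError,
)
from .gcc_core import _check_weight_grid, gcc_pvalue
from .io_gwas import AssocResult, DosageMatrix, PhenoTable, filter_variants
from .linear_models import build_kinship, fit_kinship_gls, fit_lme_pair

logger = logging.getLogger("gccscan")

__all__ = [
    "ScanConfig",
    "ScanReport",
    "adjust_phenotype",
    "boxcox_transform",
    "run_scan",
    "genomic_inflation",
    "qq_table",
    "manhattan_table",
    "genotype_density_table",
]

CHI2_1_MEDIAN = 0.4549364231195724  # median of chi-square with 1 df


@dataclass
class ScanConfig:
    """Scan settings; defaults mirror conventional GWAS practice: MAF >= 5%,
    INFO > 0.6, genome-wide threshold 5e-8, suggestive 1e-5."""

    model: str = "gcc"
    covariates: tuple[str, ...] = ("age", "sex")
    boxcox: bool = False
    maf_min: float = 0.05
    info_min: float = 0.6
    gw_threshold: float = 5e-8
    suggestive_threshold: float = 1e-5
    folds: int = 10
    weight_grid: Optional[Sequence[float]] = None
    n_perm: int = 999
    screen_n_perm: int = 99
    screen_alpha: float = 0.01
    tail_method: str = "gpd_tail"
    varcomp_mode: str = "null_once"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model not in ("gcc", "kinship", "lme"):
            raise ConfigError(f"unknown model {self.model!r}")
        for t in (self.gw_threshold, self.suggestive_threshold):
            if not (0.0 < t < 1.0):
                raise ConfigError(f"threshold {t} outside (0, 1)")
        if self.gw_threshold > self.suggestive_threshold:
            raise ConfigError("gw_threshold must be <= suggestive_threshold")


@dataclass
class ScanReport:
    results: list[AssocResult]
    lambda_gc: float
    n_gw_significant: int
    n_suggestive: int
    skipped: list[tuple[str, str]] = field(default_factory=list)
    config: Optional[ScanConfig] = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "snp_id": r.snp_id, "chrom": r.chrom, "pos": r.pos,
                    "model": r.model, "statistic": r.statistic, "beta": r.beta,
                    "se": r.se, "pvalue": r.pvalue, "n_used": r.n_used,
                }
                for r in self.results
            ]
        )


# ---------------------------------------------------------------------------
# Phenotype preparation
# ---------------------------------------------------------------------------

def _covariate_matrix(pheno: PhenoTable, covariates: Sequence[str]) -> np.ndarray:
    cols = []
    for c in covariates:
        if c not in pheno.data.columns:
            raise ConfigError(f"covariate column {c!r} not in phenotype table")
        col = pheno.data[c]
        if c == "sex" or col.dtype == object:
            col = pd.factorize(col)[0].astype(float)
        else:
            col = col.to_numpy(dtype=float)
        cols.append(np.asarray(col, dtype=float))
    return np.column_stack(cols) if cols else np.empty((pheno.n, 0))


def adjust_phenotype(
    pheno: PhenoTable, covariates: Sequence[str] = ("age", "sex")
) -> np.ndarray:
    """Residuals of the phenotype regressed on an intercept plus covariates.

    Residuals are exactly orthogonal to every covariate; a rank-deficient
    (collinear) design raises.
    """
    y = pheno.phenotype
    if np.any(~np.isfinite(y)):
        raise DegenerateInputError("phenotype contains missing/non-finite values")
    X = _covariate_matrix(pheno, covariates)
    W = np.column_stack([np.ones(pheno.n), X])
    if np.linalg.matrix_rank(W) < W.shape[1]:
        raise RankError(f"collinear covariates {tuple(covariates)}")
    beta, *_ = np.linalg.lstsq(W, y, rcond=None)
    return y - W @ beta


BOXCOX_LAMBDA_GRID = np.round(np.arange(-2.0, 2.0 + 1e-9, 0.01), 2)


def boxcox_transform(y: np.ndarray) -> tuple[np.ndarray, float, float]:
    """Box-Cox power transform with lambda chosen by profile likelihood over
    a grid on [-2, 2] (step 0.01). Non-positive inputs are first shifted by
    1 - min(y); returns (transformed, lambda, shift)."""
    y = np.asarray(y, dtype=float).ravel()
    if y.size < 10:
        raise SampleSizeError(f"Box-Cox needs >= 10 observations, got {y.size}")
    if np.ptp(y) == 0.0:
        raise DegenerateInputError("constant vector passed to Box-Cox")
    shift = 0.0
    if y.min() <= 0.0:
        shift = 1.0 - y.min()
        y = y + shift
    llf = np.array([stats.boxcox_llf(l, y) for l in BOXCOX_LAMBDA_GRID])
    lam = float(BOXCOX_LAMBDA_GRID[int(np.argmax(llf))])
    yt = np.log(y) if lam == 0.0 else (y**lam - 1.0) / lam
    return yt, lam, shift


# ---------------------------------------------------------------------------
# The scan
# ---------------------------------------------------------------------------

def run_scan(dm: DosageMatrix, pheno: PhenoTable, cfg: ScanConfig) -> ScanReport:
    """Test every retained SNP against the adjusted phenotype under the
    configured model and summarize genomic inflation and threshold counts.

    Samples are matched by id (dosage-matrix order); SNPs failing the
    MAF/INFO filters are excluded, monomorphic SNPs are skipped with a
    logged reason, and samples with a missing dosage are dropped pairwise
    per SNP.
    """
    common = [s for s in dm.samples if s in set(pheno.sample_ids)]
    if not common:
        raise JoinError("no overlap between dosage-matrix and phenotype sample ids")
    dm = dm.subset_samples([dm.samples.index(s) for s in common])
    pheno = pheno.subset(common)

    y = pheno.phenotype
    if cfg.boxcox:
        y_t, lam, shift = boxcox_transform(y)
        logger.info("Box-Cox: lambda=%.2f shift=%.3g", lam, shift)
        ph = PhenoTable(pheno.data.assign(phenotype=y_t))
    else:
        ph = pheno
    resid = adjust_phenotype(ph, cfg.covariates)

    dm = filter_variants(dm, maf_min=cfg.maf_min, info_min=cfg.info_min)
    fam = ph.family_ids
    K = build_kinship(ph) if cfg.model == "kinship" else None

    grid = _check_weight_grid(cfg.weight_grid)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed % (2**31), 0x5CA]))
    results: list[AssocResult] = []
    skipped: list[tuple[str, str]] = []
    for j, meta in enumerate(dm.snps):
        g_full = dm.values[:, j]
        used = np.isfinite(g_full)
        g = g_full[used]
        if np.unique(g).size < 2:
            skipped.append((meta.snp_id, "monomorphic"))
            logger.info("skipping %s: monomorphic", meta.snp_id)
            continue
        yj = resid[used]
        fj = fam[used]
        n_used = int(used.sum())
        if cfg.model == "gcc":
            res = _gcc_scan_test(g, yj, fj, cfg, rng)
            result = AssocResult(
                snp_id=meta.snp_id, model="gcc", statistic=res[0], pvalue=res[1],
                n_used=n_used, chrom=meta.chrom, pos=meta.pos,
            )
        elif cfg.model == "kinship":
            if n_used == dm.n_samples:
                fit = fit_kinship_gls(yj, g, None, K, varcomp_mode=cfg.varcomp_mode)
            else:
                sub = pheno.subset([s for s, u in zip(dm.samples, used) if u])
                fit = fit_kinship_gls(yj, g, None, build_kinship(sub),
                                      varcomp_mode=cfg.varcomp_mode)
            result = AssocResult(
                snp_id=meta.snp_id, model="kinship", statistic=fit.wald_z,
                pvalue=fit.pvalue, beta=fit.beta, se=fit.se, n_used=n_used,
                chrom=meta.chrom, pos=meta.pos,
            )
        else:
            fit = fit_lme_pair(yj, g, None, fj)
            result = AssocResult(
                snp_id=meta.snp_id, model="lme", statistic=fit.wald_z,
                pvalue=fit.pvalue, beta=fit.beta, se=fit.se, n_used=n_used,
                chrom=meta.chrom, pos=meta.pos,
            )
        results.append(result)

    pvals = np.array([r.pvalue for r in results])
    lam_gc = genomic_inflation(pvals) if pvals.size else float("nan")
    return ScanReport(
        results=results,
        lambda_gc=lam_gc,
        n_gw_significant=int((pvals < cfg.gw_threshold).sum()),
        n_suggestive=int((pvals < cfg.suggestive_threshold).sum()),
        skipped=skipped,
        config=cfg,
    )


def _gcc_scan_test(g, yj, fj, cfg: ScanConfig, rng) -> tuple[float, float]:
    """Two-stage GCC permutation test for one SNP: coarse screen, then full
    calibration only for SNPs passing it (no effect on top hits, large effect
    on scan runtime)."""
    screen = gcc_pvalue(
        g, yj, folds=cfg.folds, weight_grid=cfg.weight_grid,
        n_perm=cfg.screen_n_perm, tail_method="empirical",
        seed=int(rng.integers(2**31)), family=fj,
    )
    if screen.pvalue > cfg.screen_alpha:
        return screen.fit.cvlrs, screen.pvalue
    full = gcc_pvalue(
        g, yj, folds=cfg.folds, weight_grid=cfg.weight_grid,
        n_perm=cfg.n_perm, tail_method=cfg.tail_method,
        seed=int(rng.integers(2**31)), family=fj,
    )
    return full.fit.cvlrs, full.pvalue


# ---------------------------------------------------------------------------
# Summaries and plotting tables
# ---------------------------------------------------------------------------

def genomic_inflation(pvalues: np.ndarray) -> float:
    """lambda_GC = median(qchisq(1 - p, 1)) / 0.4549364."""
    p = np.asarray(pvalues, dtype=float).ravel()
    if p.size == 0:
        raise ConfigError("genomic_inflation requires at least one p-value")
    if np.any(p <= 0.0) or np.any(p > 1.0):
        raise ConfigError("p-values must lie in (0, 1]")
    return float(np.median(stats.chi2.isf(p, df=1)) / CHI2_1_MEDIAN)


def qq_table(pvalues: np.ndarray) -> pd.DataFrame:
    """Expected vs observed -log10 p for a QQ plot; expected quantiles are
    i/(n+1) for the i-th smallest p-value."""
    p = np.sort(np.asarray(pvalues, dtype=float).ravel())
    if p.size == 0:
        raise ConfigError("qq_table requires at least one p-value")
    n = p.size
    expected = np.arange(1, n + 1) / (n + 1.0)
    return pd.DataFrame(
        {"expected_neglog10": -np.log10(expected), "observed_neglog10": -np.log10(p)}
    )


def manhattan_table(results: Sequence[AssocResult]) -> pd.DataFrame:
    """(chrom, pos, -log10 p) sorted by genomic coordinate."""
    if not results:
        raise ConfigError("manhattan_table requires at least one result")
    df = pd.DataFrame(
        {
            "chrom": [r.chrom for r in results],
            "pos": [r.pos for r in results],
            "neglog10_p": [-np.log10(r.pvalue) for r in results],
            "snp_id": [r.snp_id for r in results],
        }
    )
    key = pd.to_numeric(df["chrom"], errors="coerce")
    df = df.assign(_ck=key).sort_values(["_ck", "chrom", "pos"]).drop(columns="_ck")
    return df.reset_index(drop=True)


def genotype_density_table(g: np.ndarray, y: np.ndarray) -> dict[int, np.ndarray]:
    """Phenotype values per rounded genotype class {0, 1, 2} — the table
    behind genotype-specific density (violin/bean) plots."""
    g = np.asarray(g, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if g.size != y.size or g.size == 0:
        raise ConfigError("genotype and phenotype vectors must match and be nonempty")
    classes = np.clip(np.rint(g), 0, 2).astype(int)
    return {k: y[classes == k] for k in np.unique(classes)}
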