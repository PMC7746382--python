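"""Twin-aware linear comparator models: kinship GLS and a pair mixed model.

Two conventional corrections for the within-pair correlation of twin samples:

* ``fit_kinship_gls``: generalized least squares with phenotypic covariance
  sigma2_g * K + sigma2_e * I, where K is the expected additive relationship
  matrix (MZ co-twins 1, DZ co-twins 0.5, unrelated 0). Variance components
  are estimated by restricted maximum likelihood via a one-dimensional
  profile over the heritability ratio after rotating into the eigenbasis of
  K (the EMMA device); the SNP dosage effect is then a GLS Wald test.
* ``fit_lme_pair``: a random-intercept-per-pair linear mixed model
  (statsmodels MixedLM, maximum likelihood), Wald test on the dosage
  coefficient.

The relationship matrix uses the additive-relationship scaling (twice the
kinship coefficient) so the diagonal is exactly 1 and sigma2_g reads as
additive genetic variance; rescaling K leaves the Wald test unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import optimize, stats

from .errors import (
    ConvergenceError,
    MatrixError,
    RankError,
    StructureError,
)
from .io_gwas import PhenoTable

__all__ = [
    "KinshipMatrix",
    "MixedFit",
    "build_kinship",
    "fit_kinship_gls",
    "fit_lme_pair",
]

_RELATIONSHIP = {"MZ": 1.0, "DZ": 0.5}


@dataclass
class KinshipMatrix:
    """Expected additive relationship matrix in a fixed sample order.
    Block diagonal by family for a twin design; diagonal exactly 1."""

    samples: list[str]
    values: np.ndarray
    _eig: Optional[tuple] = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.samples), len(self.samples)):
            raise MatrixError("kinship matrix shape does not match sample count")
        if not np.allclose(v, v.T, atol=1e-12):
            raise MatrixError("kinship matrix is not symmetric")
        if not np.allclose(np.diag(v), 1.0, atol=1e-12):
            raise MatrixError("kinship diagonal must be exactly 1.0")
        self.values = v

    def eig(self) -> tuple[np.ndarray, np.ndarray]:
        """Cached eigendecomposition K = U diag(lam) U'. Raises on a
        non-PSD matrix."""
        if self._eig is None:
            lam, u = np.linalg.eigh(self.values)
            if lam.min() < -1e-8:
                raise MatrixError(
                    f"kinship matrix not positive semidefinite (min eig {lam.min():.3g})"
                )
            self._eig = (np.clip(lam, 0.0, None), u)
        return self._eig


def build_kinship(pheno: PhenoTable) -> KinshipMatrix:
    """Expected relationship matrix from family/zygosity structure:
    MZ co-twin 1.0, DZ co-twin 0.5, all other pairs 0."""
    n = pheno.n
    fam = pheno.family_ids
    zyg = pheno.zygosity
    K = np.eye(n)
    seen: dict[str, int] = {}
    for i in range(n):
        f = fam[i]
        if f in seen:
            j = seen[f]
            if zyg[i] not in _RELATIONSHIP:
                raise StructureError(
                    f"family {f!r} has two members but zygosity {zyg[i]!r}"
                )
            K[i, j] = K[j, i] = _RELATIONSHIP[zyg[i]]
        else:
            seen[f] = i
    return KinshipMatrix(samples=pheno.sample_ids, values=K)


@dataclass
class MixedFit:
    """SNP effect estimate from a twin-aware linear model."""

    beta: float
    se: float
    wald_z: float
    pvalue: float
    varcomp_genetic: float
    varcomp_residual: float
    n: int


def _design(y: np.ndarray, g: Optional[np.ndarray], X: Optional[np.ndarray]):
    y = np.asarray(y, dtype=float).ravel()
    cols = [np.ones(y.size)]
    if X is not None:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[0] != y.size:
            X = X.T
        cols.extend(X[:, j] for j in range(X.shape[1]))
    if g is not None:
        cols.append(np.asarray(g, dtype=float).ravel())
    W = np.column_stack(cols)
    if np.linalg.matrix_rank(W) < W.shape[1]:
        raise RankError("design matrix is rank deficient")
    return y, W


def _reml_h2(yr: np.ndarray, Wr: np.ndarray, lam: np.ndarray) -> tuple[float, float]:
    """Profile REML over h2 = sigma2_g / (sigma2_g + sigma2_e) in the rotated
    model with diagonal covariance sigma2 * (h2 * lam + 1 - h2).
    Returns (h2, sigma2)."""
    n, p = Wr.shape

    def neg_reml(h2: float) -> float:
        d = h2 * lam + (1.0 - h2)
        d = np.maximum(d, 1e-12)
        wi = 1.0 / d
        WtW = (Wr * wi[:, None]).T @ Wr
        Wty = (Wr * wi[:, None]).T @ yr
        try:
            beta = np.linalg.solve(WtW, Wty)
        except np.linalg.LinAlgError:
            return np.inf
        r = yr - Wr @ beta
        rss = float(r @ (wi * r))
        sigma2 = rss / (n - p)
        sign, logdet_wtw = np.linalg.slogdet(WtW)
        if sign <= 0:
            return np.inf
        return 0.5 * (
            (n - p) * np.log(sigma2) + np.log(d).sum() + logdet_wtw + (n - p)
        )

    res = optimize.minimize_scalar(
        neg_reml, bounds=(0.0, 1.0 - 1e-9), method="bounded",
        options={"xatol": 1e-8},
    )
    if not res.success or not np.isfinite(res.fun):
        raise ConvergenceError(f"REML profile failed: {res}")
    h2 = float(res.x)
    d = np.maximum(h2 * lam + (1.0 - h2), 1e-12)
    wi = 1.0 / d
    WtW = (Wr * wi[:, None]).T @ Wr
    beta = np.linalg.solve(WtW, (Wr * wi[:, None]).T @ yr)
    r = yr - Wr @ beta
    sigma2 = float(r @ (wi * r)) / (yr.size - Wr.shape[1])
    return h2, sigma2


def fit_kinship_gls(
    y: np.ndarray,
    g: np.ndarray,
    X: Optional[np.ndarray],
    K: KinshipMatrix,
    varcomp_mode: str = "null_once",
) -> MixedFit:
    """Kinship-covariance GLS Wald test of the SNP dosage effect.

    ``null_once`` estimates (h2, sigma2) by REML under the covariate-only
    model — the standard two-step GWAS shortcut, reusable across SNPs because
    K's eigendecomposition is cached on the matrix — while ``per_snp`` refits
    the variance components with the SNP in the design. The residual scale is
    re-estimated from the full-model GLS residuals, so with K = I the fit is
    exactly ordinary least squares.
    """
    if varcomp_mode not in ("null_once", "per_snp"):
        raise ValueError(f"unknown varcomp_mode {varcomp_mode!r}")
    lam, u = K.eig()
    y, W_full = _design(y, g, X)
    if y.size != len(K.samples):
        raise MatrixError(
            f"y has {y.size} entries but kinship matrix has {len(K.samples)}"
        )
    yr = u.T @ y
    Wr_full = u.T @ W_full
    if varcomp_mode == "null_once":
        Wr_null = Wr_full[:, :-1]
        h2, _ = _reml_h2(yr, Wr_null, lam)
    else:
        h2, _ = _reml_h2(yr, Wr_full, lam)

    d = np.maximum(h2 * lam + (1.0 - h2), 1e-12)
    wi = 1.0 / d
    WtW = (Wr_full * wi[:, None]).T @ Wr_full
    beta_hat = np.linalg.solve(WtW, (Wr_full * wi[:, None]).T @ yr)
    r = yr - Wr_full @ beta_hat
    n, p = Wr_full.shape
    sigma2 = float(r @ (wi * r)) / (n - p)
    cov = sigma2 * np.linalg.inv(WtW)
    beta = float(beta_hat[-1])
    se = float(np.sqrt(cov[-1, -1]))
    z = beta / se
    return MixedFit(
        beta=beta,
        se=se,
        wald_z=z,
        pvalue=float(2.0 * stats.norm.sf(abs(z))),
        varcomp_genetic=h2 * sigma2,
        varcomp_residual=(1.0 - h2) * sigma2,
        n=int(n),
    )


def fit_lme_pair(
    y: np.ndarray,
    g: np.ndarray,
    X: Optional[np.ndarray],
    pair_id: np.ndarray,
) -> MixedFit:
    """Random-intercept-per-pair mixed model (ML) with a Wald test on the
    dosage coefficient. Groups of size one (singletons) are allowed; groups
    larger than two violate the twin design.

    The random intercept induces an exchangeable 2x2 within-pair covariance,
    whose eigenvectors are the within-pair sum and difference; rotating onto
    them diagonalizes the likelihood, leaving a one-dimensional profile over
    the intraclass correlation. This is numerically identical to the generic
    ML fit (it agrees with statsmodels MixedLM to optimizer tolerance) at a
    fraction of the cost.
    """
    pair_id = np.asarray(pair_id)
    codes = np.unique(pair_id, return_inverse=True)[1]
    _, counts = np.unique(codes, return_counts=True)
    if counts.max() > 2:
        raise StructureError(f"group of size {counts.max()} (twin design allows <= 2)")
    y, W = _design(y, g, X)

    order = np.argsort(codes, kind="stable")
    ys_, Ws_, f = y[order], W[order], codes[order]
    first = np.flatnonzero(np.r_[True, np.diff(f) != 0])
    sizes = np.diff(np.r_[first, f.size])
    i1 = first[sizes == 2]
    i2 = i1 + 1
    singles = first[sizes == 1]
    sq2 = np.sqrt(2.0)
    yr = np.concatenate([(ys_[i1] + ys_[i2]) / sq2, (ys_[i1] - ys_[i2]) / sq2,
                         ys_[singles]])
    Wr = np.vstack([(Ws_[i1] + Ws_[i2]) / sq2, (Ws_[i1] - Ws_[i2]) / sq2,
                    Ws_[singles]])
    # within-pair correlation rho gives rotated variances 1 + rho * lam
    lam = np.concatenate([np.ones(i1.size), -np.ones(i1.size), np.zeros(singles.size)])
    n, p = Wr.shape

    def _profile(rho: float):
        d = np.maximum(1.0 + rho * lam, 1e-12)
        wi = 1.0 / d
        WtW = (Wr * wi[:, None]).T @ Wr
        beta = np.linalg.solve(WtW, (Wr * wi[:, None]).T @ yr)
        r = yr - Wr @ beta
        s2 = float(r @ (wi * r)) / n  # ML scale
        return d, wi, WtW, beta, s2

    def neg_ml(rho: float) -> float:
        d, _, _, _, s2 = _profile(rho)
        return 0.5 * (n * np.log(s2) + np.log(d).sum() + n)

    res = optimize.minimize_scalar(
        neg_ml, bounds=(0.0, 1.0 - 1e-9), method="bounded", options={"xatol": 1e-9}
    )
    if not res.success or not np.isfinite(res.fun):
        raise ConvergenceError(f"pair mixed-model profile failed: {res}")
    rho = float(res.x)
    _, wi, WtW, beta_hat, s2 = _profile(rho)
    cov = s2 * np.linalg.inv(WtW)
    beta = float(beta_hat[-1])
    se = float(np.sqrt(cov[-1, -1]))
    z = beta / se
    return MixedFit(
        beta=beta,
        se=se,
        wald_z=z,
        pvalue=float(2.0 * stats.norm.sf(abs(z))),
        varcomp_genetic=rho * s2,
        varcomp_residual=(1.0 - rho) * s2,
        n=int(n),
    )
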