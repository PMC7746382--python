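"""Generalized correlation coefficient (GCC) for bivariate dependence.

The statistic A generalizes R-squared through a density ratio. Two models are
compared on held-out data under k-fold cross-validation:

* null model: the variables are independent, so the joint density factorizes
  into the product of the two kernel-estimated marginals, P(x) P(y);
* alternative model: a mixture  w * P(x, y) + (1 - w) * P(x) P(y)  of a
  kernel-estimated joint (dependent) component and the independence component,
  with the mixture weight w chosen on the held-out likelihood.

With per-observation held-out densities the association strength is

    A = 1 - prod_i [ P(x_i, y_i | null) / P(x_i, y_i | alt) ]^(2/n),

which is 0 when the variables are independent (the mixture collapses onto the
null at w = 0) and approaches 1 under a deterministic relationship. For
bivariate Gaussian data A approaches the squared Pearson correlation; unlike
it, A also captures non-linear and non-monotone dependence. Significance uses
the cross-validation likelihood-ratio statistic

    CVLRS = -2 log( Lcv(Null) / Lcv(Alt) ),

calibrated by permutation of y (which preserves both marginals exactly, so
the null distribution is conditional on the observed marginal structure —
including, e.g., the within-pair correlation of twin phenotypes). P-values
beyond permutation resolution are extrapolated with a generalized-Pareto fit
to the permutation tail.

All kernel estimates use Gaussian product kernels with per-dimension
bandwidths computed once on the full sample (Silverman's rule by default,
d-dimensional rate n^(-1/(d+4))).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from scipy import stats
from scipy.special import logsumexp

from .errors import (
    ConfigError,
    DegenerateInputError,
    ResolutionError,
    SampleSizeError,
)

__all__ = [
    "DensityModel",
    "GccFit",
    "GccTestResult",
    "NullCalibration",
    "estimate_marginal",
    "estimate_joint",
    "product_of_marginals",
    "mixture_model",
    "fit_gcc",
    "gcc_pvalue",
    "shared_null_calibration",
    "DEFAULT_WEIGHT_GRID",
]

DEFAULT_WEIGHT_GRID = np.round(np.linspace(0.0, 1.0, 11), 2)
_MIN_N = 20
_DENSITY_FLOOR = 1e-300  # Gaussian kernels are positive; guard only underflow
_SQRT_2PI = np.sqrt(2.0 * np.pi)
# Fraction of the largest permutation statistics used for the GPD tail fit.
GPD_TAIL_FRACTION = 0.10
# Per-dimension shrink applied to the joint-density bandwidths relative to the
# univariate Silverman/Scott value. Undersmoothing the dependent component
# counters the saturation bias of the held-out likelihood ratio under strong
# dependence (A would otherwise plateau below 1) while the CV weight search
# still protects against overfitting under independence.
JOINT_BANDWIDTH_SHRINK = 0.85


# ---------------------------------------------------------------------------
# Bandwidths and density models
# ---------------------------------------------------------------------------

def _robust_sigma(x: np.ndarray) -> float:
    sd = float(np.std(x, ddof=1))
    q75, q25 = np.percentile(x, [75, 25])
    iqr = float(q75 - q25)
    if sd <= 0.0:
        raise DegenerateInputError("zero-variance input to density estimation")
    return min(sd, iqr / 1.349) if iqr > 0 else sd


def bandwidth(x: np.ndarray, rule: str = "silverman", d: int = 1) -> float:
    """Kernel bandwidth for one dimension of a d-dimensional estimate.

    silverman: (4 / (d + 2))^(1/(d+4)) * sigma * n^(-1/(d+4)), with the robust
    sigma = min(sd, IQR/1.349); reduces to 0.9 * sigma * n^(-1/5) at d = 1.
    scott: sigma * n^(-1/(d+4)).
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    sigma = _robust_sigma(x)
    if rule == "silverman":
        const = (4.0 / (d + 2.0)) ** (1.0 / (d + 4.0)) if d > 1 else 0.9
        return const * sigma * n ** (-1.0 / (d + 4.0))
    if rule == "scott":
        return sigma * n ** (-1.0 / (d + 4.0))
    raise ConfigError(f"unknown bandwidth rule {rule!r}")


@dataclass
class DensityModel:
    """A kernel density model: a marginal, a joint, the independence product,
    or a dependence/independence mixture."""

    kind: str  # marginal_x | marginal_y | joint | product_of_marginals | mixture
    bandwidths: np.ndarray
    training_points: np.ndarray  # (n, d)
    mixture_weight: Optional[float] = None
    components: tuple = field(default=(), repr=False)

    def logpdf(self, points: np.ndarray) -> np.ndarray:
        points = np.atleast_2d(np.asarray(points, dtype=float))
        if points.shape[1] != self.dim and points.shape[0] == self.dim:
            points = points.T
        if self.kind in ("marginal_x", "marginal_y", "joint"):
            return self._kde_logpdf(points)
        if self.kind == "product_of_marginals":
            mx, my = self.components
            return mx.logpdf(points[:, :1]) + my.logpdf(points[:, 1:2])
        if self.kind == "mixture":
            joint, prod = self.components
            w = self.mixture_weight
            lj = joint.logpdf(points)
            lp = prod.logpdf(points)
            if w <= 0.0:
                return lp
            if w >= 1.0:
                return lj
            return np.logaddexp(np.log(w) + lj, np.log1p(-w) + lp)
        raise ConfigError(f"unknown density kind {self.kind!r}")

    def pdf(self, points: np.ndarray) -> np.ndarray:
        return np.exp(self.logpdf(points))

    @property
    def dim(self) -> int:
        return self.training_points.shape[1]

    def _kde_logpdf(self, points: np.ndarray) -> np.ndarray:
        t = self.training_points
        h = self.bandwidths
        # sum over dims of log N((z_d - t_d)/h_d) - log h_d, logsumexp over train
        z = (points[:, None, :] - t[None, :, :]) / h[None, None, :]
        logk = -0.5 * np.sum(z * z, axis=2) - np.sum(np.log(h * _SQRT_2PI))
        return logsumexp(logk, axis=1) - np.log(t.shape[0])


def estimate_marginal(
    x: np.ndarray, bandwidth_rule: str = "silverman", kind: str = "marginal_x"
) -> DensityModel:
    """Gaussian-kernel estimate of a univariate density."""
    x = np.asarray(x, dtype=float).ravel()
    if x.size < 10:
        raise SampleSizeError(f"need at least 10 observations, got {x.size}")
    if not np.all(np.isfinite(x)):
        raise DegenerateInputError("non-finite values in density input")
    h = bandwidth(x, bandwidth_rule, d=1)
    return DensityModel(kind=kind, bandwidths=np.array([h]), training_points=x[:, None])


def estimate_joint(
    x: np.ndarray, y: np.ndarray, bandwidth_rule: str = "silverman"
) -> DensityModel:
    """Gaussian product-kernel estimate of the bivariate joint density
    (diagonal bandwidth matrix, per-dimension d=2 rates)."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    hx = JOINT_BANDWIDTH_SHRINK * bandwidth(x, bandwidth_rule, d=1)
    hy = JOINT_BANDWIDTH_SHRINK * bandwidth(y, bandwidth_rule, d=1)
    return DensityModel(
        kind="joint",
        bandwidths=np.array([hx, hy]),
        training_points=np.column_stack([x, y]),
    )


def product_of_marginals(mx: DensityModel, my: DensityModel) -> DensityModel:
    """Independence null: P(x, y) = P(x) P(y)."""
    return DensityModel(
        kind="product_of_marginals",
        bandwidths=np.concatenate([mx.bandwidths, my.bandwidths]),
        training_points=np.column_stack(
            [mx.training_points[:, 0], my.training_points[:, 0]]
        ),
        components=(mx, my),
    )


def mixture_model(joint: DensityModel, prod: DensityModel, weight: float) -> DensityModel:
    """Alternative: w * joint + (1 - w) * product of marginals."""
    if not 0.0 <= weight <= 1.0:
        raise ConfigError(f"mixture weight {weight} outside [0, 1]")
    return DensityModel(
        kind="mixture",
        bandwidths=joint.bandwidths,
        training_points=joint.training_points,
        mixture_weight=float(weight),
        components=(joint, prod),
    )


# ---------------------------------------------------------------------------
# Fit results
# ---------------------------------------------------------------------------

@dataclass
class GccFit:
    """Fitted GCC for one variable pair.

    ``cvlrs`` is the reported statistic (the weight search includes 0, so
    independence yields exactly 0 and A = 0). ``cvlrs_test`` is the
    permutation statistic: the likelihood ratio against the best strictly
    positive mixture weight, which is continuous under the null (no atom at
    0) and therefore yields uniform permutation p-values; the two agree
    whenever there is any evidence of dependence.
    """

    A: float
    mixture_weight: float
    cv_loglik_null: float
    cv_loglik_alt: float
    cvlrs: float
    n: int
    folds: int
    seed: int
    cvlrs_test: float = 0.0
    clamped: bool = False


@dataclass
class GccTestResult:
    fit: GccFit
    pvalue: float
    n_perm: int
    tail_method: str
    perm_stats: Optional[np.ndarray] = None


# ---------------------------------------------------------------------------
# Cross-validation workspace
#
# The held-out densities for every fold reduce to row sums of three n x n
# kernel matrices (marginal-y, joint-x, joint-y terms), minus the within-fold
# diagonal blocks. Permuting y is a symmetric row/column permutation of the
# y matrices, so a full permutation test re-uses the matrices and costs only
# gathers and sums per permutation. Bandwidths are fixed on the full sample
# (permutation invariant). Fold membership is fixed per workspace.
# ---------------------------------------------------------------------------

def _is_discrete(x: np.ndarray, max_levels: int = 10) -> bool:
    return np.unique(x).size <= max_levels


def _normal_scores(v: np.ndarray) -> np.ndarray:
    """Blom rank-based normal scores: Phi^-1((rank - 3/8) / (n + 1/4))."""
    ranks = np.empty(v.size)
    ranks[np.argsort(v, kind="stable")] = np.arange(1, v.size + 1)
    return stats.norm.ppf((ranks - 0.375) / (v.size + 0.25))


class _GccWorkspace:
    def __init__(
        self,
        x: np.ndarray,
        y: np.ndarray,
        folds: int,
        seed: int,
        bandwidth_rule: str = "silverman",
        jitter_discrete: bool = True,
        rank_normalize: bool = True,
    ) -> None:
        x = np.asarray(x, dtype=float).ravel()
        y = np.asarray(y, dtype=float).ravel()
        if x.size != y.size:
            raise ConfigError(f"length mismatch: |x|={x.size}, |y|={y.size}")
        n = x.size
        if n < _MIN_N:
            raise SampleSizeError(f"need at least {_MIN_N} observations, got {n}")
        if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
            raise DegenerateInputError("non-finite values in GCC input")
        if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
            raise DegenerateInputError("zero-variance input to GCC")
        if folds < 2 or folds > n:
            raise ConfigError(f"folds must be in [2, n], got {folds}")

        rng = np.random.default_rng(np.random.SeedSequence([int(seed) % (2**31), 0x6CC]))
        # Discrete variables (hard-call or near-hard genotype dosages) get a
        # deterministic jitter that breaks KDE degeneracy while keeping the
        # class structure; continuous variables are mapped to Blom normal
        # scores, which makes A exactly invariant under strictly monotone
        # rescaling and insensitive to outliers (for Gaussian data the scores
        # are essentially the data). Normal scores are not applied to
        # discrete variables — they would smear the genotype classes into
        # contiguous intervals and erase the class contrast.
        for name in ("x", "y"):
            v = x if name == "x" else y
            if _is_discrete(v):
                if jitter_discrete:
                    v = v + rng.uniform(-0.05, 0.05, size=n)
            elif rank_normalize:
                v = _normal_scores(v)
            if name == "x":
                x = v
            else:
                y = v
        if np.std(x) == 0.0 or np.std(y) == 0.0:
            raise DegenerateInputError("zero-variance input to GCC")

        # seeded shuffle -> contiguous fold slices in slot order
        order = rng.permutation(n)
        self.order = order
        self._inv_order = np.argsort(order)
        self.x = x[order]
        self.y = y[order]
        self.n = n
        self.folds = folds
        self.seed = int(seed)
        bounds = np.linspace(0, n, folds + 1).astype(int)
        self.fold_slices = [slice(bounds[k], bounds[k + 1]) for k in range(folds)]
        n_train = np.empty(n)
        for s in self.fold_slices:
            n_train[s] = n - (s.stop - s.start)
        self._n_train = n_train

        self.hx1 = bandwidth(self.x, bandwidth_rule, d=1)
        self.hy1 = bandwidth(self.y, bandwidth_rule, d=1)
        self.hx2 = JOINT_BANDWIDTH_SHRINK * self.hx1
        self.hy2 = JOINT_BANDWIDTH_SHRINK * self.hy1

        # Kernel matrices in float32: halves the memory traffic of the
        # permutation loop; sums are accumulated in float64.
        def kmat(v: np.ndarray, h: float) -> np.ndarray:
            z = (v[:, None] - v[None, :]).astype(np.float32) / np.float32(h)
            return np.exp(-0.5 * z * z)

        kx1 = kmat(self.x, self.hx1)
        self._ky1 = kmat(self.y, self.hy1)
        self._kx2 = kmat(self.x, self.hx2)
        self._ky2 = kmat(self.y, self.hy2)
        self._ky1_rowsum = self._ky1.sum(axis=1, dtype=np.float64)

        # held-out marginal-x densities: permutation invariant, compute once
        self._fx = self._heldout_rowmeans(kx1) / (self.hx1 * _SQRT_2PI)

    def _heldout_rowmeans(self, K: np.ndarray) -> np.ndarray:
        total = K.sum(axis=1, dtype=np.float64)
        for s in self.fold_slices:
            total[s] -= K[s, s].sum(axis=1, dtype=np.float64)
        return total / self._n_train

    def heldout_densities(self, pi: Optional[np.ndarray] = None):
        """Held-out null (product of marginals) and joint density at every
        observation, under permutation pi of the y slots.

        Permuting y is a symmetric row/column permutation of the y kernel
        matrices; the marginal-y term reduces to gathered precomputed row
        sums plus small within-fold corrections, and only the joint term
        needs the full n^2 pass.
        """
        if pi is None:
            ry = self._ky1_rowsum.copy()
            for s in self.fold_slices:
                ry[s] -= self._ky1[s, s].sum(axis=1, dtype=np.float64)
            joint = self._heldout_rowmeans(self._kx2 * self._ky2)
        else:
            # full-row sums of the permuted matrix are the permuted row sums
            ry = self._ky1_rowsum[pi]
            for s in self.fold_slices:
                ry[s] -= self._ky1[np.ix_(pi[s], pi[s])].sum(axis=1, dtype=np.float64)
            ky2p = self._ky2.take(pi, axis=0).take(pi, axis=1)
            joint = self._heldout_rowmeans(self._kx2 * ky2p)
        fy = (ry / self._n_train) / (self.hy1 * _SQRT_2PI)
        joint /= self.hx2 * self.hy2 * 2.0 * np.pi
        null = self._fx * fy
        np.maximum(null, _DENSITY_FLOOR, out=null)
        np.maximum(joint, _DENSITY_FLOOR, out=joint)
        return null, joint

    def to_slot_perm(self, pi_original: np.ndarray) -> np.ndarray:
        """Translate a permutation in original index space into the
        workspace's shuffled slot space."""
        return self._inv_order[pi_original[self.order]]

    def fit(
        self,
        weight_grid: np.ndarray,
        pi: Optional[np.ndarray] = None,
    ) -> GccFit:
        null, joint = self.heldout_densities(pi)
        ll_null = float(np.log(null).sum())
        best_w, best_ll = 0.0, ll_null
        best_ll_pos = None  # best over strictly positive weights
        for w in weight_grid:
            if w == 0.0:
                ll = ll_null
            else:
                ll = float(np.log(w * joint + (1.0 - w) * null).sum())
                if best_ll_pos is None or ll > best_ll_pos:
                    best_ll_pos = ll
            if ll > best_ll + 1e-12:
                best_w, best_ll = float(w), ll
        cvlrs = -2.0 * (ll_null - best_ll)
        cvlrs_test = 0.0 if best_ll_pos is None else -2.0 * (ll_null - best_ll_pos)
        raw_a = 1.0 - np.exp(-cvlrs / self.n)
        clamped = raw_a < 0.0 or raw_a > 1.0
        a = float(np.clip(raw_a, 0.0, 1.0))
        return GccFit(
            A=a,
            mixture_weight=best_w,
            cv_loglik_null=ll_null,
            cv_loglik_alt=best_ll,
            cvlrs=cvlrs,
            n=self.n,
            folds=self.folds,
            seed=self.seed,
            cvlrs_test=cvlrs_test,
            clamped=clamped,
        )


def block_permutation(
    family: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """A null-preserving permutation for family-structured samples.

    Returns indices ``pi`` such that ``y[pi]`` permutes whole family blocks
    of y across families of equal size (with a random within-pair flip),
    keeping the within-family clustering of y — the exchangeability unit for
    twin data — while breaking any dependence on x. Samples in different-size
    families are never mixed.
    """
    family = np.asarray(family)
    codes = np.unique(family, return_inverse=True)[1]
    n = codes.size
    pi = np.empty(n, dtype=np.intp)
    # slot lists per family, bucketed by family size
    order = np.argsort(codes, kind="stable")
    sorted_codes = codes[order]
    first = np.flatnonzero(np.r_[True, np.diff(sorted_codes) != 0])
    sizes = np.diff(np.r_[first, n])
    for s in np.unique(sizes):
        blocks = np.stack(
            [order[f : f + s] for f in first[sizes == s]]
        )  # (m, s) slot indices
        m = blocks.shape[0]
        src = blocks[rng.permutation(m)]
        if s == 2:  # co-twins are exchangeable
            flip = rng.integers(0, 2, m).astype(bool)
            src[flip] = src[flip][:, ::-1]
        pi[blocks.ravel()] = src.ravel()
    return pi


def _permutation_factory(
    n: int, family: Optional[np.ndarray], rng: np.random.Generator
) -> Callable[[], np.ndarray]:
    """Individual permutations without structure, family-block permutations
    with it."""
    if family is None:
        return lambda: rng.permutation(n)
    family = np.asarray(family)
    if family.size != n:
        raise ConfigError(f"family vector length {family.size} != n {n}")
    return lambda: block_permutation(family, rng)


def _check_weight_grid(weight_grid) -> np.ndarray:
    grid = np.asarray(
        DEFAULT_WEIGHT_GRID if weight_grid is None else weight_grid, dtype=float
    ).ravel()
    if grid.size == 0 or grid.min() < 0.0 or grid.max() > 1.0:
        raise ConfigError("weight_grid must be a non-empty subset of [0, 1]")
    if not np.any(grid == 0.0):
        raise ConfigError("weight_grid must contain 0 (the independence model)")
    return np.sort(grid)


def fit_gcc(
    x: np.ndarray,
    y: np.ndarray,
    folds: int = 10,
    weight_grid: Optional[Sequence[float]] = None,
    seed: int = 0,
    bandwidth_rule: str = "silverman",
    jitter_discrete: bool = True,
    rank_normalize: bool = True,
) -> GccFit:
    """Fit the GCC: held-out null/alternative likelihoods under k-fold CV,
    mixture weight by grid search, the A statistic and the CVLRS.

    The fold assignment is a seeded shuffle; ties in the weight search go to
    the smaller weight, so independent data yield w = 0, CVLRS = 0, A = 0.
    """
    grid = _check_weight_grid(weight_grid)
    ws = _GccWorkspace(x, y, folds, seed, bandwidth_rule, jitter_discrete,
                       rank_normalize)
    return ws.fit(grid)


# ---------------------------------------------------------------------------
# Permutation p-values with generalized-Pareto tail extrapolation
# ---------------------------------------------------------------------------

def _gpd_tail_fit(null_stats: np.ndarray):
    """Fit a generalized Pareto to exceedances over the upper-tail threshold.
    Returns (threshold, tail_fraction, shape, scale) or None if the tail is
    degenerate."""
    ns = np.sort(np.asarray(null_stats, dtype=float))
    n_tail = max(int(np.ceil(GPD_TAIL_FRACTION * ns.size)), 10)
    if n_tail >= ns.size:
        return None
    u = ns[-n_tail - 1]
    exc = ns[ns > u] - u
    if exc.size < 10 or np.ptp(exc) <= 0:
        return None
    try:
        c, _, scale = stats.genpareto.fit(exc, floc=0.0)
    except Exception:
        return None
    if not np.isfinite(c) or not np.isfinite(scale) or scale <= 0:
        return None
    return u, exc.size / ns.size, c, scale


def _tail_pvalue(obs: float, null_stats: np.ndarray, n_perm: int, tail_method: str) -> float:
    n_ge = int(np.sum(null_stats >= obs))
    p_emp = (1.0 + n_ge) / (n_perm + 1.0)
    if tail_method == "empirical" or n_ge > 0:
        return p_emp
    gpd = _gpd_tail_fit(null_stats)
    if gpd is None:
        return p_emp
    u, frac, c, scale = gpd
    if obs <= u:
        return p_emp
    p = frac * float(stats.genpareto.sf(obs - u, c, loc=0.0, scale=scale))
    return float(np.clip(p, 1e-300, p_emp))


def gcc_pvalue(
    x: np.ndarray,
    y: np.ndarray,
    folds: int = 10,
    weight_grid: Optional[Sequence[float]] = None,
    n_perm: int = 999,
    tail_method: str = "gpd_tail",
    seed: int = 0,
    bandwidth_rule: str = "silverman",
    family: Optional[np.ndarray] = None,
    keep_perm_stats: bool = False,
) -> GccTestResult:
    """Permutation test of independence based on the CVLRS.

    Null statistics come from re-fitting on (x, permuted y): both marginals
    are preserved exactly, so the null is conditional on the observed marginal
    structure. When ``family`` gives a family/pair id per sample, y is
    permuted in whole family blocks (the exchangeability unit for twin data,
    preserving the within-pair clustering of y); otherwise individual
    permutation is used. Empirical p = (1 + #{null >= observed}) /
    (n_perm + 1); when the observed statistic exceeds every permutation and
    ``tail_method`` is ``gpd_tail``, a generalized-Pareto fit to the top of
    the null statistics extrapolates below the 1/(n_perm + 1) resolution.
    """
    if n_perm < 19:
        raise ResolutionError(
            f"n_perm={n_perm} cannot resolve alpha=0.05; need >= 19 permutations"
        )
    if tail_method not in ("empirical", "gpd_tail"):
        raise ConfigError(f"unknown tail_method {tail_method!r}")
    grid = _check_weight_grid(weight_grid)
    ws = _GccWorkspace(x, y, folds, seed, bandwidth_rule)
    fit = ws.fit(grid)
    prng = np.random.default_rng(np.random.SeedSequence([int(seed) % (2**31), 0x9E1]))
    next_perm = _permutation_factory(ws.n, family, prng)
    null_stats = np.empty(n_perm)
    for b in range(n_perm):
        pi = ws.to_slot_perm(next_perm())
        null_stats[b] = ws.fit(grid, pi=pi).cvlrs_test
    pval = _tail_pvalue(fit.cvlrs_test, null_stats, n_perm, tail_method)
    return GccTestResult(
        fit=fit,
        pvalue=pval,
        n_perm=n_perm,
        tail_method=tail_method,
        perm_stats=null_stats if keep_perm_stats else None,
    )


# ---------------------------------------------------------------------------
# Shared null calibration for repeated tests with identical marginal structure
# ---------------------------------------------------------------------------

@dataclass
class NullCalibration:
    """A reusable null distribution of the continuous permutation statistic
    (``GccFit.cvlrs_test``), built from fresh genotype draws paired with
    independent/permuted phenotypes. Valid for repeated tests whose variables
    share the same marginal structure (the simulation studies)."""

    stats: np.ndarray  # sorted ascending
    n_perm: int
    gpd: Optional[tuple] = None  # (threshold, tail_fraction, shape, scale)

    def pvalue(self, observed: float, tail_method: str = "gpd_tail") -> float:
        """P-value for an observed ``cvlrs_test`` statistic."""
        return _tail_pvalue(observed, self.stats, self.n_perm, tail_method)

    def quantile(self, q: float, method: str = "empirical") -> float:
        """Upper quantile of the null CVLRS distribution.

        The empirical method resolves quantiles up to 1 - 1/(n_perm + 1);
        beyond that, ``gpd_tail`` extrapolates from the fitted tail.
        """
        if not 0.0 < q < 1.0:
            raise ConfigError(f"quantile level {q} outside (0, 1)")
        if method == "empirical":
            if (1.0 - q) < 1.0 / (self.n_perm + 1.0):
                raise ResolutionError(
                    f"quantile {q} unresolvable with {self.n_perm} null statistics"
                )
            return float(np.quantile(self.stats, q, method="higher"))
        if method == "gpd_tail":
            if self.gpd is not None:
                u, frac, c, scale = self.gpd
                if (1.0 - q) < frac:
                    return u + float(
                        stats.genpareto.isf((1.0 - q) / frac, c, loc=0.0, scale=scale)
                    )
            return self.quantile(q, method="empirical")
        raise ConfigError(f"unknown quantile method {method!r}")


def shared_null_calibration(
    x_sampler: Callable[[np.random.Generator], np.ndarray],
    y: np.ndarray,
    n_perm: int = 999,
    folds: int = 10,
    weight_grid: Optional[Sequence[float]] = None,
    seed: int = 0,
    bandwidth_rule: str = "silverman",
    family: Optional[np.ndarray] = None,
    y_sampler: Optional[Callable[[np.random.Generator], np.ndarray]] = None,
) -> NullCalibration:
    """Build a null CVLRS table shared across tests with the same marginals.

    Each null draw pairs a fresh genotype vector from ``x_sampler`` with an
    independent phenotype vector: a draw from ``y_sampler`` when one is given
    (the right choice for simulation studies, where the level of the CVLRS
    varies with the realized phenotype vector), otherwise a permutation of
    the fixed ``y`` (family-block permutation when ``family`` is given, so
    the within-pair clustering of twin phenotypes is kept under the null).
    The GCC is fitted to every draw; the sorted statistics plus a
    generalized-Pareto tail fit provide quantile and p-value lookups.
    """
    if n_perm < 199:
        raise ResolutionError(
            f"shared null calibration needs >= 199 permutations, got {n_perm}"
        )
    grid = _check_weight_grid(weight_grid)
    y = np.asarray(y, dtype=float).ravel()
    root = np.random.default_rng(np.random.SeedSequence([int(seed) % (2**31), 0x5A11]))
    next_perm = _permutation_factory(y.size, family, root)
    stats_out = np.empty(n_perm)
    for b in range(n_perm):
        xb = np.asarray(x_sampler(root), dtype=float).ravel()
        if y_sampler is not None:
            yb = np.asarray(y_sampler(root), dtype=float).ravel()
        else:
            yb = y[next_perm()]
        ws = _GccWorkspace(xb, yb, folds, seed=int(root.integers(2**31)),
                           bandwidth_rule=bandwidth_rule)
        stats_out[b] = ws.fit(grid).cvlrs_test
    stats_sorted = np.sort(stats_out)
    return NullCalibration(
        stats=stats_sorted, n_perm=n_perm, gpd=_gpd_tail_fit(stats_sorted)
    )
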