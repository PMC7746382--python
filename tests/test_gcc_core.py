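import numpy as np
import pytest
from scipy import stats

from gccscan.errors import (
    ConfigError,
    DegenerateInputError,
    ResolutionError,
    SampleSizeError,
)
from gccscan.gcc_core import (
    DEFAULT_WEIGHT_GRID,
    NullCalibration,
    block_permutation,
    estimate_joint,
    estimate_marginal,
    fit_gcc,
    gcc_pvalue,
    mixture_model,
    product_of_marginals,
    shared_null_calibration,
)


class TestMarginalDensity:
    def test_standard_normal_density_at_zero(self, rng):
        x = rng.standard_normal(10_000)
        model = estimate_marginal(x)
        assert model.pdf(np.array([[0.0]]))[0] == pytest.approx(0.3989, abs=0.05)

    def test_density_integrates_to_one(self, rng):
        x = rng.standard_normal(2_000)
        model = estimate_marginal(x)
        grid = np.linspace(-6, 6, 2001)
        integral = np.trapezoid(model.pdf(grid[:, None]), grid)
        assert integral == pytest.approx(1.0, abs=0.01)

    def test_constant_vector_is_degenerate(self):
        with pytest.raises(DegenerateInputError):
            estimate_marginal(np.full(100, 3.0))

    def test_too_few_points_rejected(self):
        with pytest.raises(SampleSizeError):
            estimate_marginal(np.arange(5.0))

    def test_density_strictly_positive_far_from_data(self, rng):
        x = rng.standard_normal(200)
        model = estimate_marginal(x)
        assert np.all(model.pdf(np.array([[8.0], [-8.0]])) > 0.0)
        assert np.all(np.isfinite(model.logpdf(np.array([[50.0], [-50.0]]))))


class TestDensityModels:
    def test_mixture_interpolates_joint_and_product(self, rng):
        x = rng.standard_normal(300)
        y = 0.7 * x + 0.5 * rng.standard_normal(300)
        joint = estimate_joint(x, y)
        prod = product_of_marginals(
            estimate_marginal(x, kind="marginal_x"),
            estimate_marginal(y, kind="marginal_y"),
        )
        pts = np.column_stack([x[:20], y[:20]])
        for w in (0.0, 0.4, 1.0):
            mix = mixture_model(joint, prod, w)
            expected = w * joint.pdf(pts) + (1 - w) * prod.pdf(pts)
            np.testing.assert_allclose(mix.pdf(pts), expected, rtol=1e-10)

    def test_invalid_weight_rejected(self, rng):
        x = rng.standard_normal(100)
        joint = estimate_joint(x, x + rng.standard_normal(100))
        prod = product_of_marginals(estimate_marginal(x), estimate_marginal(x))
        with pytest.raises(ConfigError):
            mixture_model(joint, prod, 1.2)


class TestFitGcc:
    def test_independence_gives_near_zero_A(self, rng):
        x = rng.standard_normal(2_000)
        y = rng.standard_normal(2_000)
        fit = fit_gcc(x, y, seed=1)
        assert fit.A < 0.02
        assert fit.mixture_weight <= 0.3

    def test_perfect_association_near_one(self, rng):
        x = rng.standard_normal(500)
        fit = fit_gcc(x, x.copy(), seed=2)
        assert fit.A > 0.95

    def test_gaussian_A_tracks_squared_pearson(self, rng):
        x = rng.standard_normal(2_000)
        y = 0.6 * x + np.sqrt(1 - 0.36) * rng.standard_normal(2_000)
        fit = fit_gcc(x, y, seed=3)
        r2 = np.corrcoef(x, y)[0, 1] ** 2
        assert fit.A == pytest.approx(r2, abs=0.06)

    def test_detects_quadratic_dependence_pearson_misses(self, rng):
        x = rng.standard_normal(2_000)
        y = x**2 + 0.3 * rng.standard_normal(2_000)
        fit = fit_gcc(x, y, seed=4)
        assert fit.A > 0.3
        assert np.corrcoef(x, y)[0, 1] ** 2 < 0.05

    def test_symmetry_in_arguments(self, rng):
        x = rng.standard_normal(2_000)
        y = 0.5 * x + rng.standard_normal(2_000)
        assert fit_gcc(x, y, seed=5).A == pytest.approx(fit_gcc(y, x, seed=6).A,
                                                        abs=0.02)

    def test_invariance_under_monotone_rescaling(self, rng):
        x = rng.standard_normal(2_000)
        y = 0.6 * x + 0.8 * rng.standard_normal(2_000)
        base = fit_gcc(x, y, seed=7).A
        assert fit_gcc(np.exp(x), y, seed=7).A == pytest.approx(base, abs=0.02)
        assert fit_gcc(x, y**3, seed=7).A == pytest.approx(base, abs=0.02)

    def test_zero_weight_grid_forces_null_identity(self, rng):
        x = rng.standard_normal(400)
        y = x + 0.1 * rng.standard_normal(400)
        fit = fit_gcc(x, y, weight_grid=[0.0], seed=8)
        assert fit.cvlrs == 0.0
        assert fit.A == 0.0
        assert fit.cv_loglik_alt == fit.cv_loglik_null

    def test_cvlrs_identity(self, rng):
        x = rng.standard_normal(600)
        y = 0.4 * x + rng.standard_normal(600)
        fit = fit_gcc(x, y, seed=9)
        assert fit.cvlrs == pytest.approx(
            -2.0 * (fit.cv_loglik_null - fit.cv_loglik_alt), abs=1e-9
        )
        assert fit.A == pytest.approx(1.0 - np.exp(-fit.cvlrs / fit.n), abs=1e-12)

    def test_input_validation(self, rng):
        with pytest.raises(SampleSizeError):
            fit_gcc(np.arange(10.0), np.arange(10.0))
        x = rng.standard_normal(50)
        bad = x.copy()
        bad[3] = np.nan
        with pytest.raises(DegenerateInputError):
            fit_gcc(x, bad)
        with pytest.raises(ConfigError):
            fit_gcc(x, x, weight_grid=[0.5, 1.0])  # grid must contain 0

    def test_deterministic_given_seed(self, rng):
        x = rng.standard_normal(300)
        y = rng.standard_normal(300)
        a = fit_gcc(x, y, seed=42)
        b = fit_gcc(x, y, seed=42)
        assert a.A == b.A and a.cvlrs == b.cvlrs and a.mixture_weight == b.mixture_weight


@pytest.mark.parametrize("rho", [0.0, 0.3, 0.6, 0.9])
def test_equitability_across_gaussian_strengths(rho):
    r = np.random.default_rng(1000 + int(rho * 10))
    x = r.standard_normal(2_000)
    y = rho * x + np.sqrt(1 - rho**2) * r.standard_normal(2_000)
    fit = fit_gcc(x, y, seed=11)
    assert fit.A == pytest.approx(rho**2, abs=0.06)


class TestGccPvalue:
    def test_identity_relation_beats_all_permutations(self, rng):
        x = rng.standard_normal(500)
        res = gcc_pvalue(x, x.copy(), n_perm=99, tail_method="empirical", seed=12)
        assert res.pvalue == pytest.approx(1.0 / 100.0)

    def test_pvalue_bounds(self, rng):
        x = rng.standard_normal(200)
        y = rng.standard_normal(200)
        res = gcc_pvalue(x, y, n_perm=49, tail_method="empirical", seed=13)
        assert 1.0 / 50.0 <= res.pvalue <= 1.0

    def test_too_few_permutations_rejected(self, rng):
        x = rng.standard_normal(100)
        with pytest.raises(ResolutionError):
            gcc_pvalue(x, x, n_perm=10)

    def test_gpd_tail_extrapolates_below_resolution(self, rng):
        x = rng.standard_normal(500)
        res = gcc_pvalue(x, x.copy(), n_perm=99, tail_method="gpd_tail", seed=14)
        assert res.pvalue < 1.0 / 100.0

    def test_null_pvalues_uniform_over_datasets(self):
        # independence => p ~ U(0,1); KS over 200 independent datasets
        r = np.random.default_rng(77)
        ps = []
        for _ in range(200):
            x = r.standard_normal(150)
            y = r.standard_normal(150)
            ps.append(
                gcc_pvalue(x, y, n_perm=49, tail_method="empirical",
                           seed=int(r.integers(2**31))).pvalue
            )
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestBlockPermutation:
    def test_preserves_family_blocks(self):
        fam = np.array(["a", "a", "b", "b", "c", "c", "d"])
        y = np.array([1.0, 1.1, 2.0, 2.1, 3.0, 3.1, 9.0])
        r = np.random.default_rng(3)
        for _ in range(20):
            pi = block_permutation(fam, r)
            yp = y[pi]
            # each pair slot still holds a matched block (values 0.1 apart)
            for s in (0, 2, 4):
                assert abs(yp[s] - yp[s + 1]) == pytest.approx(0.1)
            assert yp[6] == 9.0  # singleton never mixed into pairs
        assert sorted(y[block_permutation(fam, r)]) == sorted(y)


@pytest.fixture(scope="module")
def calibration():
    r = np.random.default_rng(55)

    def x_sampler(rng):
        return rng.binomial(2, 0.3, 400).astype(float)

    def y_sampler(rng):
        return rng.standard_normal(400)

    calib = shared_null_calibration(
        x_sampler, y_sampler(r), n_perm=999, seed=17, y_sampler=y_sampler
    )
    return calib, x_sampler


class TestSharedNullCalibration:

    def test_threshold_rejects_fresh_nulls_at_nominal_rate(self, calibration):
        calib, x_sampler = calibration
        thr = calib.quantile(0.95, method="empirical")
        r = np.random.default_rng(123)
        rej = 0
        n_sets = 400
        for _ in range(n_sets):
            x = x_sampler(r)
            y = r.standard_normal(400)
            rej += fit_gcc(x, y, seed=int(r.integers(2**31))).cvlrs_test > thr
        # binomial 99% interval around 0.05 at 400 draws
        assert 0.05 - 2.58 * np.sqrt(0.05 * 0.95 / n_sets) <= rej / n_sets \
            <= 0.05 + 2.58 * np.sqrt(0.05 * 0.95 / n_sets)

    def test_extreme_quantile_needs_tail_model(self, calibration):
        calib, _ = calibration
        with pytest.raises(ResolutionError):
            calib.quantile(1 - 5e-8, method="empirical")

    def test_gpd_tail_consistent_with_empirical_quantile(self, calibration):
        calib, _ = calibration
        emp99 = calib.quantile(0.99, method="empirical")
        gpd99 = calib.quantile(0.99, method="gpd_tail")
        assert gpd99 == pytest.approx(emp99, rel=0.10)

    def test_too_few_draws_rejected(self):
        with pytest.raises(ResolutionError):
            shared_null_calibration(lambda r: r.standard_normal(50),
                                    np.zeros(50), n_perm=99)

    def test_pvalue_monotone_in_statistic(self, calibration):
        calib, _ = calibration
        qs = [calib.pvalue(s) for s in np.linspace(calib.stats.min(),
                                                   calib.stats.max() * 1.5, 20)]
        assert all(a >= b for a, b in zip(qs, qs[1:]))
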