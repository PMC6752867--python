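import numpy as np
import pytest
from scipy.stats import multivariate_normal

from prepaid.models import ToyNormalModel
from prepaid.prepaid_grid import GridSpec, PrepaidGrid, build_grid
from prepaid.space import PointMassPrior, UniformBoxPrior, ParameterSpace
from prepaid.synthlik_estimators import (
    ConstraintSpec,
    estimate_constrained,
    estimate_map,
    estimate_slml_grid,
    estimate_slml_svm,
    fit_local_interpolator,
    parametric_bootstrap_ci,
    select_neighbors,
    synthetic_loglik,
    tune_sigma_prior,
)


def _manual_grid(theta, mu, sigma_rows, t=100, stat_names=None, ranges=None, bank=None):
    """Small hand-built grid for exact estimator tests."""
    theta = np.atleast_2d(np.asarray(theta, dtype=float))
    if theta.shape[1] == 1:
        space = ParameterSpace(("x",), np.array([theta.min() - 1]),
                               np.array([theta.max() + 1]), ("linear",))
    else:
        names = tuple(f"p{i}" for i in range(theta.shape[1]))
        space = ParameterSpace(names, theta.min(0) - 1, theta.max(0) + 1,
                               ("linear",) * theta.shape[1])
    mu = np.atleast_2d(np.asarray(mu, dtype=float))
    R = mu.shape[1]
    if stat_names is None:
        stat_names = tuple(f"s{i}" for i in range(R))
    if ranges is None:
        ranges = np.tile([-np.inf, np.inf], (R, 1))
    return PrepaidGrid(
        theta, mu, {t: np.asarray(sigma_rows, dtype=float)},
        {} if bank is None else {t: bank}, space, stat_names, ranges,
        meta={"t_sim": t},
    )


class TestSyntheticLoglik:
    def test_zero_at_mean_identity_cov(self):
        s = np.array([1.0, 2.0, 3.0])
        assert np.isclose(synthetic_loglik(s, s, np.eye(3)), 0.0, atol=1e-7)

    def test_unit_vector_deviation(self):
        mu = np.zeros(4)
        s = np.array([1.0, 0.0, 0.0, 0.0])
        assert np.isclose(synthetic_loglik(s, mu, np.eye(4)), -0.5, atol=1e-7)

    def test_matches_mvn_logpdf_oracle(self, rng):
        for _ in range(100):
            r = rng.integers(2, 8)
            a = rng.normal(size=(r, r))
            sigma = a @ a.T + 0.5 * np.eye(r)
            mu = rng.normal(size=r)
            s = rng.normal(size=r)
            expected = multivariate_normal.logpdf(s, mu, sigma) + 0.5 * r * np.log(2 * np.pi)
            assert np.isclose(synthetic_loglik(s, mu, sigma), expected, rtol=1e-6)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            synthetic_loglik(np.zeros(3), np.zeros(2), np.eye(2))


class TestGridEstimator:
    def test_exact_row_recovered(self):
        theta = np.array([[0.0], [1.0], [2.0]])
        mu = np.array([[0.0], [5.0], [10.0]])
        sig = np.tile(np.eye(1), (3, 1, 1))
        g = _manual_grid(theta, mu, sig)
        est = estimate_slml_grid(g, np.array([5.0]), 100)
        assert est.theta[0] == 1.0
        assert est.method == "SLMLGrid"

    def test_tie_breaks_to_lowest_index(self):
        theta = np.array([[0.0], [1.0], [2.0]])
        mu = np.array([[4.0], [6.0], [8.0]])  # rows 0,1 equidistant from 5
        sig = np.tile(np.eye(1), (3, 1, 1))
        g = _manual_grid(theta, mu, sig)
        est = estimate_slml_grid(g, np.array([5.0]), 100)
        assert est.neighbor_indices[0] == 0

    def test_empty_grid_rejected(self):
        space = ParameterSpace(("x",), np.array([0.0]), np.array([1.0]), ("linear",))
        g = PrepaidGrid(
            np.empty((0, 1)), np.empty((0, 1)), {100: np.empty((0, 1, 1))}, {},
            space, ("s0",), np.array([[-np.inf, np.inf]]),
        )
        with pytest.raises(ValueError):
            estimate_slml_grid(g, np.array([0.0]), 100)

    def test_argmax_invariant_to_monotone_transform(self, toy_grid):
        s = np.array([1.234])
        ll = toy_grid.loglik(s, 100)
        assert np.argmax(ll) == np.argmax(np.tanh(ll / 100.0))


class TestSelectNeighbors:
    def test_top1_is_argmax(self, toy_grid):
        s = np.array([0.42])
        nn = select_neighbors(toy_grid, s, 100, n=1)
        assert nn[0] == estimate_slml_grid(toy_grid, s, 100).neighbor_indices[0]

    def test_all_rows(self, toy_grid):
        nn = select_neighbors(toy_grid, np.array([0.0]), 100, n=toy_grid.omega)
        assert sorted(nn) == list(range(toy_grid.omega))

    def test_default_is_100(self):
        import inspect

        sig = inspect.signature(select_neighbors)
        assert sig.parameters["n"].default == 100

    def test_descending_likelihood(self, toy_grid):
        s = np.array([-0.8])
        nn = select_neighbors(toy_grid, s, 100, n=20)
        ll = toy_grid.loglik(s, 100)
        assert (np.diff(ll[nn]) <= 1e-12).all()


class TestLocalInterpolator:
    def _linear_data(self, rng, n=60, k=2):
        theta = rng.uniform(-1, 1, size=(n, k))
        coefs = np.array([[2.0, -1.0], [0.5, 3.0], [1.0, 0.0]]).T[:k]
        stats = 1.5 + theta @ coefs
        return theta, stats

    def test_linear_data_reproduced_by_both_kinds(self, rng):
        theta, stats = self._linear_data(rng)
        for kind in ("linear", "lssvm"):
            interp = fit_local_interpolator(theta[:50], stats[:50], kind=kind)
            pred = interp.predict(theta[50:])
            np.testing.assert_allclose(pred, stats[50:], rtol=1e-6, atol=1e-6)

    def test_lssvm_beats_linear_on_quadratic(self, rng):
        theta = rng.uniform(-1, 1, size=(100, 2))
        y = (theta[:, 0] ** 2 + theta[:, 1] ** 2)[:, None]
        i_lin = fit_local_interpolator(theta[:70], y[:70], kind="linear")
        i_svm = fit_local_interpolator(theta[:70], y[:70], kind="lssvm")
        err_lin = np.sqrt(np.mean((i_lin.predict(theta[70:]) - y[70:]) ** 2))
        err_svm = np.sqrt(np.mean((i_svm.predict(theta[70:]) - y[70:]) ** 2))
        assert err_svm < err_lin

    def test_clamped_to_valid_range(self, rng):
        theta = rng.uniform(0, 1, size=(30, 1))
        prop = np.clip(theta * 1.2 - 0.1, 0, 1)  # proportion-like statistic
        clamp = np.array([[0.0, 1.0]])
        interp = fit_local_interpolator(theta, prop, kind="linear", clamp=clamp)
        pred = interp.predict(np.linspace(-5, 5, 100)[:, None])
        assert (pred >= 0).all() and (pred <= 1).all()

    def test_rank_deficient_linear_rejected(self):
        theta = np.tile([[1.0, 2.0]], (10, 1))
        stats = np.ones((10, 1))
        with pytest.raises(ValueError):
            fit_local_interpolator(theta, stats, kind="linear")

    def test_too_few_neighbors(self, rng):
        with pytest.raises(ValueError):
            fit_local_interpolator(rng.normal(size=(3, 2)), rng.normal(size=(3, 1)))


class TestSvmEstimator:
    def test_identity_surrogate_recovers_observation(self):
        # 1-D toy: statistic = theta exactly, unit covariance
        theta = np.linspace(0, 10, 51)[:, None]
        g = _manual_grid(theta, theta.copy(), np.tile(np.eye(1), (51, 1, 1)))
        s_obs = np.array([4.321])
        est = estimate_slml_svm(g, s_obs, 100, kind="linear", n_neighbors=20, seed=0)
        assert abs(est.theta[0] - 4.321) < 1e-4

    def test_lssvm_close_on_identity(self):
        theta = np.linspace(0, 10, 51)[:, None]
        g = _manual_grid(theta, theta.copy(), np.tile(np.eye(1), (51, 1, 1)))
        est = estimate_slml_svm(g, np.array([6.0]), 100, kind="lssvm",
                                n_neighbors=20, seed=0)
        assert abs(est.theta[0] - 6.0) < 0.05

    def test_objective_at_least_best_grid_row(self, toy_grid):
        s = np.array([1.9])
        grid_est = estimate_slml_grid(toy_grid, s, 100)
        svm_est = estimate_slml_svm(toy_grid, s, 100, seed=1)
        # surrogate objective uses the NN covariance; compare on that scale
        assert svm_est.objective >= grid_est.objective - 1e-6

    def test_deterministic_given_seed(self, toy_grid):
        s = np.array([-2.2])
        a = estimate_slml_svm(toy_grid, s, 100, seed=5)
        b = estimate_slml_svm(toy_grid, s, 100, seed=5)
        np.testing.assert_array_equal(a.theta, b.theta)

    def test_interpolated_beats_grid_on_toy(self, toy_model):
        # situation-2 style check at large T_obs: interpolation refines the
        # coarse grid argmax
        spec = GridSpec(space=toy_model.space, omega=60, t_sim=20_000,
                        t_prepaid=(100,), m=0, seed=31)
        g = build_grid(toy_model, spec)
        rng = np.random.default_rng(17)
        truth, e_grid, e_svm = [], [], []
        for i in range(30):
            mu = rng.uniform(-4, 4)
            s = toy_model.summarize(toy_model.simulate([mu], 10_000, rng))
            e_grid.append(estimate_slml_grid(g, s, 10_000).theta[0] - mu)
            e_svm.append(estimate_slml_svm(g, s, 10_000, kind="linear",
                                           n_neighbors=20, seed=i).theta[0] - mu)
        assert np.sqrt(np.mean(np.square(e_svm))) < np.sqrt(np.mean(np.square(e_grid)))


class TestMapEstimator:
    def test_uniform_prior_equals_grid(self, toy_grid):
        s = np.array([0.33])
        prior = UniformBoxPrior(toy_grid.space.lower, toy_grid.space.upper)
        est_map = estimate_map(toy_grid, s, 100, prior)
        est_grid = estimate_slml_grid(toy_grid, s, 100)
        np.testing.assert_array_equal(est_map.theta, est_grid.theta)

    def test_point_mass_prior_returns_that_row(self, toy_grid):
        j = 42
        prior = PointMassPrior(toy_grid.theta[j])
        est = estimate_map(toy_grid, np.array([0.0]), 100, prior)
        np.testing.assert_array_equal(est.theta_working, toy_grid.theta[j])

    def test_zero_prior_everywhere_rejected(self, toy_grid):
        prior = PointMassPrior(np.array([123.456]))
        with pytest.raises(ValueError):
            estimate_map(toy_grid, np.array([0.0]), 100, prior)


class TestConstrained:
    def _two_condition_setup(self, ricker_mini_grid, ricker_model, seed=3):
        rng = np.random.default_rng(seed)
        th = np.array([40.0, 0.3, 6.0])
        s1 = ricker_model.summarize(ricker_model.simulate(th, 100, rng))
        s2 = ricker_model.summarize(
            ricker_model.simulate(th * np.array([1.0, 1.0, 2.0]), 100, rng)
        )
        return [s1, s2]

    def test_infinite_width_equals_independent(self, ricker_mini_grid, ricker_model):
        stats = self._two_condition_setup(ricker_mini_grid, ricker_model)
        spec = ConstraintSpec(("r", "sigma"), np.inf, 2)
        ests = estimate_constrained(ricker_mini_grid, stats, [100, 100], spec)
        for s_obs, est in zip(stats, ests):
            indep = estimate_slml_grid(ricker_mini_grid, s_obs, 100)
            assert est.neighbor_indices[0] == indep.neighbor_indices[0]

    def test_shared_parameters_exactly_equal(self, ricker_mini_grid, ricker_model):
        stats = self._two_condition_setup(ricker_mini_grid, ricker_model)
        spec = ConstraintSpec(("r", "sigma"), 0.5, 2)
        ests = estimate_constrained(ricker_mini_grid, stats, [100, 100], spec)
        assert ests[0].theta[0] == ests[1].theta[0]
        assert ests[0].theta[1] == ests[1].theta[1]

    def test_coordinate_ascent_matches_exhaustive(self, ricker_mini_grid, ricker_model):
        from prepaid.synthlik_estimators import (
            _constrained_coordinate,
            _constrained_exhaustive,
        )

        stats = self._two_condition_setup(ricker_mini_grid, ricker_model)
        lls = [ricker_mini_grid.loglik(s, 100) for s in stats]
        pools = [np.argsort(-ll, kind="stable")[:40] for ll in lls]
        shared = np.array([0, 1])
        rows_a, obj_a = _constrained_exhaustive(ricker_mini_grid, lls, pools, shared, 0.5)
        rows_b, obj_b = _constrained_coordinate(ricker_mini_grid, lls, pools, shared, 0.5)
        # coordinate ascent may hit a local optimum but never a better one
        assert obj_b <= obj_a + 1e-9

    def test_condition_count_validated(self, ricker_mini_grid, ricker_model):
        stats = self._two_condition_setup(ricker_mini_grid, ricker_model)
        spec = ConstraintSpec(("r",), 1.0, 3)
        with pytest.raises(ValueError):
            estimate_constrained(ricker_mini_grid, stats, [100, 100], spec)


class TestTuneSigmaPrior:
    def test_single_candidate_returned(self, ricker_mini_grid, ricker_model):
        spec = ConstraintSpec(("r", "sigma"), 1.0, 2)
        out = tune_sigma_prior(ricker_mini_grid, ricker_model, spec, [0.7],
                               n_sim=2, t_obs=100, seed=0)
        assert out == 0.7

    def test_deterministic(self, ricker_mini_grid, ricker_model):
        spec = ConstraintSpec(("r", "sigma"), 1.0, 2)
        cands = [0.1, 1.0, 10.0]
        a = tune_sigma_prior(ricker_mini_grid, ricker_model, spec, cands,
                             n_sim=4, t_obs=100, seed=12)
        b = tune_sigma_prior(ricker_mini_grid, ricker_model, spec, cands,
                             n_sim=4, t_obs=100, seed=12)
        assert a == b

    def test_collapse_pathology_penalized(self, ricker_mini_grid, ricker_model):
        spec = ConstraintSpec(("r", "sigma"), 1.0, 2)
        best, details = tune_sigma_prior(
            ricker_mini_grid, ricker_model, spec, [1e-8, 2.0],
            n_sim=6, t_obs=100, seed=4, return_details=True,
        )
        tiny = next(d for d in details if d["sigma_prior"] == 1e-8)
        # near-zero width collapses both conditions onto one grid point
        assert tiny["collapse_frac"] > 0.5
        assert best == 2.0


class TestBootstrap:
    def test_degenerate_model_gives_point_interval(self, toy_grid):
        class ConstModel(ToyNormalModel):
            def simulate(self, theta, T, rng):
                return np.full(T, 1.5)

        res = parametric_bootstrap_ci(
            toy_grid, ConstModel(), np.array([1.5]), 100, B=30, seed=0,
            allow_fallback=False,
        )
        assert res.intervals[0, 0] == res.intervals[0, 1]

    def test_interval_monotone_in_level(self, toy_grid, toy_model):
        wide = parametric_bootstrap_ci(toy_grid, toy_model, np.array([0.5]), 100,
                                       B=60, level=0.95, seed=2, allow_fallback=False)
        narrow = parametric_bootstrap_ci(toy_grid, toy_model, np.array([0.5]), 100,
                                         B=60, level=0.5, seed=2, allow_fallback=False)
        assert narrow.intervals[0, 0] >= wide.intervals[0, 0]
        assert narrow.intervals[0, 1] <= wide.intervals[0, 1]

    def test_theta_outside_box_rejected(self, toy_grid, toy_model):
        with pytest.raises(ValueError):
            parametric_bootstrap_ci(toy_grid, toy_model, np.array([99.0]), 100, B=5)
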