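"""Frequentist / MAP estimation on a prepaid grid.

Implements nearest-neighbour synthetic-likelihood estimation, local
surrogate interpolation (LS-SVM or linear) with differential-evolution
maximization, priors, cross-condition equality constraints, and parametric
bootstrap confidence intervals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import differential_evolution

from ._lssvm import LSSVMRegressor
from .models.base import Model, SummaryVector
from .prepaid_grid import PrepaidGrid, regularize_covariance
from .space import Prior

__all__ = [
    "Estimate",
    "LocalInterpolator",
    "ConstraintSpec",
    "BootstrapResult",
    "synthetic_loglik",
    "estimate_slml_grid",
    "select_neighbors",
    "fit_local_interpolator",
    "estimate_slml_svm",
    "estimate_map",
    "estimate_constrained",
    "tune_sigma_prior",
    "parametric_bootstrap_ci",
]

log = logging.getLogger(__name__)

DE_SETTINGS = dict(
    strategy="rand1bin",
    popsize=15,
    mutation=0.8,
    recombination=0.9,
    maxiter=200,
    tol=1e-8,
    init="latinhypercube",
    updating="deferred",
    vectorized=True,
    polish=True,
)


@dataclass(frozen=True)
class Estimate:
    """A point estimate with method tag and diagnostics.

    ``theta`` is on the natural scale; ``theta_working`` on the grid's
    working (possibly log) scale.
    """

    theta: np.ndarray
    theta_working: np.ndarray
    method: str
    objective: float
    neighbor_indices: np.ndarray | None = None
    ci: np.ndarray | None = None          # (K, 2), natural scale
    ci_level: float | None = None
    warnings: tuple[str, ...] = ()


def _values(s_obs) -> np.ndarray:
    if isinstance(s_obs, SummaryVector):
        return s_obs.values
    return np.asarray(s_obs, dtype=float)


def synthetic_loglik(s_obs, mu: np.ndarray, sigma: np.ndarray) -> float:
    """-(1/2) d' Sigma^-1 d - (1/2) log|Sigma| with d = s_obs - mu.

    No 2*pi constant is included. ``sigma`` is ridge-regularized before
    inversion.
    """
    s = _values(s_obs)
    mu = np.asarray(mu, dtype=float)
    if s.shape != mu.shape:
        raise ValueError("dimension mismatch between statistics and mean")
    sig = regularize_covariance(np.asarray(sigma, dtype=float))
    if sig.shape != (s.size, s.size):
        raise ValueError("dimension mismatch between statistics and covariance")
    chol = np.linalg.cholesky(sig)
    z = np.linalg.solve(chol, s - mu)
    logdet = 2.0 * np.log(np.diag(chol)).sum()
    return float(-0.5 * z @ z - 0.5 * logdet)


def estimate_slml_grid(grid: PrepaidGrid, s_obs, t_obs: int) -> Estimate:
    """Maximum synthetic likelihood over the raw grid rows (SLMLGrid)."""
    if grid.omega < 1:
        raise ValueError("empty grid")
    ll = grid.loglik(_values(s_obs), t_obs)
    j = int(np.argmax(ll))  # ties resolve to the lowest row index
    theta_w = grid.theta[j]
    return Estimate(
        theta=grid.space.to_natural(theta_w),
        theta_working=theta_w.copy(),
        method="SLMLGrid",
        objective=float(ll[j]),
        neighbor_indices=np.array([j]),
    )


def select_neighbors(grid: PrepaidGrid, s_obs, t_obs: int, n: int = 100) -> np.ndarray:
    """Indices of the ``n`` largest synthetic log-likelihoods, descending."""
    if not 1 <= n <= grid.omega:
        raise ValueError("require 1 <= n <= omega")
    ll = grid.loglik(_values(s_obs), t_obs)
    return np.argsort(-ll, kind="stable")[:n]


@dataclass(frozen=True)
class LocalInterpolator:
    """Per-statistic local surrogate mapping working-scale theta -> statistic."""

    kind: str
    regressors: tuple
    training_box: np.ndarray  # (K, 2) min/max of training neighbours
    clamp: np.ndarray         # (R, 2) admissible statistic ranges
    stat_names: tuple[str, ...] = ()

    def predict(self, theta: np.ndarray) -> np.ndarray:
        theta = np.atleast_2d(np.asarray(theta, dtype=float))
        out = np.empty((theta.shape[0], len(self.regressors)))
        for r, reg in enumerate(self.regressors):
            if self.kind == "linear":
                intercept, coef = reg
                out[:, r] = intercept + theta @ coef
            else:
                out[:, r] = reg.predict(theta)
        return np.clip(out, self.clamp[:, 0], self.clamp[:, 1])


def fit_local_interpolator(
    theta_nn: np.ndarray,
    stats_nn: np.ndarray,
    kind: str = "lssvm",
    clamp: np.ndarray | None = None,
    stat_names: tuple[str, ...] = (),
) -> LocalInterpolator:
    """Fit one regressor per statistic on the neighbourhood (N, K) -> (N, R)."""
    theta_nn = np.atleast_2d(np.asarray(theta_nn, dtype=float))
    stats_nn = np.atleast_2d(np.asarray(stats_nn, dtype=float))
    n, k = theta_nn.shape
    if n < k + 2:
        raise ValueError("need at least K+2 training neighbours")
    if kind not in ("lssvm", "linear"):
        raise ValueError("kind must be 'lssvm' or 'linear'")
    if clamp is None:
        clamp = np.tile([-np.inf, np.inf], (stats_nn.shape[1], 1))
    regs = []
    if kind == "linear":
        design = np.column_stack([np.ones(n), theta_nn])
        if np.linalg.matrix_rank(design) < k + 1:
            raise ValueError("rank-deficient design for linear interpolator")
        coef, *_ = np.linalg.lstsq(design, stats_nn, rcond=None)
        regs = [(float(coef[0, r]), coef[1:, r].copy()) for r in range(stats_nn.shape[1])]
    else:
        for r in range(stats_nn.shape[1]):
            regs.append(LSSVMRegressor().fit(theta_nn, stats_nn[:, r]))
    box = np.stack([theta_nn.min(axis=0), theta_nn.max(axis=0)], axis=1)
    return LocalInterpolator(kind, tuple(regs), box, np.asarray(clamp, dtype=float), stat_names)


def estimate_slml_svm(
    grid: PrepaidGrid,
    s_obs,
    t_obs: int,
    kind: str = "lssvm",
    n_neighbors: int = 100,
    seed: int = 0,
    de_settings: dict | None = None,
) -> Estimate:
    """Interpolated synthetic-likelihood maximization (SLMLSVM / SLMLLin).

    Fits a local surrogate on the ``n_neighbors`` best grid rows, then
    maximizes l(theta) = -1/2 (s - f(theta))' S^-1 (s - f(theta)) - 1/2 log|S|
    with S the rescaled covariance of the single nearest neighbour, by
    differential evolution bounded by the neighbours' parameter box.
    """
    s = _values(s_obs)
    nn = select_neighbors(grid, s, t_obs, n_neighbors)
    interp = fit_local_interpolator(
        grid.theta[nn], grid.mu[nn], kind=kind, clamp=grid.stat_ranges,
        stat_names=grid.stat_names,
    )
    sig = regularize_covariance(grid.sigma_scaled(int(nn[0]), t_obs))
    chol = np.linalg.cholesky(sig)
    logdet = 2.0 * np.log(np.diag(chol)).sum()

    def neg_obj(x):
        pts = np.atleast_2d(x.T if x.ndim == 2 else x)  # DE passes (K, S) when vectorized
        d = interp.predict(pts) - s
        z = np.linalg.solve(chol, d.T)
        return 0.5 * (z * z).sum(axis=0) + 0.5 * logdet

    lo = interp.training_box[:, 0]
    hi = interp.training_box[:, 1]
    width = np.maximum(hi - lo, 1e-12)
    bounds = list(zip(lo, lo + width))
    settings = dict(DE_SETTINGS)
    settings.update(de_settings or {})
    result = differential_evolution(neg_obj, bounds, seed=seed, **settings)
    warnings = () if result.success else (f"optimizer did not converge: {result.message}",)
    theta_w = np.clip(result.x, lo, hi)
    method = "SLMLSVM" if kind == "lssvm" else "SLMLLin"
    return Estimate(
        theta=grid.space.to_natural(theta_w),
        theta_working=theta_w,
        method=method,
        objective=float(-np.atleast_1d(neg_obj(theta_w))[0]),
        neighbor_indices=nn,
        warnings=warnings,
    )


def estimate_map(grid: PrepaidGrid, s_obs, t_obs: int, prior: Prior) -> Estimate:
    """Maximum a posteriori over the grid rows: argmax log prior + loglik."""
    lp = prior.logpdf(grid.theta)
    if not np.isfinite(lp).any():
        raise ValueError("prior is zero at every grid row")
    post = grid.loglik(_values(s_obs), t_obs) + lp
    j = int(np.argmax(post))
    theta_w = grid.theta[j]
    return Estimate(
        theta=grid.space.to_natural(theta_w),
        theta_working=theta_w.copy(),
        method="SLMAPGrid",
        objective=float(post[j]),
        neighbor_indices=np.array([j]),
    )


@dataclass(frozen=True)
class ConstraintSpec:
    """Equality-style constraint: ``shared`` parameters are (softly) equal
    across ``n_conditions`` experimental conditions."""

    shared: tuple[str, ...]
    sigma_prior: float
    n_conditions: int

    def __post_init__(self):
        if self.sigma_prior <= 0:
            raise ValueError("sigma_prior must be > 0")
        if self.n_conditions < 2:
            raise ValueError("need at least 2 conditions")


def _constraint_logprior(thetas: np.ndarray, shared_idx: np.ndarray, sigma_prior: float):
    """Unnormalized product-normal penalty on the working scale.

    ``thetas``: (..., C, K) stacked condition parameters.
    """
    if not np.isfinite(sigma_prior):
        return np.zeros(thetas.shape[:-2])
    sub = thetas[..., shared_idx]               # (..., C, S)
    mean = sub.mean(axis=-2, keepdims=True)
    return -(((sub - mean) ** 2).sum(axis=(-2, -1))) / (2.0 * sigma_prior ** 2)


def estimate_constrained(
    grid: PrepaidGrid,
    s_obs_list,
    t_obs_list,
    constraint: ConstraintSpec,
    pool_size: int = 200,
) -> list[Estimate]:
    """Joint estimation over conditions with a soft equality prior.

    Step 1: per-condition candidate pools (top ``pool_size`` grid rows by
    synthetic likelihood). Step 2: maximize the summed log-likelihood plus
    the product-normal penalty over pool combinations. Step 3: replace each
    shared parameter by its cross-condition mean so the equality constraint
    holds exactly.
    """
    C = constraint.n_conditions
    if len(s_obs_list) != C or len(t_obs_list) != C:
        raise ValueError("number of observed conditions must match the constraint")
    shared_idx = np.array([grid.space.names.index(nm) for nm in constraint.shared])
    lls = [grid.loglik(_values(s), t) for s, t in zip(s_obs_list, t_obs_list)]
    pools = [np.argsort(-ll, kind="stable")[: min(pool_size, grid.omega)] for ll in lls]
    if any(p.size == 0 for p in pools):
        raise ValueError("empty candidate pool")

    p_sizes = [p.size for p in pools]
    if int(np.prod(p_sizes, dtype=np.int64)) <= 1_000_000:
        choice = _constrained_exhaustive(grid, lls, pools, shared_idx, constraint.sigma_prior)
    else:
        choice = _constrained_coordinate(grid, lls, pools, shared_idx, constraint.sigma_prior)
    rows, objective = choice

    thetas = grid.theta[rows].copy()            # (C, K)
    thetas[:, shared_idx] = thetas[:, shared_idx].mean(axis=0)
    return [
        Estimate(
            theta=grid.space.to_natural(thetas[c]),
            theta_working=thetas[c],
            method="constrained",
            objective=objective,
            neighbor_indices=np.array([rows[c]]),
        )
        for c in range(C)
    ]


def _constrained_exhaustive(grid, lls, pools, shared_idx, sigma_prior):
    C = len(pools)
    shapes = [tuple(pools[i].size if c == i else 1 for c in range(C)) for i in range(C)]
    total = sum(lls[i][pools[i]].reshape(shapes[i]) for i in range(C))
    if np.isfinite(sigma_prior):
        for s in shared_idx:
            vals = [grid.theta[pools[i], s].reshape(shapes[i]) for i in range(C)]
            mean = sum(vals) / C
            total = total - sum((v - mean) ** 2 for v in vals) / (2.0 * sigma_prior ** 2)
    flat = int(np.argmax(total))
    combo = np.unravel_index(flat, total.shape)
    rows = np.array([pools[i][combo[i]] for i in range(C)])
    return rows, float(total[combo])


def _constrained_coordinate(grid, lls, pools, shared_idx, sigma_prior, max_sweeps=100):
    C = len(pools)
    picks = [int(p[0]) for p in pools]

    def objective(rows):
        th = grid.theta[np.asarray(rows)]
        return sum(lls[c][rows[c]] for c in range(C)) + float(
            _constraint_logprior(th, shared_idx, sigma_prior)
        )

    for _ in range(max_sweeps):
        changed = False
        for c in range(C):
            cand_theta = grid.theta[pools[c]]
            stack = np.repeat(grid.theta[np.asarray(picks)][None], cand_theta.shape[0], axis=0)
            stack[:, c, :] = cand_theta
            scores = lls[c][pools[c]] + _constraint_logprior(stack, shared_idx, sigma_prior)
            best = int(pools[c][int(np.argmax(scores))])
            if best != picks[c]:
                picks[c] = best
                changed = True
        if not changed:
            break
    return np.array(picks), float(objective(picks))


def tune_sigma_prior(
    grid: PrepaidGrid,
    model: Model,
    constraint: ConstraintSpec,
    candidates,
    n_sim: int,
    t_obs: int,
    seed: int = 0,
    pool_size: int = 200,
    trim: float = 0.01,
    return_details: bool = False,
):
    """Pick the penalty width minimizing summed standardized RMSE on
    simulated constraint-satisfying test sets. Deterministic given ``seed``.

    Candidates for which the estimation collapses onto a single grid point
    for all conditions (pooled estimates identical across conditions) are
    penalized.
    """
    candidates = list(candidates)
    if len(candidates) == 1 and not return_details:
        return candidates[0]
    space = grid.space
    C = constraint.n_conditions
    shared_idx = np.array([space.names.index(nm) for nm in constraint.shared])

    # simulate constraint-satisfying truths and their datasets once
    truths, stats = [], []
    for i in range(n_sim):
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(i,)))
        lo = space.lower + trim * space.range
        hi = space.upper - trim * space.range
        th = np.stack([_draw_trimmed(space, lo, hi, rng) for _ in range(C)])
        th[:, shared_idx] = th[0, shared_idx]
        truths.append(th)
        stats.append(
            [model.summarize(model.simulate(space.to_natural(th[c]), t_obs, rng)) for c in range(C)]
        )

    scores, details = [], []
    for cand in candidates:
        spec = ConstraintSpec(constraint.shared, cand, C)
        sq = np.zeros(space.ndim)
        collapse = 0
        for th, s_list in zip(truths, stats):
            ests = estimate_constrained(grid, s_list, [t_obs] * C, spec, pool_size=pool_size)
            est_w = np.stack([e.theta_working for e in ests])
            sq += (((est_w - th) / space.range) ** 2).mean(axis=0)
            if C > 1 and np.allclose(est_w, est_w[0]):
                collapse += 1
        rmse = np.sqrt(sq / n_sim)
        collapse_frac = collapse / n_sim
        score = float(rmse.sum()) + 10.0 * collapse_frac
        scores.append(score)
        details.append({"sigma_prior": cand, "score": score, "collapse_frac": collapse_frac})
    best = candidates[int(np.argmin(scores))]
    if return_details:
        return best, details
    return best


def _draw_trimmed(space, lo, hi, rng, max_tries: int = 1000) -> np.ndarray:
    for _ in range(max_tries):
        th = space.prior.sample(1, rng)[0]
        if ((th >= lo) & (th <= hi)).all():
            return th
    return np.clip(th, lo, hi)


@dataclass(frozen=True)
class BootstrapResult:
    intervals: np.ndarray          # (K, 2), natural scale
    level: float
    estimates: np.ndarray          # (B, K), natural scale
    used_svm_fallback: bool
    warnings: tuple[str, ...] = ()


def parametric_bootstrap_ci(
    grid: PrepaidGrid,
    model: Model,
    theta_hat: np.ndarray,
    t_obs: int,
    B: int = 1000,
    level: float = 0.95,
    seed: int = 0,
    s_obs=None,
    n_neighbors: int = 100,
    allow_fallback: bool = True,
) -> BootstrapResult:
    """Percentile parametric bootstrap around ``theta_hat`` (natural scale).

    Each bootstrap dataset of length ``t_obs`` is estimated by SLMLGrid.
    If fewer than half of the first 100 bootstrap estimates land on unique
    grid rows, every bootstrap is re-estimated by differential evolution on
    the surrogate built from the original observation's neighbours.
    """
    theta_hat = np.asarray(theta_hat, dtype=float)
    space = grid.space
    if not space.contains(space.from_natural(theta_hat)).all():
        raise ValueError("theta_hat outside the parameter box")
    warnings: list[str] = []

    boot_stats = np.empty((B, grid.n_stats))
    rows = np.empty(B, dtype=int)
    for b in range(B):
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(b,)))
        boot_stats[b] = model.summarize(model.simulate(theta_hat, t_obs, rng))
        rows[b] = int(np.argmax(grid.loglik(boot_stats[b], t_obs)))

    probe = min(100, B)
    n_unique = np.unique(rows[:probe]).size
    use_fallback = allow_fallback and n_unique < probe / 2
    if use_fallback and s_obs is None:
        warnings.append(
            "bootstrap distribution degenerate on the grid but no s_obs supplied "
            "for the surrogate fallback"
        )
        use_fallback = False

    if use_fallback:
        nn = select_neighbors(grid, s_obs, t_obs, n_neighbors)
        interp = fit_local_interpolator(
            grid.theta[nn], grid.mu[nn], kind="lssvm", clamp=grid.stat_ranges
        )
        sig = regularize_covariance(grid.sigma_scaled(int(nn[0]), t_obs))
        chol = np.linalg.cholesky(sig)
        lo, hi = interp.training_box[:, 0], interp.training_box[:, 1]
        width = np.maximum(hi - lo, 1e-12)
        est_w = np.empty((B, space.ndim))
        for b in range(B):
            s_b = boot_stats[b]

            def neg_obj(x, s_b=s_b):
                pts = np.atleast_2d(x.T if x.ndim == 2 else x)
                d = interp.predict(pts) - s_b
                z = np.linalg.solve(chol, d.T)
                return 0.5 * (z * z).sum(axis=0)

            res = differential_evolution(
                neg_obj, list(zip(lo, lo + width)), seed=int(seed) + b, **DE_SETTINGS
            )
            est_w[b] = np.clip(res.x, lo, hi)
    else:
        est_w = grid.theta[rows]

    est_nat = space.to_natural(est_w)
    alpha = (1.0 - level) / 2.0
    intervals = np.stack(
        [
            np.percentile(est_nat, 100 * alpha, axis=0),
            np.percentile(est_nat, 100 * (1 - alpha), axis=0),
        ],
        axis=1,
    )
    return BootstrapResult(intervals, level, est_nat, use_fallback, tuple(warnings))
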