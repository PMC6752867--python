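"""Bayesian prepaid estimation: grid posterior means, sample-bank ABC, and
LS-SVM / minimum-volume-ellipse refined ABC posteriors."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage

from ._ellipse import fit_region
from .prepaid_grid import PrepaidGrid, regularize_covariance
from .space import ParameterSpace
from .synthlik_estimators import Estimate, _values, fit_local_interpolator

__all__ = [
    "PosteriorSample",
    "CoverageSet",
    "posterior_mean_grid",
    "select_coverage_set",
    "abc_posterior_grid",
    "abc_posterior_svm",
    "posterior_interval",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PosteriorSample:
    """Weighted parameter draws (working scale) approximating a posterior."""

    draws: np.ndarray        # (n, K), working scale
    weights: np.ndarray      # nonnegative, sum 1
    method: str
    source: np.ndarray | None = None  # per-draw grid row or cluster id

    def __post_init__(self):
        draws = np.atleast_2d(np.asarray(self.draws, dtype=float))
        w = np.asarray(self.weights, dtype=float)
        if (w < 0).any() or w.sum() <= 0:
            raise ValueError("weights must be nonnegative with positive sum")
        object.__setattr__(self, "draws", draws)
        object.__setattr__(self, "weights", w / w.sum())

    @property
    def n(self) -> int:
        return self.draws.shape[0]

    def mean(self) -> np.ndarray:
        return self.weights @ self.draws

    def draws_natural(self, space: ParameterSpace) -> np.ndarray:
        return space.to_natural(self.draws)


@dataclass(frozen=True)
class CoverageSet:
    """Smallest set of grid rows holding >= 99.9% normalized likelihood mass."""

    indices: np.ndarray
    Q: int


def _softmax(log_w: np.ndarray) -> np.ndarray:
    log_w = np.asarray(log_w, dtype=float)
    w = np.exp(log_w - log_w.max())
    return w / w.sum()


def posterior_mean_grid(grid: PrepaidGrid, s_obs, t_obs: int):
    """Posterior mean over grid rows with weights proportional to the
    prepaid synthetic likelihood (SLPMGrid). Assumes the grid was laid out
    under the (uniform) prior."""
    ll = grid.loglik(_values(s_obs), t_obs)
    w = _softmax(ll)
    theta_w = w @ grid.theta
    sample = PosteriorSample(grid.theta, w, "SLPMGrid", source=np.arange(grid.omega))
    est = Estimate(
        theta=grid.space.to_natural(theta_w),
        theta_working=theta_w,
        method="SLPMGrid",
        objective=float(ll.max()),
    )
    return est, sample


def select_coverage_set(log_weights: np.ndarray, mass: float = 0.999) -> CoverageSet:
    """Highest-weight rows whose normalized mass first reaches ``mass``."""
    log_weights = np.asarray(log_weights, dtype=float)
    if not np.isfinite(log_weights).any():
        raise ValueError("all log weights are -inf")
    w = _softmax(log_weights)
    order = np.argsort(-w, kind="stable")
    cum = np.cumsum(w[order])
    q = int(np.searchsorted(cum, mass)) + 1
    q = min(q, order.size)
    return CoverageSet(order[:q], q)


@dataclass(frozen=True)
class ABCGridResult:
    sample: PosteriorSample
    estimate: Estimate
    coverage_set: CoverageSet
    t_prepaid: int
    w_q_inv: np.ndarray
    kept_rows: np.ndarray          # grid row of each kept bank sample
    kept_eps: np.ndarray
    row_counts: dict[int, int]     # kept-sample count per grid row in S
    row_min_eps: dict[int, float]  # best epsilon per grid row in S
    warnings: tuple[str, ...] = ()


def _nearest_bank_t(grid: PrepaidGrid, t_obs: int) -> int:
    ts = np.array(sorted(grid.bank), dtype=float)
    if ts.size == 0:
        raise ValueError("grid carries no ABC sample bank")
    d = np.abs(np.log(ts) - np.log(float(t_obs)))
    return int(ts[int(np.argmin(d))])


def abc_posterior_grid(
    grid: PrepaidGrid, s_obs, t_obs: int, n_keep: int = 1000
) -> ABCGridResult:
    """Sample-bank ABC posterior (ABCPMGrid).

    Ranks the pooled bank samples of the 99.9% coverage set by Mahalanobis
    distance to ``s_obs`` (metric: pooled covariance of all Q x M samples),
    keeps the best ``n_keep``, and uses their source parameters with equal
    weights as the posterior. For an observed length not in the stored
    bank lengths, the kept parameter draws are rescaled about their mean so
    the posterior covariance picks up the factor T_prepaid / T_obs.
    """
    s = _values(s_obs)
    tp = _nearest_bank_t(grid, t_obs)
    ll = grid.loglik(s, t_obs)
    cov_set = select_coverage_set(ll)
    S_idx = cov_set.indices
    bank = grid.bank[tp][S_idx]                          # (Q, M, R)
    Q, M, R = bank.shape
    pooled = bank.reshape(Q * M, R)
    w_q = regularize_covariance(np.cov(pooled, rowvar=False, ddof=1).reshape(R, R))
    w_q_inv = np.linalg.inv(w_q)
    d = pooled - s
    eps = np.einsum("nr,rs,ns->n", d, w_q_inv, d)

    warnings = ()
    if Q * M < n_keep:
        warnings = (f"only {Q * M} bank samples available; keeping all",)
        n_keep = Q * M
    order = np.argsort(eps, kind="stable")[:n_keep]
    kept_rows = S_idx[order // M]
    kept_eps = eps[order]

    draws = grid.theta[kept_rows].copy()
    mean = draws.mean(axis=0)
    if tp != t_obs:
        factor = np.sqrt(tp / float(t_obs))
        draws = mean + factor * (draws - mean)
        draws = grid.space.clip(draws)
    sample = PosteriorSample(
        draws, np.full(n_keep, 1.0 / n_keep), "ABCPMGrid", source=kept_rows
    )
    est = Estimate(
        theta=grid.space.to_natural(mean),
        theta_working=mean,
        method="ABCPMGrid",
        objective=float(-kept_eps.mean()),
        warnings=warnings,
    )
    uniq, counts = np.unique(kept_rows, return_counts=True)
    row_counts = dict(zip(uniq.tolist(), counts.tolist()))
    row_min = eps.reshape(Q, M).min(axis=1)
    row_min_eps = dict(zip(S_idx.tolist(), row_min.tolist()))
    return ABCGridResult(
        sample, est, cov_set, tp, w_q_inv, kept_rows, kept_eps, row_counts,
        row_min_eps, warnings,
    )


def _top_rows(result: ABCGridResult, n: int) -> np.ndarray:
    """Grid rows contributing the most kept samples, padded by best epsilon."""
    by_count = sorted(result.row_counts, key=lambda r: (-result.row_counts[r], r))
    chosen = list(by_count[:n])
    if len(chosen) < n:
        rest = [r for r in result.row_min_eps if r not in result.row_counts]
        rest.sort(key=lambda r: (result.row_min_eps[r], r))
        chosen.extend(rest[: n - len(chosen)])
    return np.array(chosen, dtype=int)


def _cluster_rows(theta_std: np.ndarray, max_size: int) -> np.ndarray:
    """Ward clustering cut at the shallowest level with all clusters <= max_size."""
    n = theta_std.shape[0]
    if n <= max_size:
        return np.zeros(n, dtype=int)
    Z = linkage(theta_std, method="ward")
    for ncl in range(2, n + 1):
        labels = fcluster(Z, ncl, criterion="maxclust")
        if np.bincount(labels).max() <= max_size:
            return labels - 1
    return np.arange(n)


def abc_posterior_svm(
    grid: PrepaidGrid,
    s_obs,
    t_obs: int,
    n_neighbors: int = 100,
    n_keep: int = 1000,
    seed: int = 0,
    n_sample: int = 1000,
    keep_per_cluster: int = 5000,
    max_cluster_size: int = 50,
    min_cluster_size: int = 20,
    stop_rtol: float = 1e-3,
    max_iter: int = 50,
    return_info: bool = False,
):
    """Ellipse-refined surrogate ABC posterior (ABCPMSVM).

    Clusters the best-contributing grid rows, fits a per-cluster LS-SVM
    surrogate and minimum-volume enclosing ellipse, and iteratively zooms:
    sample parameters uniformly in the ellipse, predict their statistics,
    translate the nearest grid row's sample bank accordingly, score the
    Mahalanobis distance to the observation, keep the best pairs and refit
    the ellipse until the worst kept distance stops decreasing. Pooled
    draws are weighted by originating-ellipse volume.
    """
    s = _values(s_obs)
    gres = abc_posterior_grid(grid, s_obs, t_obs, n_keep=n_keep)
    tp, w_q_inv = gres.t_prepaid, gres.w_q_inv
    rows = _top_rows(gres, n_neighbors)

    scale = np.where(grid.space.range > 0, grid.space.range, 1.0)
    labels = _cluster_rows(grid.theta[rows] / scale, max_cluster_size)

    bank = grid.bank[tp]
    if tp != t_obs:
        factor = np.sqrt(tp / float(t_obs))
        means = bank.mean(axis=1, keepdims=True)
        bank = means + factor * (bank - means)

    all_theta, all_eps, all_cluster, all_vol = [], [], [], []
    volumes = []
    worst_traces = []
    for c in range(labels.max() + 1):
        c_rows = rows[labels == c]
        if c_rows.size < min_cluster_size:
            # pad with the grid rows closest to the cluster centroid
            centroid = grid.theta[c_rows].mean(axis=0)
            d = np.linalg.norm((grid.theta - centroid) / scale, axis=1)
            d[c_rows] = np.inf
            extra = np.argsort(d, kind="stable")[: min_cluster_size - c_rows.size]
            c_rows = np.concatenate([c_rows, extra])
        theta_c = grid.theta[c_rows]
        interp = fit_local_interpolator(
            theta_c, grid.mu[c_rows], kind="lssvm", clamp=grid.stat_ranges
        )
        region = fit_region(theta_c)
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(c,)))

        kept_theta = np.empty((0, grid.ndim))
        kept_eps = np.empty(0)
        kept_vol = np.empty(0)   # volume of the ellipse each draw was sampled in
        worst = np.inf
        trace = []
        for _ in range(max_iter):
            cand = grid.space.clip(region.sample(n_sample, rng))
            pred = interp.predict(cand)                                   # (n, R)
            dist2 = (((cand[:, None, :] - theta_c[None, :, :]) / scale) ** 2).sum(axis=2)
            near = np.argmin(dist2, axis=1)
            shift = pred - grid.mu[c_rows[near]]                          # (n, R)
            translated = bank[c_rows[near]] + shift[:, None, :]           # (n, M, R)
            diff = translated - s
            eps = np.einsum("nmr,rs,nms->nm", diff, w_q_inv, diff)
            n_cand, M = eps.shape
            cand_theta = np.repeat(cand, M, axis=0)
            cand_eps = eps.reshape(-1)
            pool_theta = np.concatenate([kept_theta, cand_theta])
            pool_eps = np.concatenate([kept_eps, cand_eps])
            pool_vol = np.concatenate(
                [kept_vol, np.full(cand_eps.size, region.volume)]
            )
            order = np.argsort(pool_eps, kind="stable")[:keep_per_cluster]
            kept_theta, kept_eps, kept_vol = (
                pool_theta[order], pool_eps[order], pool_vol[order]
            )
            new_worst = float(kept_eps.max())
            trace.append(new_worst)
            uniq = np.unique(kept_theta, axis=0)
            if uniq.shape[0] > grid.ndim:
                region = fit_region(uniq)
            if np.isfinite(worst) and worst - new_worst <= stop_rtol * abs(worst):
                worst = new_worst
                break
            worst = new_worst
        all_theta.append(kept_theta)
        all_eps.append(kept_eps)
        all_cluster.append(np.full(kept_eps.size, c))
        all_vol.append(kept_vol)
        volumes.append(region.volume)
        worst_traces.append(trace)

    theta = np.concatenate(all_theta)
    eps = np.concatenate(all_eps)
    cluster = np.concatenate(all_cluster)
    vol = np.concatenate(all_vol)
    order = np.argsort(eps, kind="stable")[: min(n_keep, eps.size)]
    draws = theta[order]
    src = cluster[order]
    weights = vol[order]
    if not np.isfinite(weights).all() or weights.sum() <= 0:
        weights = np.ones_like(weights)
    sample = PosteriorSample(draws, weights, "ABCPMSVM", source=src)
    mean_w = sample.mean()
    est = Estimate(
        theta=grid.space.to_natural(mean_w),
        theta_working=mean_w,
        method="ABCPMSVM",
        objective=float(-eps[order].mean()),
    )
    if return_info:
        info = {"volumes": volumes, "worst_traces": worst_traces, "labels": labels,
                "rows": rows}
        return est, sample, info
    return est, sample


def posterior_interval(
    sample: PosteriorSample, level: float = 0.95, space: ParameterSpace | None = None
) -> np.ndarray:
    """Weighted central interval per parameter, (K, 2).

    Quantile rule: after dropping zero-weight draws and sorting, plotting
    positions (C_i - w_i)/(1 - w_n) reduce to numpy's linear interpolation
    for equal weights. With ``space`` given, draws are mapped to the
    natural scale first.
    """
    if sample.n < 2 and sample.weights.size < 1:
        raise ValueError("need at least one draw")
    draws = sample.draws if space is None else sample.draws_natural(space)
    w_all = sample.weights
    lo_q = (1.0 - level) / 2.0
    hi_q = 1.0 - lo_q
    out = np.empty((draws.shape[1], 2))
    for k in range(draws.shape[1]):
        x = draws[:, k]
        keep = w_all > 0
        xs, ws = x[keep], w_all[keep]
        order = np.argsort(xs, kind="stable")
        xs, ws = xs[order], ws[order]
        if xs.size == 1:
            out[k] = (xs[0], xs[0])
            continue
        cum = np.cumsum(ws)
        denom = cum[-1] - ws[-1]
        if denom <= 0:
            out[k] = (xs[-1], xs[-1])
            continue
        pos = (cum - ws) / denom
        out[k] = (np.interp(lo_q, pos, xs), np.interp(hi_q, pos, xs))
    return out
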