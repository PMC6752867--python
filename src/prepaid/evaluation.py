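"""Recovery and coverage study harness.

Draws test parameters away from the box edges, simulates one dataset per
(test point, observed length), runs each estimator, and aggregates RMSE /
median absolute error / interval coverage per parameter. Errors for
log-scaled parameters are computed on the log (working) scale, matching
how such parameters are reported.
"""

from __future__ import annotations

import logging
import time

import numpy as np
import pandas as pd

from .models.base import Model
from .prepaid_grid import PrepaidGrid
from .space import ParameterSpace, Prior

__all__ = ["make_test_set", "run_recovery_study", "run_coverage_study"]

log = logging.getLogger(__name__)


def make_test_set(
    space: ParameterSpace,
    generator_prior: Prior | None,
    n_test: int,
    trim: float = 0.01,
    seed: int = 0,
    max_tries: int = 1000,
) -> np.ndarray:
    """Draw ``n_test`` working-scale parameter vectors from the generating
    prior, discarding draws within ``trim`` * range of any bound."""
    if n_test < 1:
        raise ValueError("n_test must be >= 1")
    prior = generator_prior if generator_prior is not None else space.prior
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    lo = space.lower + trim * space.range
    hi = space.upper - trim * space.range
    out = []
    for _ in range(max_tries):
        draws = prior.sample(n_test, rng)
        keep = ((draws >= lo) & (draws <= hi)).all(axis=1) if trim > 0 else np.ones(n_test, bool)
        out.extend(draws[keep])
        if len(out) >= n_test:
            break
    if len(out) < n_test:
        raise RuntimeError("could not draw enough interior test parameters")
    return np.stack(out[:n_test])


def _cell_rng(seed: int, test_index: int, t_obs: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(test_index, t_obs)))


def run_recovery_study(
    grid: PrepaidGrid,
    model: Model,
    methods: dict,
    test_set: np.ndarray,
    t_obs_list,
    seed: int = 0,
) -> pd.DataFrame:
    """Recovery study: one simulated dataset per (test theta, T_obs),
    estimated with every method in ``methods`` (name -> callable taking
    (grid, s_obs, t_obs) and returning an Estimate).

    Returns tidy rows (parameter, T_obs, method, rmse, mae, n_test, n_failed)
    where mae is the *median* absolute error.
    """
    space = grid.space
    test_set = np.atleast_2d(test_set)
    records = []
    for t_obs in t_obs_list:
        stats = []
        for i, theta_w in enumerate(test_set):
            rng = _cell_rng(seed, i, int(t_obs))
            data = model.simulate(space.to_natural(theta_w), int(t_obs), rng)
            stats.append(model.summarize(data))
        for name, fn in methods.items():
            t0 = time.perf_counter()
            errors = np.full((len(test_set), space.ndim), np.nan)
            n_failed = 0
            for i, theta_w in enumerate(test_set):
                try:
                    est = fn(grid, stats[i], int(t_obs))
                    errors[i] = est.theta_working - theta_w
                except Exception as exc:  # recorded per cell, not fatal
                    n_failed += 1
                    log.warning("estimator %s failed on test %d (T=%s): %s",
                                name, i, t_obs, exc)
            log.info("recovery: method=%s T_obs=%s took %.2fs",
                     name, t_obs, time.perf_counter() - t0)
            ok = ~np.isnan(errors).any(axis=1)
            for k in range(space.ndim):
                e = errors[ok, k]
                records.append(
                    {
                        "parameter": space.label(k),
                        "T_obs": int(t_obs),
                        "method": name,
                        "rmse": float(np.sqrt(np.mean(e ** 2))) if e.size else np.nan,
                        "mae": float(np.median(np.abs(e))) if e.size else np.nan,
                        "n_test": int(ok.sum()),
                        "n_failed": n_failed,
                    }
                )
    return pd.DataFrame(records)


def run_coverage_study(
    grid: PrepaidGrid,
    model: Model,
    interval_fn,
    test_set: np.ndarray,
    t_obs: int,
    seed: int = 0,
) -> pd.DataFrame:
    """Fraction of test points whose interval contains the truth.

    ``interval_fn(grid, s_obs, t_obs, rng_seed)`` must return a (K, 2)
    array of natural-scale intervals.
    """
    space = grid.space
    test_set = np.atleast_2d(test_set)
    hits = np.zeros((len(test_set), space.ndim))
    ok = np.ones(len(test_set), dtype=bool)
    for i, theta_w in enumerate(test_set):
        rng = _cell_rng(seed, i, int(t_obs))
        theta_nat = space.to_natural(theta_w)
        data = model.simulate(theta_nat, int(t_obs), rng)
        s_obs = model.summarize(data)
        try:
            ci = np.asarray(interval_fn(grid, s_obs, int(t_obs), int(seed) + i))
            hits[i] = (ci[:, 0] <= theta_nat) & (theta_nat <= ci[:, 1])
        except Exception as exc:
            ok[i] = False
            log.warning("interval estimation failed on test %d: %s", i, exc)
    records = [
        {
            "parameter": space.label(k),
            "T_obs": int(t_obs),
            "coverage": float(hits[ok, k].mean()),
            "n_test": int(ok.sum()),
        }
        for k in range(space.ndim)
    ]
    return pd.DataFrame(records)
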