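"""Stochastic Ricker population model with Poisson observation.

Hidden dynamics N_{t+1} = r * N_t * exp(-N_t + e_t), e_t ~ N(0, sigma^2),
observed counts y_t ~ Poisson(phi * N_t).
"""

from __future__ import annotations

from dataclasses import dataclass

import numba as nb
import numpy as np

from ..space import ParameterSpace
from .base import Model, SummaryVector

__all__ = [
    "RickerParams",
    "RickerModel",
    "ricker_space",
    "ricker_log_space",
    "simulate_ricker",
    "summarize_ricker",
    "RICKER_STAT_NAMES",
]

#: default number of discarded warm-up steps (the stationary regime is reached
#: quickly from N0 = 1; 50 steps removes the transient)
BURN_IN = 50
N0 = 1.0

RICKER_STAT_NAMES = (
    "mean",
    "prop_zeros",
    "acov1",
    "acov2",
    "acov3",
    "acov4",
    "acov5",
    "ar_c0",
    "ar_c1",
    "ar_c2",
)

_INF = float("inf")
RICKER_STAT_RANGES = np.array(
    [
        [0.0, _INF],       # mean count
        [0.0, 1.0],        # proportion of zeros
        [-_INF, _INF],     # autocovariances, lags 1..5
        [-_INF, _INF],
        [-_INF, _INF],
        [-_INF, _INF],
        [-_INF, _INF],
        [-_INF, _INF],     # quadratic autoregression coefficients
        [-_INF, _INF],
        [-_INF, _INF],
    ]
)


@dataclass(frozen=True)
class RickerParams:
    r: float
    sigma: float
    phi: float

    def __post_init__(self):
        if not (self.r > 0 and self.sigma >= 0 and self.phi >= 0):
            raise ValueError(f"invalid Ricker parameters {self.as_array()}")

    def as_array(self) -> np.ndarray:
        return np.array([self.r, self.sigma, self.phi], dtype=float)


def ricker_space() -> ParameterSpace:
    """Linear-scale box r in [1, 90], sigma in [0.05, 0.7], phi in [0, 20]."""
    return ParameterSpace(
        names=("r", "sigma", "phi"),
        lower=np.array([1.0, 0.05, 0.0]),
        upper=np.array([90.0, 0.7, 20.0]),
        scale=("linear", "linear", "linear"),
    )


def ricker_log_space() -> ParameterSpace:
    """Wider box with r and phi on natural-log working scale."""
    return ParameterSpace(
        names=("r", "sigma", "phi"),
        lower=np.array([np.log(1.0), 0.05, -2.0]),
        upper=np.array([np.log(200.0), 0.7, 7.0]),
        scale=("log", "linear", "log"),
    )


@nb.njit(cache=False)
def _hidden_path(r: float, e: np.ndarray, T: int, burn: int, n0: float) -> np.ndarray:
    N = np.empty(T)
    n = n0
    for t in range(burn):
        n = r * n * np.exp(-n + e[t])
    for t in range(T):
        N[t] = n
        n = r * n * np.exp(-n + e[burn + t])
    return N


def simulate_ricker(
    params: RickerParams | np.ndarray,
    T: int,
    rng: np.random.Generator,
    burn_in: int = BURN_IN,
    n0: float = N0,
) -> np.ndarray:
    """Simulate ``T`` Poisson counts from the Ricker model."""
    if not isinstance(params, RickerParams):
        params = RickerParams(*np.asarray(params, dtype=float))
    if T < 1:
        raise ValueError("T must be >= 1")
    if params.sigma > 0:
        e = rng.normal(0.0, params.sigma, size=burn_in + T)
    else:
        e = np.zeros(burn_in + T)
    N = _hidden_path(params.r, e, T, burn_in, n0)
    if not np.isfinite(N).all():
        raise FloatingPointError(
            f"non-finite hidden trajectory for parameters {params.as_array()}"
        )
    return rng.poisson(params.phi * N).astype(np.int64)


def _quad_ar_coefs(z: np.ndarray) -> np.ndarray:
    """OLS of z_t on {1, z_{t-1}, z_{t-1}^2} for a batch of series (n, T).

    Degenerate designs (constant series) get coefficients (mean(z), 0, 0).
    """
    z = np.atleast_2d(z)
    n_series, T = z.shape
    x, y = z[:, :-1], z[:, 1:]
    m = float(T - 1)
    s1 = x.sum(axis=1)
    s2 = (x * x).sum(axis=1)
    s3 = (x ** 3).sum(axis=1)
    s4 = (x ** 4).sum(axis=1)
    t0 = y.sum(axis=1)
    t1 = (x * y).sum(axis=1)
    t2 = (x * x * y).sum(axis=1)

    coefs = np.zeros((n_series, 3))
    xbar = s1 / m
    varx = s2 / m - xbar ** 2
    degenerate = varx <= 1e-12 * (1.0 + xbar ** 2)
    coefs[degenerate, 0] = z[degenerate].mean(axis=1)

    ok = ~degenerate
    if ok.any():
        A = np.empty((int(ok.sum()), 3, 3))
        A[:, 0, 0] = m
        A[:, 0, 1] = A[:, 1, 0] = s1[ok]
        A[:, 0, 2] = A[:, 1, 1] = A[:, 2, 0] = s2[ok]
        A[:, 1, 2] = A[:, 2, 1] = s3[ok]
        A[:, 2, 2] = s4[ok]
        b = np.stack([t0[ok], t1[ok], t2[ok]], axis=1)
        try:
            coefs[ok] = np.linalg.solve(A, b[..., None])[..., 0]
        except np.linalg.LinAlgError:
            # rare near-singular designs: fall back per series
            idx = np.flatnonzero(ok)
            for j, i in enumerate(idx):
                coefs[i] = np.linalg.lstsq(
                    np.stack([np.ones(x.shape[1]), x[i], x[i] ** 2], axis=1),
                    y[i],
                    rcond=None,
                )[0]
    bad = ~np.isfinite(coefs).all(axis=1)
    if bad.any():
        coefs[bad] = 0.0
        coefs[bad, 0] = z[bad].mean(axis=1)
    return coefs


def _summaries_2d(y: np.ndarray) -> np.ndarray:
    """Vectorized Ricker summary statistics for a batch of series (n, T)."""
    y = np.atleast_2d(np.asarray(y, dtype=float))
    n_series, T = y.shape
    if T < 7:
        raise ValueError("series too short: need length >= 7 for lag-5 autocovariances")
    out = np.empty((n_series, 10))
    mean = y.mean(axis=1)
    out[:, 0] = mean
    out[:, 1] = (y == 0).mean(axis=1)
    c = y - mean[:, None]
    for k in range(1, 6):
        out[:, 1 + k] = (c[:, :-k] * c[:, k:]).sum(axis=1) / T
    out[:, 7:10] = _quad_ar_coefs(y ** 0.3)
    return out


def summarize_ricker(series: np.ndarray) -> np.ndarray:
    """Summary statistics of a count series.

    Returns (mean, proportion of zeros, autocovariances at lags 1-5,
    coefficients of the quadratic autoregression of y^0.3 on its lag).
    """
    series = np.asarray(series)
    if series.ndim != 1:
        raise ValueError("expected a 1-D count series")
    if (series < 0).any():
        raise ValueError("counts must be nonnegative")
    return _summaries_2d(series[None, :])[0]


class RickerModel(Model):
    model_id = "ricker"
    stat_names = RICKER_STAT_NAMES
    stat_ranges = RICKER_STAT_RANGES

    def __init__(self, space: ParameterSpace | None = None, burn_in: int = BURN_IN):
        self.space = space if space is not None else ricker_space()
        self.burn_in = burn_in

    def simulate(self, theta: np.ndarray, T: int, rng: np.random.Generator) -> np.ndarray:
        r, sigma, phi = np.asarray(theta, dtype=float)
        return simulate_ricker(RickerParams(r, sigma, phi), T, rng, burn_in=self.burn_in)

    def summarize(self, data: np.ndarray) -> np.ndarray:
        return summarize_ricker(data)

    def summarize_blocks(self, data: np.ndarray, block: int) -> np.ndarray:
        n = data.shape[0] // block
        return _summaries_2d(data[: n * block].reshape(n, block))

    def summary_vector(self, data: np.ndarray) -> SummaryVector:
        return SummaryVector(self.stat_names, self.summarize(data), self.stat_ranges)
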