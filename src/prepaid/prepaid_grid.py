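"""Construction, persistence and querying of the prepaid database.

A prepaid grid pairs quasi-random parameter vectors with long-run summary
statistic means, per-length statistic covariances estimated from contiguous
splits of one long simulation, and (optionally) banks of raw split
statistics used by the sample-based ABC estimators.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np

from .models.base import Model
from .space import ParameterSpace

__all__ = [
    "GridSpec",
    "PrepaidGrid",
    "halton_points",
    "build_grid",
    "scale_covariance",
    "regularize_covariance",
    "save_grid",
    "load_grid",
]

log = logging.getLogger(__name__)

FORMAT_VERSION = 1

#: relative ridge added to covariance diagonals before inversion
_RIDGE = 1e-8

_PRIMES = (2, 3, 5, 7, 11, 13, 17, 19, 23, 29, 31, 37, 41, 43, 47)


def _radical_inverse(indices: np.ndarray, base: int) -> np.ndarray:
    idx = indices.astype(np.int64).copy()
    out = np.zeros(idx.shape, dtype=float)
    f = 1.0 / base
    while (idx > 0).any():
        out += f * (idx % base)
        idx //= base
        f /= base
    return out


def halton_points(omega: int, space: ParameterSpace) -> np.ndarray:
    """First ``omega`` Halton points (prime bases, index starting at 1),
    affinely mapped onto the working-scale box. Deterministic."""
    if omega < 1:
        raise ValueError("omega must be >= 1")
    k = space.ndim
    if k > len(_PRIMES):
        raise ValueError(f"at most {len(_PRIMES)} dimensions supported")
    idx = np.arange(1, omega + 1)
    u = np.stack([_radical_inverse(idx, _PRIMES[d]) for d in range(k)], axis=1)
    return space.lower + u * (space.upper - space.lower)


def scale_covariance(sigma: np.ndarray, t_prepaid: int, t_obs: int) -> np.ndarray:
    """Rescale a stored covariance from length ``t_prepaid`` to ``t_obs``:
    Sigma_hat(T_obs) = (T_prepaid / T_obs) * Sigma_hat(T_prepaid)."""
    if t_prepaid < 1 or t_obs < 1:
        raise ValueError("lengths must be >= 1")
    return (t_prepaid / t_obs) * np.asarray(sigma, dtype=float)


def regularize_covariance(sigma: np.ndarray, ridge: float = _RIDGE) -> np.ndarray:
    """Add ridge * mean(diag) to the diagonal (guards near-singular stats)."""
    sigma = np.asarray(sigma, dtype=float)
    diag_mean = np.einsum("...ii->...i", sigma).mean(axis=-1)
    # absolute floor keeps exactly-degenerate rows invertible
    eps = ridge * np.maximum(diag_mean, 1e-30)
    out = sigma.copy()
    idx = np.arange(sigma.shape[-1])
    out[..., idx, idx] += np.asarray(eps)[..., None]
    return out


@dataclass(frozen=True)
class GridSpec:
    """Build recipe for a prepaid grid."""

    space: ParameterSpace
    omega: int
    t_sim: int
    t_prepaid: tuple[int, ...]
    m: int = 1000
    seed: int = 0
    model_id: str = ""

    def __post_init__(self):
        object.__setattr__(self, "t_prepaid", tuple(int(t) for t in self.t_prepaid))
        if self.omega < 1:
            raise ValueError("omega must be >= 1")
        if self.m < 0:
            raise ValueError("m must be >= 0")
        for t in self.t_prepaid:
            if t < 1 or t > self.t_sim:
                raise ValueError("every t_prepaid must satisfy 1 <= t <= t_sim")


class PrepaidGrid:
    """The prepaid database: parameters, statistic means, covariances, banks.

    Arrays: ``theta`` (omega, K; working scale), ``mu`` (omega, R),
    ``sigma[t]`` (omega, R, R) per stored length, ``bank[t]`` (omega, M_t, R).
    """

    def __init__(
        self,
        theta: np.ndarray,
        mu: np.ndarray,
        sigma: dict[int, np.ndarray],
        bank: dict[int, np.ndarray],
        space: ParameterSpace,
        stat_names: tuple[str, ...],
        stat_ranges: np.ndarray,
        meta: dict | None = None,
    ):
        self.theta = np.asarray(theta, dtype=float)
        self.mu = np.asarray(mu, dtype=float)
        self.sigma = {int(t): np.asarray(s, dtype=float) for t, s in sigma.items()}
        self.bank = {int(t): np.asarray(b, dtype=float) for t, b in bank.items()}
        self.space = space
        self.stat_names = tuple(stat_names)
        self.stat_ranges = np.asarray(stat_ranges, dtype=float)
        self.meta = dict(meta or {})
        self._factors: dict[int, tuple[np.ndarray, np.ndarray]] = {}
        if self.mu.shape != (self.omega, self.n_stats):
            raise ValueError("inconsistent mu shape")
        for t, s in self.sigma.items():
            if s.shape != (self.omega, self.n_stats, self.n_stats):
                raise ValueError(f"inconsistent sigma shape for t={t}")

    @property
    def omega(self) -> int:
        return self.theta.shape[0]

    @property
    def ndim(self) -> int:
        return self.theta.shape[1]

    @property
    def n_stats(self) -> int:
        return len(self.stat_names)

    @property
    def t_prepaid(self) -> tuple[int, ...]:
        return tuple(sorted(self.sigma))

    def nearest_t(self, t_obs: int) -> int:
        """Stored length closest to ``t_obs`` on log scale (ties: smaller)."""
        ts = np.array(self.t_prepaid, dtype=float)
        d = np.abs(np.log(ts) - np.log(float(t_obs)))
        return int(ts[int(np.argmin(d))])

    def _sigma_factors(self, t: int) -> tuple[np.ndarray, np.ndarray]:
        """Cached (inverse, logdet) of the regularized stored covariances."""
        if t not in self._factors:
            sig = regularize_covariance(self.sigma[t])
            chol = np.linalg.cholesky(sig)
            logdet = 2.0 * np.log(np.einsum("...ii->...i", chol)).sum(axis=-1)
            inv = np.linalg.inv(sig)
            self._factors[t] = (inv, logdet)
        return self._factors[t]

    def loglik(self, s_obs: np.ndarray, t_obs: int) -> np.ndarray:
        """Synthetic log-likelihood of ``s_obs`` at every grid row, using the
        stored covariance nearest to ``t_obs`` in log scale, rescaled."""
        s_obs = np.asarray(s_obs, dtype=float)
        tp = self.nearest_t(t_obs)
        c = tp / float(t_obs)
        inv, logdet = self._sigma_factors(tp)
        d = s_obs - self.mu
        quad = np.einsum("or,ors,os->o", d, inv, d) / c
        return -0.5 * quad - 0.5 * (logdet + self.n_stats * np.log(c))

    def sigma_scaled(self, row: int, t_obs: int) -> np.ndarray:
        tp = self.nearest_t(t_obs)
        return scale_covariance(self.sigma[tp][row], tp, t_obs)


def point_rng(master_seed: int, index: int) -> np.random.Generator:
    """Per-point stream derived from (master seed, point index); independent
    of build order / worker partitioning."""
    return np.random.default_rng(np.random.SeedSequence(master_seed, spawn_key=(index,)))


def build_grid(model: Model, spec: GridSpec, verbose: bool = False) -> PrepaidGrid:
    """Build the prepaid database for ``model`` according to ``spec``.

    Per grid point: one length-``t_sim`` run; the statistic vector of the
    full run is the long-run mean; the sample covariance of statistics over
    contiguous length-t splits gives the per-length covariance; the first
    ``m`` split statistics fill the ABC bank.
    """
    space = spec.space
    R = model.n_stats
    for t in spec.t_prepaid:
        n_splits = spec.t_sim // t
        if n_splits < R + 1:
            raise ValueError(
                f"insufficient splits for t_prepaid={t}: t_sim/t = {n_splits} < R+1 = {R + 1}"
            )
    theta = halton_points(spec.omega, space)
    mu = np.empty((spec.omega, R))
    sigma = {t: np.empty((spec.omega, R, R)) for t in spec.t_prepaid}
    m_per_t = {t: min(spec.m, spec.t_sim // t) for t in spec.t_prepaid}
    bank = {
        t: np.empty((spec.omega, m_per_t[t], R))
        for t in spec.t_prepaid
        if spec.m > 0
    }
    theta_nat = space.to_natural(theta)
    for i in range(spec.omega):
        rng = point_rng(spec.seed, i)
        data = model.simulate(theta_nat[i], spec.t_sim, rng)
        mu[i] = model.summarize(data)
        for t in spec.t_prepaid:
            stats = model.summarize_blocks(data, t)
            sigma[t][i] = np.cov(stats, rowvar=False, ddof=1)
            if spec.m > 0:
                bank[t][i] = stats[: m_per_t[t]]
        if verbose and (i + 1) % max(1, spec.omega // 20) == 0:
            log.info("grid build: %d / %d points", i + 1, spec.omega)
    meta = {
        "model_id": spec.model_id or model.model_id,
        "omega": spec.omega,
        "t_sim": spec.t_sim,
        "t_prepaid": list(spec.t_prepaid),
        "m": spec.m,
        "seed": spec.seed,
    }
    return PrepaidGrid(theta, mu, sigma, bank, space, model.stat_names, model.stat_ranges, meta)


def save_grid(grid: PrepaidGrid, path) -> None:
    """Write a grid to a self-describing HDF5 container (deterministic)."""
    import h5py

    meta = {
        "version": FORMAT_VERSION,
        "stat_names": list(grid.stat_names),
        "space": {
            "names": list(grid.space.names),
            "lower": grid.space.lower.tolist(),
            "upper": grid.space.upper.tolist(),
            "scale": list(grid.space.scale),
        },
        **grid.meta,
    }
    with h5py.File(path, "w", track_order=True) as f:
        f.create_dataset("theta", data=grid.theta, track_times=False)
        f.create_dataset("mu", data=grid.mu, track_times=False)
        f.create_dataset("stat_ranges", data=grid.stat_ranges, track_times=False)
        for t, s in sorted(grid.sigma.items()):
            f.create_dataset(f"sigma/{t}", data=s, track_times=False)
        for t, b in sorted(grid.bank.items()):
            f.create_dataset(f"bank/{t}", data=b, track_times=False)
        f.attrs["meta"] = json.dumps(meta, sort_keys=True)


def load_grid(path) -> PrepaidGrid:
    """Load a grid container written by :func:`save_grid`."""
    import h5py

    try:
        f = h5py.File(path, "r")
    except OSError as exc:
        raise OSError(f"cannot open grid container {path!r}: {exc}") from exc
    with f:
        if "meta" not in f.attrs:
            raise OSError(f"{path!r} is not a prepaid grid container")
        meta = json.loads(f.attrs["meta"])
        version = meta.pop("version", None)
        if version != FORMAT_VERSION:
            raise OSError(
                f"grid container version mismatch: file has {version}, "
                f"this build reads {FORMAT_VERSION}"
            )
        sp = meta.pop("space")
        space = ParameterSpace(
            names=tuple(sp["names"]),
            lower=np.array(sp["lower"]),
            upper=np.array(sp["upper"]),
            scale=tuple(sp["scale"]),
        )
        stat_names = tuple(meta.pop("stat_names"))
        sigma = {int(t): f[f"sigma/{t}"][...] for t in f["sigma"]} if "sigma" in f else {}
        bank = {int(t): f[f"bank/{t}"][...] for t in f["bank"]} if "bank" in f else {}
        return PrepaidGrid(
            theta=f["theta"][...],
            mu=f["mu"][...],
            sigma=sigma,
            bank=bank,
            space=space,
            stat_names=stat_names,
            stat_ranges=f["stat_ranges"][...],
            meta=meta,
        )
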