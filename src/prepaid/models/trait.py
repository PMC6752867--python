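"""Dispersal-limited trait-based community dynamics model.

A local community of J individuals drawn from a regional pool of S species
(evenly spaced on a trait axis 0..100). At each step one random local
individual dies and is replaced either by a regional immigrant (probability
I/(I+J+1)) or by the offspring of a local individual chosen proportionally
to its trait-dependent competitiveness F(u) = 1 + A*exp(-(u-h)^2/(2*sigma^2)).
"""

from __future__ import annotations

from dataclasses import dataclass

import numba as nb
import numpy as np
from scipy.special import xlogy

from ..space import ParameterSpace
from .base import Model

__all__ = [
    "TraitParams",
    "TraitModelConfig",
    "CommunityState",
    "TraitModel",
    "trait_space",
    "filtering_value",
    "simulate_trait",
    "summarize_trait",
    "TRAIT_STAT_NAMES",
]

TRAIT_STAT_NAMES = ("richness", "shannon", "trait_mean", "trait_skew")


@dataclass(frozen=True)
class TraitParams:
    I: float
    A: float
    h: float
    sigma_f: float

    def __post_init__(self):
        if not (self.I > 0 and self.A >= 0 and self.sigma_f > 0):
            raise ValueError(f"invalid trait-model parameters {self.as_array()}")

    def as_array(self) -> np.ndarray:
        return np.array([self.I, self.A, self.h, self.sigma_f], dtype=float)


@dataclass(frozen=True)
class TraitModelConfig:
    """Regional pool size S, local community size J, and snapshot thinning
    (community deaths between recorded statistic snapshots)."""

    S: int = 1000
    J: int = 500
    thinning: int = 500
    burn_deaths: int | None = None  # default 10 * J

    def __post_init__(self):
        if self.S < 2 or self.J < 2 or self.thinning < 1:
            raise ValueError("require S >= 2, J >= 2, thinning >= 1")
        if self.burn_deaths is None:
            object.__setattr__(self, "burn_deaths", 10 * self.J)

    @property
    def traits(self) -> np.ndarray:
        return np.linspace(0.0, 100.0, self.S)


@dataclass(frozen=True)
class CommunityState:
    abundance: np.ndarray  # integer count per regional species, sums to J
    trait: np.ndarray      # trait value per regional species


def trait_space() -> ParameterSpace:
    """log(I) in [3, 5], log(A) in [log 0.1, log 5], h in [-25, 125],
    log(sigma) in [log 0.5, log 25] (natural logs)."""
    return ParameterSpace(
        names=("I", "A", "h", "sigma_f"),
        lower=np.array([3.0, np.log(0.1), -25.0, np.log(0.5)]),
        upper=np.array([5.0, np.log(5.0), 125.0, np.log(25.0)]),
        scale=("log", "log", "linear", "log"),
    )


def immigration_probability(I: float, J: int) -> float:
    """Probability that a dead individual is replaced by a regional
    immigrant rather than local offspring: I / (I + J + 1)."""
    return I / (I + J + 1.0)


def filtering_value(u: np.ndarray | float, params: TraitParams) -> np.ndarray | float:
    """Competitiveness 1 + A*exp(-(u-h)^2 / (2*sigma_f^2))."""
    u = np.asarray(u, dtype=float)
    return 1.0 + params.A * np.exp(-((u - params.h) ** 2) / (2.0 * params.sigma_f ** 2))


@nb.njit(cache=False)
def _community_kernel(abund, F, p_imm, thinning, n_snap, burn, u):
    S = abund.size
    J = 0
    for s in range(S):
        J += abund[s]
    W = 0.0
    for s in range(S):
        W += abund[s] * F[s]
    snaps = np.empty((n_snap, S), np.int64)
    n_events = burn + n_snap * thinning
    for e in range(n_events):
        # refresh the running total periodically to stop FP drift
        if e % 4096 == 0:
            W = 0.0
            for s in range(S):
                W += abund[s] * F[s]
        # death: uniformly chosen individual
        target = u[e, 0] * J
        acc = 0.0
        ds = S - 1
        for s in range(S):
            acc += abund[s]
            if acc > target:
                ds = s
                break
        abund[ds] -= 1
        W -= F[ds]
        # replacement
        if u[e, 1] < p_imm:
            bs = int(u[e, 2] * S)
            if bs >= S:
                bs = S - 1
        else:
            target2 = u[e, 2] * W
            acc = 0.0
            bs = -1
            for s in range(S):
                if abund[s] > 0:
                    acc += abund[s] * F[s]
                    if acc > target2:
                        bs = s
                        break
            if bs < 0:  # FP shortfall: take the last present species
                for s in range(S - 1, -1, -1):
                    if abund[s] > 0:
                        bs = s
                        break
        abund[bs] += 1
        W += F[bs]
        k = e - burn + 1
        if k > 0 and k % thinning == 0:
            snaps[k // thinning - 1] = abund
    return snaps


def _simulate_snapshots(
    params: TraitParams,
    config: TraitModelConfig,
    n_snapshots: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Abundance snapshots (n_snapshots, S) after a discarded transient."""
    if n_snapshots < 1:
        raise ValueError("n_snapshots must be >= 1")
    S, J = config.S, config.J
    F = np.asarray(filtering_value(config.traits, params))
    abund = np.bincount(rng.integers(0, S, size=J), minlength=S).astype(np.int64)
    p_imm = immigration_probability(params.I, J)
    n_events = config.burn_deaths + n_snapshots * config.thinning
    u = rng.random((n_events, 3))
    return _community_kernel(abund, F, p_imm, config.thinning, n_snapshots, config.burn_deaths, u)


def simulate_trait(
    params: TraitParams,
    config: TraitModelConfig,
    n_snapshots: int,
    rng: np.random.Generator,
) -> list[CommunityState]:
    traits = config.traits
    snaps = _simulate_snapshots(params, config, n_snapshots, rng)
    return [CommunityState(a, traits) for a in snaps]


def _snapshot_stats(snaps: np.ndarray, traits: np.ndarray) -> np.ndarray:
    """Vectorized per-snapshot statistics (n, 4) from abundances (n, S)."""
    snaps = np.atleast_2d(snaps).astype(float)
    J = snaps.sum(axis=1, keepdims=True)
    p = snaps / J
    richness = (snaps > 0).sum(axis=1).astype(float)
    shannon = -xlogy(p, p).sum(axis=1)
    m1 = p @ traits
    m2 = p @ traits ** 2 - m1 ** 2
    m3 = p @ traits ** 3 - 3.0 * m1 * (p @ traits ** 2) + 2.0 * m1 ** 3
    with np.errstate(divide="ignore", invalid="ignore"):
        skew = np.where(m2 > 1e-12, m3 / np.maximum(m2, 1e-300) ** 1.5, 0.0)
    return np.stack([richness, shannon, m1, skew], axis=1)


def summarize_trait(state: CommunityState | list[CommunityState]) -> np.ndarray:
    """Richness, Shannon entropy, and mean/skewness of the community trait
    distribution; for a list of states, the average over snapshots."""
    if isinstance(state, CommunityState):
        states = [state]
    else:
        states = list(state)
    traits = states[0].trait
    snaps = np.stack([s.abundance for s in states])
    return _snapshot_stats(snaps, traits).mean(axis=0)


class TraitModel(Model):
    model_id = "trait"
    stat_names = TRAIT_STAT_NAMES

    def __init__(self, config: TraitModelConfig | None = None, space: ParameterSpace | None = None):
        self.config = config if config is not None else TraitModelConfig()
        self.space = space if space is not None else trait_space()
        S, J = self.config.S, self.config.J
        self.stat_ranges = np.array(
            [
                [0.0, float(min(S, J))],
                [0.0, np.log(min(S, J))],
                [0.0, 100.0],
                [-np.inf, np.inf],
            ]
        )

    def simulate(self, theta: np.ndarray, T: int, rng: np.random.Generator) -> np.ndarray:
        """Per-snapshot statistic series (T, 4); one time unit = one recorded
        snapshot (``thinning`` community deaths)."""
        I, A, h, sigma_f = np.asarray(theta, dtype=float)
        params = TraitParams(I, A, h, sigma_f)
        snaps = _simulate_snapshots(params, self.config, T, rng)
        return _snapshot_stats(snaps, self.config.traits)

    def summarize(self, data: np.ndarray) -> np.ndarray:
        data = np.atleast_2d(np.asarray(data, dtype=float))
        return data.mean(axis=0)

    def summarize_blocks(self, data: np.ndarray, block: int) -> np.ndarray:
        n = data.shape[0] // block
        return data[: n * block].reshape(n, block, -1).mean(axis=1)
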