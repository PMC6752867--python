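"""Bounded parameter spaces and priors.

All estimation machinery works on a *working scale*: parameters flagged
``log``/``log10`` are stored and optimized as logarithms, and only
transformed back to the natural scale when estimates are reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np

__all__ = [
    "ParameterSpace",
    "Prior",
    "UniformBoxPrior",
    "BetaBoxPrior",
    "PointMassPrior",
]

_SCALES = ("linear", "log", "log10")


class Prior:
    """Density over a bounded working-scale box."""

    def logpdf(self, theta: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


@dataclass(frozen=True)
class ParameterSpace:
    """A box of parameters with per-axis working scales and a prior.

    ``lower``/``upper`` are bounds on the working scale (i.e. already
    log-transformed for axes flagged ``log`` or ``log10``).
    """

    names: tuple[str, ...]
    lower: np.ndarray
    upper: np.ndarray
    scale: tuple[str, ...]
    prior: Prior | None = field(default=None, compare=False)

    def __post_init__(self):
        lower = np.asarray(self.lower, dtype=float)
        upper = np.asarray(self.upper, dtype=float)
        object.__setattr__(self, "lower", lower)
        object.__setattr__(self, "upper", upper)
        if not (len(self.names) == lower.size == upper.size == len(self.scale)):
            raise ValueError("names, bounds and scale must have equal length")
        if not (np.isfinite(lower).all() and np.isfinite(upper).all()):
            raise ValueError("bounds must be finite")
        if not (lower < upper).all():
            raise ValueError("require lower < upper elementwise")
        for s in self.scale:
            if s not in _SCALES:
                raise ValueError(f"unknown scale {s!r}; expected one of {_SCALES}")
        if self.prior is None:
            object.__setattr__(self, "prior", UniformBoxPrior(lower, upper))

    @property
    def ndim(self) -> int:
        return len(self.names)

    @property
    def range(self) -> np.ndarray:
        return self.upper - self.lower

    def contains(self, theta: np.ndarray, atol: float = 1e-9) -> np.ndarray:
        theta = np.atleast_2d(np.asarray(theta, dtype=float))
        return ((theta >= self.lower - atol) & (theta <= self.upper + atol)).all(axis=-1)

    def clip(self, theta: np.ndarray) -> np.ndarray:
        return np.clip(theta, self.lower, self.upper)

    def to_natural(self, theta: np.ndarray) -> np.ndarray:
        """Map working-scale parameters to the natural scale."""
        theta = np.asarray(theta, dtype=float)
        out = theta.copy()
        for k, s in enumerate(self.scale):
            if s == "log":
                out[..., k] = np.exp(theta[..., k])
            elif s == "log10":
                out[..., k] = 10.0 ** theta[..., k]
        return out

    def from_natural(self, theta: np.ndarray) -> np.ndarray:
        theta = np.asarray(theta, dtype=float)
        out = theta.copy()
        for k, s in enumerate(self.scale):
            if s == "log":
                out[..., k] = np.log(theta[..., k])
            elif s == "log10":
                out[..., k] = np.log10(theta[..., k])
        return out

    def label(self, k: int) -> str:
        """Report label for axis ``k`` (e.g. ``log(I)`` for a log axis)."""
        if self.scale[k] == "linear":
            return self.names[k]
        if self.scale[k] == "log10":
            return f"log10({self.names[k]})"
        return f"log({self.names[k]})"


@dataclass(frozen=True)
class UniformBoxPrior(Prior):
    """Uniform density on a working-scale box (the default grid prior)."""

    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "lower", np.asarray(self.lower, dtype=float))
        object.__setattr__(self, "upper", np.asarray(self.upper, dtype=float))

    @property
    def _log_volume(self) -> float:
        return float(np.sum(np.log(self.upper - self.lower)))

    def logpdf(self, theta: np.ndarray) -> np.ndarray:
        theta = np.atleast_2d(np.asarray(theta, dtype=float))
        inside = ((theta >= self.lower) & (theta <= self.upper)).all(axis=-1)
        out = np.where(inside, -self._log_volume, -np.inf)
        return out

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return rng.uniform(self.lower, self.upper, size=(n, self.lower.size))


@dataclass(frozen=True)
class BetaBoxPrior(Prior):
    """Independent Beta marginals mapped affinely onto a box.

    Each axis k: (x_k - lower_k)/(upper_k - lower_k) ~ Beta(a_k, b_k).
    With a = b = 1 this reduces to the uniform box prior.
    """

    lower: np.ndarray
    upper: np.ndarray
    a: np.ndarray
    b: np.ndarray

    def __post_init__(self):
        for name in ("lower", "upper", "a", "b"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))

    def logpdf(self, theta: np.ndarray) -> np.ndarray:
        from scipy.stats import beta as beta_dist

        theta = np.atleast_2d(np.asarray(theta, dtype=float))
        width = self.upper - self.lower
        z = (theta - self.lower) / width
        inside = ((z >= 0.0) & (z <= 1.0)).all(axis=-1)
        z = np.clip(z, 0.0, 1.0)
        lp = beta_dist.logpdf(z, self.a, self.b) - np.log(width)
        lp = lp.sum(axis=-1)
        return np.where(inside, lp, -np.inf)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        z = rng.beta(self.a, self.b, size=(n, self.a.size))
        return self.lower + z * (self.upper - self.lower)


@dataclass(frozen=True)
class PointMassPrior(Prior):
    """Degenerate prior concentrated at one point (diagnostic use only)."""

    point: np.ndarray
    atol: float = 1e-12

    def __post_init__(self):
        object.__setattr__(self, "point", np.asarray(self.point, dtype=float))

    def logpdf(self, theta: np.ndarray) -> np.ndarray:
        theta = np.atleast_2d(np.asarray(theta, dtype=float))
        hit = np.isclose(theta, self.point, atol=self.atol).all(axis=-1)
        return np.where(hit, 0.0, -np.inf)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return np.tile(self.point, (n, 1))
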