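"""Toy model: i.i.d. normal draws with known SD and unknown mean.

Two summary-statistic choices are supported: the sample mean (situation 1,
a sufficient statistic) and its square (situation 2, a nonlinear statistic).
"""

from __future__ import annotations

import numpy as np

from ..space import ParameterSpace
from .base import Model

__all__ = ["ToyNormalModel", "toy_space"]


def toy_space(lower: float = -5.0, upper: float = 5.0) -> ParameterSpace:
    return ParameterSpace(
        names=("mu",),
        lower=np.array([lower]),
        upper=np.array([upper]),
        scale=("linear",),
    )


class ToyNormalModel(Model):
    model_id = "toynormal"

    def __init__(
        self,
        s: float = 1.0,
        space: ParameterSpace | None = None,
        situation: int = 1,
    ):
        if situation not in (1, 2):
            raise ValueError("situation must be 1 (mean) or 2 (squared mean)")
        self.s = float(s)
        self.situation = situation
        self.space = space if space is not None else toy_space()
        if situation == 1:
            self.stat_names = ("ybar",)
            self.stat_ranges = np.array([[-np.inf, np.inf]])
        else:
            self.stat_names = ("ybar_sq",)
            self.stat_ranges = np.array([[0.0, np.inf]])

    def simulate(self, theta: np.ndarray, T: int, rng: np.random.Generator) -> np.ndarray:
        (mu,) = np.asarray(theta, dtype=float)
        return rng.normal(mu, self.s, size=T)

    def summarize(self, data: np.ndarray) -> np.ndarray:
        m = float(np.mean(data))
        return np.array([m if self.situation == 1 else m * m])

    def summarize_blocks(self, data: np.ndarray, block: int) -> np.ndarray:
        n = data.shape[0] // block
        m = data[: n * block].reshape(n, block).mean(axis=1)
        return (m if self.situation == 1 else m * m)[:, None]
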