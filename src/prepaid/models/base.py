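"""Simulator / summary-statistic contract shared by all models."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..space import ParameterSpace

__all__ = ["SummaryVector", "Model"]


@dataclass(frozen=True)
class SummaryVector:
    """A named vector of summary statistics with admissible ranges.

    ``valid_range`` is an (R, 2) array of per-statistic bounds used to
    clamp interpolator output to physically possible values.
    """

    names: tuple[str, ...]
    values: np.ndarray
    valid_range: np.ndarray

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        vr = np.asarray(self.valid_range, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "valid_range", vr)
        if values.size != len(self.names) or vr.shape != (values.size, 2):
            raise ValueError("inconsistent summary-vector dimensions")

    def __len__(self) -> int:
        return len(self.names)


class Model:
    """Base class for prepaid-estimable models.

    A model provides a bounded :class:`~prepaid.space.ParameterSpace`, a
    simulator producing a dataset whose leading axis is "time" (so a long
    run can be split into contiguous chunks), and a summarizer mapping a
    dataset to a fixed-length statistic vector.
    """

    model_id: str
    space: ParameterSpace
    stat_names: tuple[str, ...]
    stat_ranges: np.ndarray  # (R, 2)

    @property
    def n_stats(self) -> int:
        return len(self.stat_names)

    def simulate(self, theta: np.ndarray, T: int, rng: np.random.Generator) -> np.ndarray:
        """Simulate a dataset of T time units at natural-scale ``theta``."""
        raise NotImplementedError

    def summarize(self, data: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def summarize_blocks(self, data: np.ndarray, block: int) -> np.ndarray:
        """Statistics of contiguous non-overlapping length-``block`` chunks.

        Default implementation loops over :meth:`summarize`; models may
        override with a vectorized version. The leftover tail is dropped.
        """
        n = data.shape[0] // block
        return np.stack([self.summarize(data[i * block:(i + 1) * block]) for i in range(n)])

    def summary_vector(self, data: np.ndarray) -> SummaryVector:
        return SummaryVector(self.stat_names, self.summarize(data), self.stat_ranges)

    def simulate_stats(self, theta: np.ndarray, T: int, rng: np.random.Generator) -> np.ndarray:
        return self.summarize(self.simulate(theta, T, rng))
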