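import numpy as np
import pytest

from prepaid.models import RickerModel, ToyNormalModel
from prepaid.prepaid_grid import GridSpec, build_grid


@pytest.fixture(scope="session")
def toy_model():
    return ToyNormalModel(s=1.0)


@pytest.fixture(scope="session")
def toy_grid(toy_model):
    """Dense 1-D toy grid used across estimator tests."""
    spec = GridSpec(
        space=toy_model.space, omega=300, t_sim=10_000, t_prepaid=(100,), m=20, seed=123
    )
    return build_grid(toy_model, spec)


@pytest.fixture(scope="session")
def ricker_model():
    return RickerModel()


@pytest.fixture(scope="session")
def ricker_mini_grid(ricker_model):
    """Small Ricker grid for unit tests (not the reduced study grid)."""
    spec = GridSpec(
        space=ricker_model.space, omega=200, t_sim=5000, t_prepaid=(100,), m=8, seed=7
    )
    return build_grid(ricker_model, spec)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
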