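import numpy as np
import pytest

from clonedyn import (
    CloneState,
    GrowthParams,
    InteractionParams,
    ModelParams,
)


@pytest.fixture(scope="session")
def base_growth():
    """The taxonomy-simulation growth constants."""
    return GrowthParams(k_sensitive=1.0, k_resistant=0.5, capacity=6e5)


@pytest.fixture(scope="session")
def invitro_growth():
    """Monoculture-derived growth constants of the fluorescence experiments."""
    return GrowthParams(k_sensitive=1.069, k_resistant=0.4695, capacity=6e5)


@pytest.fixture(scope="session")
def plain_params(base_growth):
    return ModelParams(base_growth)


@pytest.fixture(scope="session")
def mutualistic_params(base_growth):
    """Unweighted mutualism at the published constants."""
    return ModelParams(base_growth, InteractionParams(1e-6, 1e-6, weighted=False))


@pytest.fixture(scope="session")
def equal_seed():
    return CloneState(5e4, 5e4)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20231360)


def random_states(rng, n, scale=6e5):
    """Nonnegative random (G, R) pairs spanning several magnitudes."""
    mags = 10 ** rng.uniform(-1, 1, size=(n, 2))
    return rng.uniform(0, scale, size=(n, 2)) * mags
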