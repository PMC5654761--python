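import numpy as np
import pytest

from eidhotspots import BoostConfig, SynthConfig, generate_world
from eidhotspots.grid import GridSpec


@pytest.fixture(scope="session")
def world():
    """One default synthetic world shared across tests (read-only)."""
    return generate_world(SynthConfig(seed=7))


@pytest.fixture(scope="session")
def fast_boost():
    """Boosting config scaled for unit-test speed."""
    return BoostConfig(learning_rate=0.05, step_size=25,
                       internal_cv_folds=5, max_trees=500, patience=2)


@pytest.fixture(scope="session")
def desk_boost():
    """Boosting config used for desk-scale ensemble and CV runs."""
    return BoostConfig(learning_rate=0.01, internal_cv_folds=5,
                       max_trees=1000, patience=3)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def one_deg_grid():
    """The full 1° study lattice with an all-land mask."""
    return GridSpec()
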