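import numpy as np
import pytest

from tauread import build_synthetic_atlas


@pytest.fixture(scope="session")
def atlas():
    """Default 48-cube, 2 mm synthetic atlas shared across tests."""
    return build_synthetic_atlas((48, 48, 48), (2.0, 2.0, 2.0))


@pytest.fixture(scope="session")
def small_atlas():
    """Smallest supported atlas, for cheap construction tests."""
    return build_synthetic_atlas((16, 16, 16), (3.0, 3.0, 3.0))


@pytest.fixture()
def rng():
    return np.random.default_rng(20260921)
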