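import numpy as np
import pytest

from nicheshift import GridSpec, make_demo_study


@pytest.fixture(scope="session")
def small_grid() -> GridSpec:
    """20x20 grid at 0.1 degree cells over a mid-latitude window."""
    return GridSpec(n_rows=20, n_cols=20, cell_size=0.1, origin_lon=80.0, origin_lat=45.0)


@pytest.fixture(scope="session")
def demo_study():
    """Session-wide synthetic study: 6 layers, 194 raw presences, known truth."""
    return make_demo_study(n_layers=6, seed=2)


@pytest.fixture(scope="session")
def recovery_study():
    """Study sized for truth-recovery checks: 1 active + 3 noise layers, 500 presences."""
    return make_demo_study(n_layers=4, n_presences=500, duplicate_fraction=0.0, seed=1)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
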