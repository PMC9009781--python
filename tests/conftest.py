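import numpy as np
import pytest

from gogrownet import (
    DimensionlessParams,
    ExperimentConfig,
    build_grid,
    generate_reference_dataset,
    make_benchmark,
)
from gogrownet.io import make_test_fixture


@pytest.fixture(scope="session")
def default_params():
    return DimensionlessParams()


@pytest.fixture(scope="session")
def default_grid():
    return build_grid(l=50.0, dxi=1.0, tau_star=10.0, dtau=0.01)


@pytest.fixture(scope="session")
def coarse_battery():
    """Three-configuration coarse battery (l=10, tau*=0.5), MM ground truth."""
    return make_test_fixture(seed=0)


@pytest.fixture(scope="session")
def coarse_params():
    return DimensionlessParams(l=10.0)


@pytest.fixture(scope="session")
def mm_truth():
    return make_benchmark("michaelis_menten", k=2.0)


@pytest.fixture(scope="session")
def gradient_dataset(default_params, default_grid, mm_truth):
    """Full-size reference solve of the (0, 4) gradient configuration."""
    config = ExperimentConfig(o2_left=0.0, o2_right=4.0, label=2)
    return generate_reference_dataset(config, default_params, mm_truth, default_grid)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
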