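import numpy as np
import pytest

from mscancer import PreprocessConfig, SimConfig, SVMConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_pre_cfg():
    """Coarse grid so preprocessing tests run in milliseconds."""
    return PreprocessConfig(grid_n=3000)


@pytest.fixture
def small_sim_cfg():
    """Down-scaled cohort (raw axis 12k points) with the default peak set."""
    return SimConfig(raw_n=12000, seed=17)


@pytest.fixture
def coarse_svm_cfg():
    """Sparse hyperparameter grid for fast experiment tests."""
    return SVMConfig(
        c_grid=tuple(2.0 ** e for e in range(-5, 16, 4)),
        g_grid=tuple(2.0 ** e for e in range(-15, 4, 4)),
    )
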