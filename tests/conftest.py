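import numpy as np
import pytest

from v2pool import synthetic


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_map():
    """Noiseless synthetic orientation map with ground truth."""
    cfg = synthetic.MapSimConfig(height=64, width=64, noise_sd=0.0, seed=7)
    return synthetic.simulate_orientation_map(cfg)


@pytest.fixture(scope="session")
def v1_population_16():
    """16 complex cells, POs on a uniform grid, identical aspect ratio."""
    cells, tunings = synthetic.simulate_v1_population(
        16, seed=11, po_mode="grid", gamma_range=(1.0, 1.0))
    return cells, tunings
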