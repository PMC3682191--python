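import numpy as np
import pytest

from repdim.core import PatternDataset
from repdim.simulate import SimConfig, make_random_features, simulate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_dataset():
    """Two conditions, one unit, two runs; all statistics computable by hand."""
    return PatternDataset(
        values=np.array([[1.0], [2.0], [3.0], [4.0]]),
        condition=np.array([1, 2, 1, 2]),
        run=np.array([1, 1, 2, 2]),
    )


@pytest.fixture
def sim_dataset(rng):
    """Moderate-signal 4-condition dataset with known 2-D structure."""
    spec = make_random_features(4, 2, rng)
    cfg = SimConfig(P=30, n_runs=6, sigma_a2=0.4)
    return simulate_dataset(spec, cfg, rng)
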