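import numpy as np
import pytest

from hdboost import LabeledDataset, SimulationConfig, simulate_block_mvn


@pytest.fixture(scope="session")
def small_block_mvn():
    """One train/test replicate of the standard high-dimensional benchmark
    (p=1000, n=50, mu2=0.7, rho=0.8, 100 DE variables, 500+500 test)."""
    return simulate_block_mvn(SimulationConfig(seed=42))


@pytest.fixture
def toy_separable():
    """Ten samples, two features; feature 0 separates the classes."""
    rng = np.random.default_rng(0)
    x0 = np.r_[rng.uniform(-2, -1, 5), rng.uniform(1, 2, 5)]
    x1 = rng.standard_normal(10)
    y = np.repeat([1, 2], 5)
    return LabeledDataset(np.column_stack([x0, x1]), y)
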