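import numpy as np
import pytest

from cosmospot import SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def tiny_sim():
    """Small simulated dataset with ground truth (shared, read-only)."""
    cfg = SimConfig(N=3, Nc=2, F=8, P=10, pi=0.3, lam=0.3, seed=42)
    ds, truth = simulate_dataset(cfg)
    return ds, truth, cfg


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
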