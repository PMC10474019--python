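import matplotlib

matplotlib.use("Agg")

import numpy as np
import pytest

import trialdecode as td


@pytest.fixture(scope="session")
def demo_dataset():
    """Desk-scale study with a choice pattern at 200-300 ms (SNR 1)."""
    cfg = td.demo_config(seed=7)
    epochs, trials = td.simulate_dataset(cfg)
    return cfg, epochs, trials


@pytest.fixture(scope="session")
def null_dataset():
    """Desk-scale study with no decodable signal."""
    cfg = td.null_config(seed=11)
    epochs, trials = td.simulate_dataset(cfg)
    return cfg, epochs, trials


@pytest.fixture(scope="session")
def tiny_dataset():
    """Very small dataset for fast structural tests."""
    cfg = td.SimConfig(n_subjects=3, n_stimuli=12, n_channels=6, sfreq=10.0, seed=3)
    epochs, trials = td.simulate_dataset(cfg)
    return cfg, epochs, trials


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
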