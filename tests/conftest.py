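import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make helpers importable

from phasebind import SimConfig, simulate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture
def trial_table():
    """A small hand-made valid trial table."""
    n = 12
    return pd.DataFrame({
        "subject_id": ["s01"] * n,
        "trial_id": np.arange(n),
        "condition": ["short", "long"] * (n // 2),
        "t_move": np.linspace(1.2, 2.4, n),
        "t_stim": np.linspace(-0.7, 0.8, n),
        "outcome": [0, 1] * (n // 2),
    })


@pytest.fixture(scope="session")
def small_dataset():
    """Two simulated subjects at modest size, shared across tests."""
    cfg = SimConfig(n_subjects=2, n_trials=80, n_channels=3, fs=500.0)
    return cfg, simulate_dataset(cfg, seed=101)
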