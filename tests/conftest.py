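"""Shared fixtures: small simulated dyad datasets built at test time."""

import numpy as np
import pytest

from covgreml import simulate_model_mode
from covgreml.pipeline import DyadDataset

#: Generating components used across the suite: genetic and residual
#: covariance 0.15 each (total trait covariance 0.30), variances 0.3 / 0.7.
THETA_DEFAULT = np.array([0.3, 0.15, 0.3, 0.7, 0.15, 0.7])


@pytest.fixture(scope="session")
def small_model_dataset():
    """n=300 model-mode dataset with its analysis-ready pipeline object."""
    panel, dyads, truth = simulate_model_mode(300, 500, THETA_DEFAULT, seed=11)
    data = DyadDataset.from_panel(panel, dyads, n_pcs=0, rel_threshold=None)
    return panel, dyads, truth, data


@pytest.fixture(scope="session")
def tiny_model_dataset():
    """n=60 model-mode dataset for expensive per-replicate checks."""
    panel, dyads, truth = simulate_model_mode(60, 200, THETA_DEFAULT, seed=7)
    data = DyadDataset.from_panel(panel, dyads, n_pcs=0, rel_threshold=None)
    return panel, dyads, truth, data
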