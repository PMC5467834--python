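import numpy as np
import pytest

from roiglasso.forward_sim import simulate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """Two-subject dataset at reduced size for fast structural tests."""
    return simulate_dataset(
        2, n_rois=6, size_profile=(14, 10, 9, 9, 8, 12), n_sensors=24,
        T=31, active_rois=(1, 3), seed=123)


@pytest.fixture(scope="session")
def protocol_subject():
    """One subject under the full protocol conditions."""
    return simulate_dataset(1, seed=2024)
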