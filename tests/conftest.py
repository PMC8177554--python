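import numpy as np
import pytest

from gaitdnd import condition_presets, simulate_record


@pytest.fixture(scope="session")
def clean_con_record():
    """Noiseless, artifact-free 60-s control record with ground truth."""
    config = condition_presets(
        "CON", duration_s=60.0, noise_sd=0.0, spike_rate_per_min=0.0
    )
    return simulate_record(config, seed=7)


@pytest.fixture(scope="session")
def noisy_als_record():
    """ALS record at preset noise, no spikes, 120 s."""
    config = condition_presets(
        "ALS", duration_s=120.0, spike_rate_per_min=0.0
    )
    return simulate_record(config, seed=21)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
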