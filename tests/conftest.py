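import numpy as np
import pytest

from arcnet.core import SpikeTrain
from arcnet.synthetic import ScenarioConfig, generate_three_epoch_dataset


@pytest.fixture(scope="session")
def small_culture():
    """One refinement culture at reduced size, shared across tests."""
    return generate_three_epoch_dataset(ScenarioConfig(n_neurons=40, seed=7))


@pytest.fixture(scope="session")
def nonrefined_culture():
    return generate_three_epoch_dataset(
        ScenarioConfig(n_neurons=40, seed=7, refinement=False)
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_train(rng, duration_s=60.0, max_spikes=30, ms_aligned=False):
    """Random spike train helper for fuzz/oracle tests."""
    n = rng.integers(1, max_spikes + 1)
    times = rng.uniform(0.0, duration_s, size=n)
    if ms_aligned:
        times = np.round(times, 3)
    return SpikeTrain(np.sort(times), duration_s)
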