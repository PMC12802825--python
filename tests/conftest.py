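import numpy as np
import pytest

from ctplac.core import CTPVolume
from ctplac.phantom import PhantomConfig, generate_phantom, noiseless
from ctplac.preprocess import brain_mask, temporal_average


@pytest.fixture(scope="session")
def default_config():
    return PhantomConfig()


@pytest.fixture(scope="session")
def noiseless_case():
    """Deterministic zero-noise phantom shared across tests."""
    vol, labels, truth = generate_phantom(noiseless(), seed=0)
    return vol, labels, truth


@pytest.fixture(scope="session")
def noisy_case():
    vol, labels, truth = generate_phantom(PhantomConfig(), seed=42)
    return vol, labels, truth


@pytest.fixture(scope="session")
def noiseless_masked(noiseless_case):
    vol, labels, truth = noiseless_case
    mask = brain_mask(temporal_average(vol))
    return vol, labels, truth, mask


@pytest.fixture(scope="session")
def noisy_masked(noisy_case):
    vol, labels, truth = noisy_case
    mask = brain_mask(temporal_average(vol))
    return vol, labels, truth, mask


@pytest.fixture
def random_volume():
    """Factory for small random CTP volumes (anisotropic by default)."""

    def make(shape=(5, 4, 5, 6), spacing=(0.7, 1.0, 0.9), seed=0, scale=50.0, offset=40.0):
        rng = np.random.default_rng(seed)
        data = offset + scale * rng.standard_normal(shape)
        times = np.arange(shape[0], dtype=float) * 2.0
        return CTPVolume(data, spacing, times)

    return make
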