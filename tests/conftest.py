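import numpy as np
import pytest

from odormap import SynthConfig, TrainConfig, gen_dataset, gen_toy_fixture


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_pair():
    return gen_toy_fixture()


@pytest.fixture
def fast_config():
    """Training config with the standard constants but a small epoch budget."""
    return TrainConfig(epochs=10, seed=0)


@pytest.fixture(scope="session")
def small_dataset():
    """Reduced-size synthetic dataset shared by slower tests."""
    cfg = SynthConfig(
        n_samples=40, n_mz_bins=24, n_descriptors=12, latent_dim=2,
        peaks_per_spectrum=5, seed=7,
    )
    spectra, sensory, truth = gen_dataset(cfg)
    return spectra.values, sensory.values, truth
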