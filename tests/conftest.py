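import numpy as np
import pytest

from dkiprep import phantom


@pytest.fixture(scope="session")
def clinical_protocol():
    """The clinical multi-shell scheme: 5 b0, 4 b250, 20 b1000, 60 b2000."""
    return phantom.make_protocol()


@pytest.fixture(scope="session")
def small_phantom():
    """Small multi-shell phantom shared by read-only tests."""
    return phantom.make_multishell_phantom((24, 24, 8), seed=11)


@pytest.fixture(scope="session")
def small_noisy(small_phantom):
    """One SNR-20 Rician realization of the small phantom."""
    noise = phantom.NoiseModel.from_truth(small_phantom, 20.0, seed=21)
    return phantom.add_rician_noise(small_phantom.truth, noise)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
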