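import numpy as np
import pytest

from adiposeat import coil, synthetic as syn

DEFAULT_GRADIENT = (3000.0, -0.5)


@pytest.fixture(scope="session")
def noiseless_subject():
    """One noiseless subject at the population-mean SubQF contrast."""
    params = syn.SubjectParams(subqf_contrast=0.58, noise_sd=0.0, seed=3)
    return syn.generate_subject_slice(params)


@pytest.fixture(scope="session")
def noisy_subject():
    params = syn.SubjectParams(subqf_contrast=0.58, seed=11)
    return syn.generate_subject_slice(params)


@pytest.fixture(scope="session")
def phantom_curve():
    """Normalization curve fitted to a noiseless phantom with the default gradient."""
    phantom, mask = syn.generate_phantom_scan(
        gradient=DEFAULT_GRADIENT, noise_sd=0.0, seed=0
    )
    return coil.fit_normalization_curve(phantom, mask)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
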