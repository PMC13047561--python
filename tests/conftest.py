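import numpy as np
import pandas as pd
import pytest

import mangonir as m
from mangonir.simulate import scale_noise


@pytest.fixture(scope="session")
def profiles():
    return m.default_profiles()


@pytest.fixture(scope="session")
def noiseless_profiles():
    return scale_noise(m.default_profiles(), fluctuation_frac=0.0,
                       noise_frac=0.0, spectral_noise_sd=0.0)


@pytest.fixture(scope="session")
def small_design():
    """One variety, full 11-batch window, few fruit: fast but structured."""
    return m.SamplingDesign(varieties=("Tainong",), batches_per_variety=(11,),
                            fruits_per_batch=5)


@pytest.fixture(scope="session")
def small_dataset(small_design, profiles):
    quality = m.generate_quality(small_design, profiles, seed=101)
    spectra = m.generate_spectra(quality, profiles, seed=101)
    return spectra, quality


@pytest.fixture(scope="session")
def full_dataset(profiles):
    """The complete three-variety study design (775 fruit)."""
    return m.generate_dataset(seed=2026)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_spectrumset(rng, n=10, p=30):
    wl = np.linspace(650, 950, p)
    ab = 0.5 + 0.1 * rng.standard_normal((n, p))
    return m.SpectrumSet(wl, ab, [f"s{i}" for i in range(n)])


@pytest.fixture()
def random_spectra(rng):
    return random_spectrumset(rng)
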