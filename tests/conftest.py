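import numpy as np
import pytest

from brixmap import SpectraTable, SynthConfig, generate_spectra


@pytest.fixture(scope="session")
def small_dataset():
    """120-sample synthetic dataset with default study conditions."""
    return generate_spectra(SynthConfig(n_samples=120, seed=42))


@pytest.fixture(scope="session")
def small_table(small_dataset):
    return small_dataset.to_table()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def linear_table(rng):
    """Noiseless exactly-linear toy: y is a fixed linear map of x."""
    n, p = 40, 8
    x = rng.normal(size=(n, p))
    beta = np.arange(1, p + 1, dtype=float)
    y = 2.0 + x @ beta
    return SpectraTable(
        x=x, wavelengths=np.linspace(400, 1000, p), y=y
    )
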