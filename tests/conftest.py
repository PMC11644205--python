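import numpy as np
import pytest

from forelule.chromaticity import FuiLookupTable


@pytest.fixture(scope="session")
def table() -> FuiLookupTable:
    return FuiLookupTable.default()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20131223)


@pytest.fixture(scope="session")
def random_spectra():
    """10,000 random valid water-like spectra, (N, 4) in sr^-1."""
    gen = np.random.default_rng(8)
    return gen.uniform(0.0005, 0.03, size=(10_000, 4))
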