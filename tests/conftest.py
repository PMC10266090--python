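import numpy as np
import pytest

from rmtfc import EigSpectrum, simulate_goe


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20230614)


@pytest.fixture(scope="session")
def fixture_spectrum_100():
    """Fixed 100-eigenvalue spectrum for bookkeeping tests (all positive)."""
    r = np.random.default_rng(42)
    vals = np.sort(r.uniform(0.5, 120.0, size=100))
    return EigSpectrum(vals)


@pytest.fixture(scope="session")
def goe_2000():
    """One GOE spectrum of size 2000, shared across tests."""
    return simulate_goe(2000, seed=7)
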