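import numpy as np
import pytest

from gwasthresh import simulate_genotypes


@pytest.fixture(scope="session")
def small_panel():
    """60 individuals x 150 markers on 3 chromosomes, modest LD."""
    return simulate_genotypes(60, 150, n_chromosomes=3, ld_rho=0.3, seed=42)


@pytest.fixture(scope="session")
def medium_panel():
    """200 individuals x 1000 markers, used by scan-level tests."""
    return simulate_genotypes(200, 1000, n_chromosomes=5, ld_rho=0.3, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260920)
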