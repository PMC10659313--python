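import numpy as np
import pytest

from fitland import generate_landscape, sample_local_dataset

# L=20 wild type covering every amino acid once; keeps fixtures small.
WT20 = "ACDEFGHIKLMNPQRSTVWY"


@pytest.fixture(scope="session")
def wt20():
    return WT20


@pytest.fixture(scope="session")
def additive_landscape():
    """Purely additive landscape (no epistasis, no noise)."""
    return generate_landscape(WT20, epistasis_density=0.0, seed=11)


@pytest.fixture(scope="session")
def epistatic_landscape():
    """Landscape with dense, strong pairwise epistasis."""
    return generate_landscape(
        WT20, epistasis_density=0.05, epistasis_sd=2.0, seed=12
    )


@pytest.fixture(scope="session")
def local_dataset(epistatic_landscape):
    return sample_local_dataset(
        epistatic_landscape, double_fraction=0.05, noise_sd=0.0, seed=13
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)
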