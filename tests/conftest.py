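import numpy as np
import pytest

from neutralforest.census_io import Census
from neutralforest.fixtures import FixtureSpec, generate_clustered_community


@pytest.fixture
def rng():
    return np.random.default_rng(20250901)


@pytest.fixture(scope="session")
def csr_census():
    """Complete-spatial-randomness census: 2000 trees, 20 species, 300 x 160 m."""
    r = np.random.default_rng(42)
    n = 2000
    return Census(
        x=r.uniform(0, 300, n),
        y=r.uniform(0, 160, n),
        species=r.integers(0, 20, n),
        width=300.0,
        height=160.0,
    )


@pytest.fixture(scope="session")
def clustered_census():
    """Small clustered multi-species census from the Thomas-process generator."""
    spec = FixtureSpec(n_species=60, logser_p=0.99, width=300.0, height=160.0, sigma_c=8.0)
    return generate_clustered_community(spec, rng=np.random.default_rng(7))


@pytest.fixture
def toy_census():
    """Hand-sized census for exact brute-force checks."""
    r = np.random.default_rng(5)
    n = 30
    return Census(
        x=r.uniform(0, 100, n),
        y=r.uniform(0, 80, n),
        species=r.integers(0, 5, n),
        width=100.0,
        height=80.0,
    )
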