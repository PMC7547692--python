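import numpy as np
import pytest

from soilscape.grid import GridDomain
from soilscape.synthetic import generate_dem


@pytest.fixture(scope="session")
def domain32():
    return GridDomain(32, 32)


@pytest.fixture(scope="session")
def natural_dem(domain32):
    return generate_dem(domain32, "natural", relief=15.0, seed=3)


@pytest.fixture(scope="session")
def consolidated_dem(domain32):
    return generate_dem(domain32, "consolidated", relief=15.0, seed=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
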