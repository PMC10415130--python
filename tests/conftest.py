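import numpy as np
import pytest

from pr2kinetics.rate_model import (
    RateSet,
    table1_individual_means,
    table1_symmetric_means,
    nsb_expand,
)


@pytest.fixture(scope="session")
def table1_rates() -> RateSet:
    """The packaged 12 individual human rate means."""
    return table1_individual_means()


@pytest.fixture(scope="session")
def table1_symmetric():
    """The packaged strand-symmetry-averaged six rates."""
    return table1_symmetric_means()


@pytest.fixture(scope="session")
def table1_nsb_rates(table1_symmetric) -> RateSet:
    """The symmetric means expanded into an exactly NSB 12-rate set."""
    return nsb_expand(table1_symmetric)


@pytest.fixture
def random_rate_set() -> RateSet:
    """A generic strictly positive rate set (no NSB structure)."""
    rng = np.random.default_rng(20240917)
    return RateSet.from_vector(rng.uniform(0.05, 2.0, 12))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(8675309)
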