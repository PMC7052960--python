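import numpy as np
import pytest

from markovcea.config import build_bundle
from markovcea.lifetable import LifeTable
from markovcea.synthetic import GompertzSpec, gompertz_life_table


@pytest.fixture(scope="session")
def bundle():
    """Default configuration with the bundled life table."""
    return build_bundle()


@pytest.fixture(scope="session")
def lt(bundle):
    return bundle.life_table


@pytest.fixture(scope="session")
def gomp_lt():
    return gompertz_life_table(GompertzSpec())


def constant_life_table(q: float, start: int = 0, terminal: int = 110) -> LifeTable:
    ages = np.arange(start, terminal + 1)
    qx = np.full(ages.shape, float(q))
    qx[-1] = 1.0
    return LifeTable(ages=ages, qx=qx)


@pytest.fixture
def const_q_table():
    return constant_life_table
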