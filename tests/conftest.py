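import numpy as np
import pytest

from amoebacsp.core import SolverConfig
from amoebacsp.sat import example_formula


@pytest.fixture
def formula_f():
    """The 4-variable, 9-clause demo instance with three solutions."""
    return example_formula()


@pytest.fixture
def config():
    return SolverConfig(seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
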