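import numpy as np
import pytest
from hypothesis import settings

from icamod import demo_spec, fastica, generate_expression

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def demo_data():
    """The frozen demonstration fixture: matrix + planted truth (seed 7)."""
    return generate_expression(demo_spec())


@pytest.fixture(scope="session")
def demo_decomposition(demo_data):
    """fastICA of the demo fixture at k = 3 (the planted module count)."""
    matrix, _ = demo_data
    return fastica(matrix, k=3, seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
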