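import numpy as np
import pytest

import gjgate as gj
from gjgate.sweep import default_params


@pytest.fixture(scope="session")
def two_state_params():
    return default_params()


@pytest.fixture(scope="session")
def three_state_params():
    return default_params(three_state=True)


@pytest.fixture(scope="session")
def two12_gen(two_state_params):
    """49-state generator at Vj = 40 mV, shared across read-only tests."""
    p = two_state_params
    return gj.build_generator("two12", p, p, 40.0)


@pytest.fixture(scope="session")
def two12_dense_pi(two12_gen):
    return gj.solve_dense(two12_gen).pi


@pytest.fixture(scope="session")
def three6_gen(three_state_params):
    p = three_state_params
    return gj.build_generator("three6", p, p, 40.0)


@pytest.fixture(scope="session")
def three12_gen(three_state_params):
    p = three_state_params
    return gj.build_generator("three12", p, p, 40.0)


def random_generator_matrix(rng: np.random.Generator, n: int) -> np.ndarray:
    """Dense random irreducible generator (test oracle helper)."""
    q = rng.uniform(0.1, 1.0, size=(n, n))
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    return q
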