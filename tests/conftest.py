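import itertools

import numpy as np
import pytest

from looplaw import figure2_network
from looplaw.model import SignPattern


@pytest.fixture
def fig2():
    return figure2_network()


@pytest.fixture
def cycle3_matrix(fig2):
    """Internal submatrix of the toy cycle: columns M1→M2, M2→M3, M3→M1."""
    from looplaw import internal_submatrix

    return internal_submatrix(fig2)


def random_matrices(count, seed, max_m=4, max_n=5, coeff=2):
    """Deterministic stream of small integer matrices for property suites."""
    rng = np.random.default_rng(seed)
    for _ in range(count):
        m = int(rng.integers(1, max_m + 1))
        n = int(rng.integers(1, max_n + 1))
        yield rng.integers(-coeff, coeff + 1, size=(m, n))


def all_sign_patterns(n):
    for signs in itertools.product((-1, 0, 1), repeat=n):
        yield SignPattern(signs)
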