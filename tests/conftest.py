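import numpy as np
import pytest

import localsem as ls


@pytest.fixture(scope="session")
def one_factor_syntax():
    return "FX =~ X1 + X2 + X3"


@pytest.fixture(scope="session")
def two_factor_syntax():
    return """
    FX =~ X1 + X2 + X3
    FY =~ Y1 + Y2 + Y3
    """


@pytest.fixture(scope="session")
def dgm3_pop_small():
    """Exact-moment null population (one factor, 13 ages, 1000/age)."""
    dgm = ls.dgm_preset("dgm3", n_factors=1, group_size=1000)
    return dgm, ls.make_population(dgm, seed=101)


@pytest.fixture(scope="session")
def dgm1_pop_small():
    dgm = ls.dgm_preset("dgm1", n_factors=1, group_size=1000)
    return dgm, ls.make_population(dgm, seed=202)


@pytest.fixture(scope="session")
def dgm2_pop_two_factor():
    dgm = ls.dgm_preset("dgm2", n_factors=2, group_size=1000)
    return dgm, ls.make_population(dgm, seed=303)


def random_pd(rng, n, jitter=0.5):
    """Random well-conditioned PD matrix."""
    A = rng.standard_normal((n, n))
    return A @ A.T / n + jitter * np.eye(n)
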