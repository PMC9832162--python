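import numpy as np
import pytest
from hypothesis import settings

import epilayers as ep
from epilayers.gf_core import InitialSusceptibility

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture
def regular3():
    """Single 3-regular layer: G(x) = x^3, Gt(x) = x^2."""
    return ep.make_degree_distribution("regular", k=3)


@pytest.fixture
def regular2():
    return ep.make_degree_distribution("regular", k=2)


@pytest.fixture
def poisson_pair():
    """Two Poisson layers, means 50 and 2 (two-type worked configuration)."""
    return (
        ep.make_degree_distribution("poisson", mean=50),
        ep.make_degree_distribution("poisson", mean=2),
    )


@pytest.fixture
def two_regular2_ensemble():
    """Two 2-regular layers with T = (0.25, 0.5): Gt_i = x_i x_j^2."""
    return ep.NetworkEnsemble(
        [
            (ep.make_degree_distribution("regular", k=2), 0.25),
            (ep.make_degree_distribution("regular", k=2), 0.5),
        ]
    )


@pytest.fixture
def full_susceptibility():
    return InitialSusceptibility(mode="constant", s0=1.0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
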