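import numpy as np
import pytest
from hypothesis import settings

from edrnet import mouse_like

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def mouse_fixture():
    """One mouse-regime synthetic species shared across the suite:
    33 areas, <d> = 4.54 mm, lambda = 0.78 /mm, rho = 0.68."""
    return mouse_like(seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_connectome(n, density, rng, labels=None):
    """Erdos-Renyi-style random digraph helper used by several suites."""
    from edrnet import Connectome

    a = (rng.random((n, n)) < density).astype(float)
    np.fill_diagonal(a, 0)
    if labels is None:
        labels = tuple(f"n{i}" for i in range(n))
    return Connectome(labels, a)
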