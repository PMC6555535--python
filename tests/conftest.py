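import numpy as np
import pytest

from riboland.landscape import Landscape
from riboland.synthetic_data import SyntheticSpec, make_dual_pair


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_landscape():
    """Factory for seeded random positive landscapes of any small L."""

    def make(L: int, seed: int = 0, zeros: float = 0.0) -> Landscape:
        r = np.random.default_rng(seed)
        fit = r.uniform(0.05, 2.0, size=1 << L)
        if zeros > 0:
            fit[r.random(fit.size) < zeros] = 0.0
        return Landscape(L=L, fitness=fit, name=f"random{L}")

    return make


@pytest.fixture(scope="session")
def default_pair():
    """The default synthetic dual landscape pair (L=14, seeded)."""
    return make_dual_pair(SyntheticSpec(seed=0))


@pytest.fixture(scope="session")
def small_pair():
    """A small (L=8) synthetic dual pair for exhaustive cross-checks."""
    return make_dual_pair(SyntheticSpec(L=8, seed=3))
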