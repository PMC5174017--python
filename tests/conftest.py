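import numpy as np
import pytest

from hlck import build_layout
from hlck.coefficient_mapping import LinearCoefficientArray
from hlck.synthetic_fixtures import FixtureSpec, generate

# the three small codec geometries used throughout: (S, R, C, L)
SMALL_GEOMETRIES = [(1, 8, 8, 1), (2, 16, 16, 2), (8, 32, 32, 3)]


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20160)


@pytest.fixture(scope="session")
def blobs_volume():
    """Smooth, inter-slice-correlated default-geometry fixture."""
    return generate(FixtureSpec(shape=(8, 128, 128), model="blobs", seed=7))


@pytest.fixture(scope="session")
def noise_volume():
    """Correlated-noise fixture at the default study geometry."""
    return generate(FixtureSpec(shape=(8, 128, 128),
                                model="correlated-noise", seed=11))


@pytest.fixture(scope="session")
def small_volume():
    return generate(FixtureSpec(shape=(8, 32, 32), model="blobs", seed=3))


def random_linear(geometry, rng, lo=-255, hi=255):
    """A random integer coefficient array on the given codec geometry."""
    S, R, C, L = geometry
    lay = build_layout(S, R, C, L)
    xi = rng.integers(lo, hi + 1, lay.total_len).astype(np.int64)
    return LinearCoefficientArray(xi=xi, layout=lay)
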