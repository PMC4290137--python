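import numpy as np
import pytest

from vesselseg import BallSeed, PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def small_phantom():
    """A small default-tree phantom with ground truth, shared across tests."""
    spec = PhantomSpec.default((40, 32, 40), rng_seed=0)
    return generate_phantom(spec)


@pytest.fixture(scope="session")
def trunk_seed():
    """A ball seed strictly inside the trunk of a default tree."""

    def _make(spec):
        trunk = spec.centerline_tree[0]
        i = len(trunk.points) // 5
        return BallSeed(tuple(trunk.points[i]), max(float(trunk.radii[i]) - 1.0, 1.5))

    return _make


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
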