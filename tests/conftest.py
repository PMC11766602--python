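import numpy as np
import pytest

from ipcc_ar.preprocessing import skeletonize
from ipcc_ar.synthetic import VesselTreeParams, generate_vessel_tree, random_fixture


@pytest.fixture(scope="session")
def vessel_tree():
    """One deterministic 256x256 vessel mask."""
    return generate_vessel_tree(VesselTreeParams(seed=7))


@pytest.fixture(scope="session")
def vessel_skeleton(vessel_tree):
    return skeletonize(vessel_tree)


@pytest.fixture(scope="session")
def small_fixture_pairs():
    """A handful of skeletonized fixture pairs for registration tests."""
    pairs = []
    for seed in range(6):
        fx = random_fixture(seed)
        pairs.append(
            (skeletonize(fx.fixed), skeletonize(fx.moving), fx.truth)
        )
    return pairs


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
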