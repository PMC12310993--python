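import numpy as np
import pytest

from perfterra import PerfusionModel
from perfterra.synthetic import PhantomSpec, make_phantom


@pytest.fixture(scope="session")
def cow():
    """Default toy circle-of-Willis phantom (network, mesh)."""
    return make_phantom(PhantomSpec())


@pytest.fixture(scope="session")
def cow_results(cow):
    net, mesh = cow
    return PerfusionModel(net, mesh).fit()


@pytest.fixture(scope="session")
def cow_murray_results(cow):
    net, mesh = cow
    return PerfusionModel(net, mesh, boundary_model="murray").fit()


@pytest.fixture(scope="session")
def small_phantom():
    """Small convex box phantom + binary-tree network for cheap tests."""
    return make_phantom(PhantomSpec(template="binary_tree", tree_depth=3))


def mirror_pairs():
    return [("LMCA", "RMCA"), ("LACA", "RACA"), ("LPCA", "RPCA")]


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)
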