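import numpy as np
import pytest

from dendroclust.morphology import Dendrite, pairwise_distance, proximity_matrix
from dendroclust.params import nominal_params


@pytest.fixture(scope="session")
def params():
    return nominal_params()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_branch():
    """Five synapses on a periodic 150-um branch with their proximity matrix."""
    dend = Dendrite(mode="linear", length=150.0, periodic=True)
    positions = np.array([10.0, 14.0, 30.0, 75.0, 140.0])
    p = nominal_params()
    s = proximity_matrix(pairwise_distance(dend, positions), p.sigma_c)
    return dend, positions, s


@pytest.fixture(scope="session")
def y_tree_swc():
    """A 50-um trunk with two 50-um children (hand geometry fixture)."""
    return "\n".join([
        "# Y-shaped test tree",
        "1 1 0 0 0 1.0 -1",
        "2 3 0 50 0 0.5 1",
        "3 3 -35.3553 85.3553 0 0.5 2",
        "4 3 35.3553 85.3553 0 0.5 2",
    ]) + "\n"
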