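import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracle helpers

from dyadnet import BipartiteNetwork, DirectedNetwork, ModelParameters


@pytest.fixture
def tiny_bipartite():
    """2 actors × 2 events with one edge."""
    return BipartiteNetwork(["a0", "a1"], ["e0", "e1"], [(0, 0)])


@pytest.fixture
def small_digraph():
    """4-node digraph with one mutual pair and a 2-path."""
    return DirectedNetwork(["n0", "n1", "n2", "n3"],
                           [(0, 1), (1, 0), (1, 2), (2, 3)])


@pytest.fixture
def random_bipartite_params():
    """5 × 4 network with valid random parameters (seeded)."""
    rng = np.random.default_rng(42)
    params = ModelParameters(
        activities=rng.uniform(0.1, 1.0, 5),
        popularities=rng.uniform(0.1, 1.0, 4),
        actor_classes=rng.integers(0, 2, 5),
        event_classes=rng.integers(0, 2, 4),
        preference=rng.uniform(0.05, 0.95, (2, 2)),
    )
    x = (rng.random((5, 4)) < 0.4).astype(int)
    return BipartiteNetwork.from_adjacency(x), params
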