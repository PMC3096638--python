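import networkx as nx
import numpy as np
import pytest

# A 3-regular graph on six vertices whose BFS replay reproduces a fully
# worked two-queue traversal with hand-computed coordinates (asserted in
# test_bfsmap.TestReplayedTraversal).
FIG_EDGES = [(0, 3), (0, 4), (0, 5), (1, 2), (1, 4), (1, 5),
             (2, 3), (2, 4), (3, 5)]

# Neighbor processing order per explored vertex for the replay (root 2).
FIG_ORDER = {
    2: [1, 3, 4],
    1: [2, 4, 5],
    3: [2, 5, 0],
    4: [2, 1, 0],
    5: [1, 3, 0],
    0: [3, 4, 5],
}


@pytest.fixture
def fig_graph():
    g = nx.Graph(FIG_EDGES)
    assert all(d == 3 for _, d in g.degree())
    return g


@pytest.fixture
def fig_order():
    return lambda v, nbrs: FIG_ORDER[v]


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
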