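import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", deadline=None, max_examples=25, derandomize=True)
settings.load_profile("ci")


def graph_from_edges(n_nodes, edges):
    a = np.zeros((n_nodes, n_nodes), dtype=int)
    for u, v in edges:
        a[u, v] = a[v, u] = 1
    return a


@pytest.fixture
def two_triangles():
    """Two disjoint 3-cliques: the canonical perfectly 2-modular graph."""
    return graph_from_edges(6, [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)])


@pytest.fixture
def barbell():
    """Two triangles joined by a single bridge edge (7 edges, 6 nodes)."""
    return graph_from_edges(
        6, [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5), (2, 3)]
    )
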