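import numpy as np
import pytest

from biproj import synth
from biproj.graph_core import BipartiteGraph


@pytest.fixture
def worked_example():
    """Two objects (degrees 3 and 2) sharing one degree-2 attribute; W = 5."""
    return synth.worked_example()


def random_connected_graph(rng, max_n=12, max_m=12):
    """Small random connected bipartite graph for property tests."""
    while True:
        n = int(rng.integers(2, max_n + 1))
        m = int(rng.integers(2, max_m + 1))
        mask = rng.random((n, m)) < rng.uniform(0.2, 0.7)
        if not mask.any():
            continue
        weighted = rng.random() < 0.5
        edges = []
        for i, b in zip(*np.nonzero(mask)):
            w = float(rng.uniform(0.5, 3.0)) if weighted else 1.0
            edges.append((f"o{i}", f"a{b}", w))
        g = BipartiteGraph.from_edges(edges)
        if g.is_connected() and g.n_objects >= 2:
            return g
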