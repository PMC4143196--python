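"""Sparse network maps from similarity matrices.

A full similarity matrix is a clique and useless as a map.  Following the
maximum-spanning-tree backbone idea, a map keeps (1) the maximum spanning
tree of the positive-similarity graph — guaranteeing connectivity while
retaining the strongest links — and (2) the next-strongest remaining
pairs, added in descending similarity order until the average degree
``2E/N`` reaches a target (3 by default, a typical sparsity for readable
maps).  Two structural diagnostics mirror what one checks on real
networks: the shortest-path-length histogram (small-world behaviour) and
the complementary cumulative degree distribution (hub structure).
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass

import networkx as nx
import numpy as np
from networkx.utils import UnionFind

from .bpr import SimilarityMatrix
from .graph_core import DisconnectedGraphError

logger = logging.getLogger(__name__)

__all__ = [
    "NetworkMap",
    "build_map",
    "shortest_path_distribution",
    "cumulative_degree_distribution",
]


@dataclass
class NetworkMap:
    """Sparse unipartite map: nodes, weighted edges, degree bookkeeping."""

    nodes: tuple[str, ...]
    edges: dict[tuple[str, str], float]
    mst_edges: frozenset[tuple[str, str]]
    target_avg_degree: float

    @property
    def achieved_avg_degree(self) -> float:
        return 2.0 * len(self.edges) / len(self.nodes)

    def to_networkx(self) -> nx.Graph:
        G = nx.Graph()
        G.add_nodes_from(self.nodes)
        for (a, b), w in self.edges.items():
            G.add_edge(a, b, weight=w)
        return G


def _sorted_positive_pairs(
    sim: SimilarityMatrix,
) -> list[tuple[float, str, str]]:
    """Positive off-diagonal pairs, descending weight then lexicographic."""
    sym = sim.symmetrized()
    labels = sym.object_order
    n = len(labels)
    iu, ju = np.triu_indices(n, k=1)
    out = []
    for i, j in zip(iu, ju):
        w = float(sym.values[i, j])
        if w > 0:
            a, b = sorted((labels[i], labels[j]))
            out.append((w, a, b))
    out.sort(key=lambda t: (-t[0], t[1], t[2]))
    return out


def build_map(
    sim: SimilarityMatrix, target_avg_degree: float = 3.0
) -> NetworkMap:
    """Maximum spanning tree plus strongest extra edges up to a degree target.

    Kruskal over descending similarity (ties resolved by lexicographic
    pair order, so the result is deterministic); only strictly positive
    similarities are candidates — a negative Pearson score is evidence
    *against* a link.  After the tree, remaining candidate pairs are
    appended in the same order until ``2E/N >= target_avg_degree``; the
    last addition may overshoot by ``2/N``.  If candidates run out first
    a warning is logged and the map is returned as-is.
    """
    labels = sim.object_order
    n = len(labels)
    ranked = _sorted_positive_pairs(sim)

    uf = UnionFind(labels)
    mst: dict[tuple[str, str], float] = {}
    rest: list[tuple[float, str, str]] = []
    for w, a, b in ranked:
        if uf[a] != uf[b]:
            uf.union(a, b)
            mst[(a, b)] = w
        else:
            rest.append((w, a, b))
    roots = {uf[x] for x in labels}
    if len(roots) > 1:
        comps: dict[str, list[str]] = {}
        for x in labels:
            comps.setdefault(uf[x], []).append(x)
        detail = "; ".join(
            ",".join(sorted(v)[:5]) for v in list(comps.values())[:4]
        )
        raise DisconnectedGraphError(
            f"positive-similarity graph has {len(roots)} components "
            f"({detail}); cannot span a connected map"
        )

    edges = dict(mst)
    for w, a, b in rest:
        if 2.0 * len(edges) / n >= target_avg_degree:
            break
        edges[(a, b)] = w
    if 2.0 * len(edges) / n < target_avg_degree:
        logger.warning(
            "ran out of positive-similarity pairs at average degree %.3f "
            "(target %.3f)",
            2.0 * len(edges) / n,
            target_avg_degree,
        )
    return NetworkMap(
        nodes=tuple(labels),
        edges=edges,
        mst_edges=frozenset(mst),
        target_avg_degree=float(target_avg_degree),
    )


def shortest_path_distribution(net: NetworkMap) -> dict[int, int]:
    """Histogram of unweighted shortest-path lengths over all node pairs."""
    G = net.to_networkx()
    if not nx.is_connected(G):
        raise DisconnectedGraphError("map is disconnected")
    hist: Counter[int] = Counter()
    for _, dists in nx.all_pairs_shortest_path_length(G):
        for d in dists.values():
            if d >= 1:
                hist[d] += 1
    return {length: count // 2 for length, count in sorted(hist.items())}


def cumulative_degree_distribution(net: NetworkMap) -> dict[int, float]:
    """Complementary cumulative distribution ``P(degree >= k)``."""
    if not net.nodes:
        raise ValueError("empty map")
    G = net.to_networkx()
    degrees = np.array([d for _, d in G.degree()])
    kmax = int(degrees.max()) if degrees.size else 0
    return {
        k: float(np.mean(degrees >= k)) for k in range(1, kmax + 1)
    }
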