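"""Bipartite graph data model, edge-list I/O, and validation.

A bipartite graph connects *objects* (class ``I``, size ``n``) to
*attributes* (class ``B``, size ``m``) through positively weighted edges.
All projection measures in this package operate on this container; it is
deliberately format-agnostic — node labels are opaque strings and the only
on-disk representation is a 2- or 3-column TSV edge list.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable, Iterator, Sequence

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components

if TYPE_CHECKING:  # pragma: no cover
    from .bpr import SimilarityMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "BipartiteGraph",
    "GraphValidationError",
    "ParseError",
    "ClassCollisionError",
    "DuplicateEdgeError",
    "DisconnectedGraphError",
    "read_bipartite_edgelist",
    "write_bipartite_edgelist",
    "largest_connected_component",
    "strengths",
    "write_similarity_edgelist",
]


class GraphValidationError(ValueError):
    """Input violates the bipartite-graph contract."""


class ParseError(GraphValidationError):
    """An edge-list row could not be parsed."""


class ClassCollisionError(GraphValidationError):
    """A label appears both as an object and as an attribute."""


class DuplicateEdgeError(GraphValidationError):
    """The same (object, attribute) pair occurs more than once."""


class DisconnectedGraphError(GraphValidationError):
    """An operation requiring a connected graph received a disconnected one."""


@dataclass(frozen=True)
class BipartiteGraph:
    """Immutable weighted bipartite graph.

    Parameters
    ----------
    object_ids
        Ordered unique object labels (class ``I``), insertion order preserved.
    attribute_ids
        Ordered unique attribute labels (class ``B``).
    adjacency
        ``n x m`` CSR matrix ``A``; ``A[i, b]`` is the strictly positive
        weight of edge ``(object i, attribute b)`` (1.0 for binary graphs).
    """

    object_ids: tuple[str, ...]
    attribute_ids: tuple[str, ...]
    adjacency: sp.csr_matrix = field(repr=False)

    def __post_init__(self) -> None:
        n, m = len(self.object_ids), len(self.attribute_ids)
        if self.adjacency.shape != (n, m):
            raise GraphValidationError(
                f"adjacency shape {self.adjacency.shape} != ({n}, {m})"
            )
        collisions = set(self.object_ids) & set(self.attribute_ids)
        if collisions:
            raise ClassCollisionError(
                f"labels in both classes: {sorted(collisions)[:5]}"
            )
        if len(set(self.object_ids)) != n or len(set(self.attribute_ids)) != m:
            raise GraphValidationError("duplicate labels within a class")
        if self.adjacency.nnz and self.adjacency.data.min() <= 0:
            raise GraphValidationError("all edge weights must be > 0")
        if n and m:
            obj_s = np.asarray(self.adjacency.sum(axis=1)).ravel()
            att_s = np.asarray(self.adjacency.sum(axis=0)).ravel()
            if (obj_s <= 0).any() or (att_s <= 0).any():
                raise GraphValidationError("isolated nodes are not allowed")

    # -- constructors ------------------------------------------------------

    @classmethod
    def from_edges(
        cls, edges: Iterable[tuple[str, str, float]]
    ) -> "BipartiteGraph":
        """Build a graph from ``(object, attribute, weight)`` triples.

        Node order follows first appearance; duplicate pairs raise
        :class:`DuplicateEdgeError` (summing silently would hide data bugs).
        """
        obj_index: dict[str, int] = {}
        att_index: dict[str, int] = {}
        rows, cols, data = [], [], []
        seen: set[tuple[str, str]] = set()
        for obj, att, w in edges:
            if (obj, att) in seen:
                raise DuplicateEdgeError(f"duplicate edge ({obj!r}, {att!r})")
            seen.add((obj, att))
            if w <= 0:
                raise GraphValidationError(
                    f"edge ({obj!r}, {att!r}) has non-positive weight {w}"
                )
            rows.append(obj_index.setdefault(obj, len(obj_index)))
            cols.append(att_index.setdefault(att, len(att_index)))
            data.append(float(w))
        n, m = len(obj_index), len(att_index)
        A = sp.csr_matrix(
            (data, (rows, cols)), shape=(n, m), dtype=np.float64
        )
        return cls(tuple(obj_index), tuple(att_index), A)

    # -- basic accessors ---------------------------------------------------

    @property
    def n_objects(self) -> int:
        return len(self.object_ids)

    @property
    def n_attributes(self) -> int:
        return len(self.attribute_ids)

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.nnz)

    @property
    def total_weight(self) -> float:
        """Total edge weight ``W``."""
        return float(self.adjacency.sum())

    def edges(self) -> Iterator[tuple[str, str, float]]:
        """Iterate ``(object, attribute, weight)`` in row-major order."""
        coo = self.adjacency.tocoo()
        for i, b, w in zip(coo.row, coo.col, coo.data):
            yield self.object_ids[i], self.attribute_ids[b], float(w)

    def object_strengths(self) -> np.ndarray:
        """Strength ``s_i`` of each object (degree ``k_i`` for binary graphs)."""
        return np.asarray(self.adjacency.sum(axis=1)).ravel()

    def attribute_strengths(self) -> np.ndarray:
        return np.asarray(self.adjacency.sum(axis=0)).ravel()

    def is_connected(self) -> bool:
        if self.n_objects == 0:
            return False
        return self._components()[0] == 1

    def _components(self) -> tuple[int, np.ndarray]:
        """Connected components of the combined (n+m)-node graph.

        Returns the component count and a label array over objects then
        attributes.
        """
        n, m = self.n_objects, self.n_attributes
        block = sp.bmat(
            [[None, self.adjacency], [self.adjacency.T, None]], format="csr"
        )
        n_comp, labels = connected_components(block, directed=False)
        assert labels.shape == (n + m,)
        return n_comp, labels


# -- file I/O --------------------------------------------------------------


def read_bipartite_edgelist(
    path, weighted: bool = False, delimiter: str = "\t"
) -> BipartiteGraph:
    """Read a bipartite edge list from a 2- or 3-column TSV file.

    Lines starting with ``#`` and blank lines are ignored.  Without
    ``weighted`` every edge gets weight 1.0; with it, a third column of
    strictly positive weights is required.
    """
    expected = 3 if weighted else 2
    edges: list[tuple[str, str, float]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split(delimiter)
            if len(fields) != expected:
                raise ParseError(
                    f"{path}:{lineno}: expected {expected} fields, "
                    f"got {len(fields)}"
                )
            if weighted:
                try:
                    w = float(fields[2])
                except ValueError as exc:
                    raise ParseError(
                        f"{path}:{lineno}: weight {fields[2]!r} is not a number"
                    ) from exc
                if w <= 0:
                    raise GraphValidationError(
                        f"{path}:{lineno}: weight must be > 0, got {w}"
                    )
            else:
                w = 1.0
            edges.append((fields[0], fields[1], w))
    return BipartiteGraph.from_edges(edges)


def write_bipartite_edgelist(
    g: BipartiteGraph, path, weighted: bool = False, delimiter: str = "\t"
) -> None:
    """Write the graph back to TSV (inverse of :func:`read_bipartite_edgelist`)."""
    with open(path, "w") as fh:
        for obj, att, w in g.edges():
            if weighted:
                fh.write(f"{obj}{delimiter}{att}{delimiter}{w:.17g}\n")
            else:
                fh.write(f"{obj}{delimiter}{att}\n")


def largest_connected_component(g: BipartiteGraph) -> BipartiteGraph:
    """Induced subgraph on the largest connected component.

    Size ties are broken in favour of the component containing the
    lexicographically smallest object label, so the reduction is
    deterministic.  The number of dropped nodes is logged.
    """
    if g.n_objects == 0 or g.n_attributes == 0:
        raise GraphValidationError("cannot take a component of an empty graph")
    n_comp, labels = g._components()
    if n_comp == 1:
        return g
    n = g.n_objects
    sizes = np.bincount(labels, minlength=n_comp)
    best = sizes.max()
    candidates = set(np.flatnonzero(sizes == best))
    if len(candidates) == 1:
        keep = candidates.pop()
    else:
        keep = min(
            candidates,
            key=lambda c: min(
                g.object_ids[i] for i in range(n) if labels[i] == c
            ),
        )
    obj_keep = [i for i in range(n) if labels[i] == keep]
    att_keep = [b for b in range(g.n_attributes) if labels[n + b] == keep]
    dropped = (g.n_objects - len(obj_keep)) + (g.n_attributes - len(att_keep))
    logger.warning(
        "graph has %d components; keeping largest, dropping %d node(s)",
        n_comp,
        dropped,
    )
    A = g.adjacency[obj_keep, :][:, att_keep].tocsr()
    return BipartiteGraph(
        tuple(g.object_ids[i] for i in obj_keep),
        tuple(g.attribute_ids[b] for b in att_keep),
        A,
    )


def strengths(g: BipartiteGraph, side: str) -> dict[str, float]:
    """Node strengths ``s_x`` (weighted degrees) on one side of the graph."""
    if side == "object":
        return dict(zip(g.object_ids, g.object_strengths().tolist()))
    if side == "attribute":
        return dict(zip(g.attribute_ids, g.attribute_strengths().tolist()))
    raise ValueError(f"side must be 'object' or 'attribute', got {side!r}")


def write_similarity_edgelist(
    s: "SimilarityMatrix",
    path,
    top_k: int | None = None,
    delimiter: str = "\t",
) -> None:
    """Write a similarity matrix as a 3-column TSV edge list.

    Symmetric methods emit each unordered pair once (``i < j`` in label
    order); asymmetric methods emit both directions.  Rows are sorted by
    descending score, then lexicographic pair, so output is deterministic.
    With ``top_k``, only each source node's ``k`` highest-scoring partners
    are kept (union over sources, so a row may survive via either endpoint
    for symmetric methods).
    """
    labels = s.object_order
    V = s.values
    n = len(labels)
    pairs: list[tuple[str, str, float]] = []
    if s.symmetric:
        idx_i, idx_j = np.triu_indices(n, k=1)
        order = np.argsort([labels[i] for i in range(n)])
        rank = np.empty(n, dtype=int)
        rank[order] = np.arange(n)
        for i, j in zip(idx_i, idx_j):
            a, b = (i, j) if rank[i] < rank[j] else (j, i)
            pairs.append((labels[a], labels[b], float(V[a, b])))
    else:
        for i in range(n):
            for j in range(n):
                if i != j:
                    pairs.append((labels[i], labels[j], float(V[i, j])))
    if top_k is not None:
        keep: set[tuple[str, str]] = set()
        for i in range(n):
            scores = [
                (float(V[i, j]), labels[j])
                for j in range(n)
                if j != i
            ]
            scores.sort(key=lambda t: (-t[0], t[1]))
            for _, other in scores[:top_k]:
                keep.add((labels[i], other))
        if s.symmetric:
            pairs = [
                p for p in pairs
                if (p[0], p[1]) in keep or (p[1], p[0]) in keep
            ]
        else:
            pairs = [p for p in pairs if (p[0], p[1]) in keep]
    pairs.sort(key=lambda p: (-p[2], p[0], p[1]))
    with open(path, "w") as fh:
        for a, b, w in pairs:
            fh.write(f"{a}{delimiter}{b}{delimiter}{w:.12g}\n")
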