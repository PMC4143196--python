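"""Random-walk bipartite projection (BPR).

The similarity between two objects ``i`` and ``j`` is the long-run
frequency with which a random walker on the bipartite graph visits ``i``
and ``j`` consecutively through a single shared attribute ``b``:

    S_ij = v*_i * sum_b P(i -> b) P(b -> j)

where ``P`` are the one-step transition probabilities of the walk
(``P(x -> y) = A_xy / s_x``) and ``v*`` is the stationary distribution of
the chain.  For a connected undirected graph the stationary mass of a node
is proportional to its strength, ``v*_x = s_x / (2W)`` with ``W`` the
total edge weight, which gives the equivalent closed form

    S_ij = sum_b A_ib A_jb / (2 W s_b).

The walk factor ``v*_i`` is what distinguishes BPR from pure
resource-allocation measures (ProbS/HeatS): it injects global structural
information — how often the walker is at ``i`` at all — and damps the
contribution of attribute hubs, whose probability of routing the walker
between the same pair of objects twice is small.

A note on periodicity: a simple walk on a connected bipartite graph has
period 2, so the *sequence* ``v_t`` oscillates between the two classes and
does not converge pointwise.  The fixed point ``v = v M`` nevertheless
exists and is unique for any irreducible chain, and equals the
strength-proportional measure above.  Power iteration therefore runs on
the lazy chain ``(I + M) / 2``, which is aperiodic and shares the same
fixed point.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .graph_core import BipartiteGraph, DisconnectedGraphError

__all__ = [
    "WalkModel",
    "SimilarityMatrix",
    "ConvergenceError",
    "transition_matrix",
    "stationary_distribution",
    "bpr_similarity",
    "monte_carlo_similarity",
]

#: above this many states the transition matrix stays sparse
DENSE_STATE_LIMIT = 2000

DEFAULT_TOL = 1e-12
DEFAULT_MAX_ITER = 100_000


class ConvergenceError(RuntimeError):
    """Stationary-distribution iteration failed to reach tolerance."""


@dataclass(frozen=True)
class WalkModel:
    """Markov chain of the random walk on a bipartite graph.

    States are ordered objects-first then attributes (length ``n + m``).
    ``M`` is the right-stochastic transition matrix; ``strengths`` holds
    the node strengths used to build it; ``v_star`` is filled in by
    :func:`stationary_distribution`.
    """

    state_order: tuple[str, ...]
    n_objects: int
    M: sp.csr_matrix = field(repr=False)
    strengths: np.ndarray = field(repr=False)
    total_weight: float
    v_star: np.ndarray | None = field(default=None, repr=False)
    tol: float = DEFAULT_TOL


@dataclass(frozen=True)
class SimilarityMatrix:
    """Object-by-object projection scores with method metadata.

    The diagonal is stored (it is needed for conservation checks) but all
    ranking, prediction, and map operations exclude it.
    """

    object_order: tuple[str, ...]
    values: np.ndarray = field(repr=False)
    method: str = "BPR"
    symmetric: bool = True
    params: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.object_order)
        if self.values.shape != (n, n):
            raise ValueError(
                f"values shape {self.values.shape} != ({n}, {n})"
            )

    def index(self, label: str) -> int:
        try:
            return self.object_order.index(label)
        except ValueError as exc:
            raise KeyError(f"unknown object {label!r}") from exc

    def pair(self, a: str, b: str) -> float:
        return float(self.values[self.index(a), self.index(b)])

    def symmetrized(self) -> "SimilarityMatrix":
        """Mean of the two directed entries; identity for symmetric methods."""
        if self.symmetric:
            return self
        return replace(
            self,
            values=(self.values + self.values.T) / 2.0,
            symmetric=True,
        )


def _require_connected(g: BipartiteGraph) -> None:
    if not g.is_connected():
        raise DisconnectedGraphError(
            "graph is disconnected, so the walk is not irreducible; "
            "reduce to the largest component first "
            "(graph_core.largest_connected_component)"
        )


def transition_matrix(g: BipartiteGraph) -> WalkModel:
    """One-step transition matrix of the random walk on ``g``.

    ``P(x -> y) = A_xy / s_x`` for neighbouring ``x, y`` in opposite
    classes, 0 otherwise; every row sums to 1.
    """
    _require_connected(g)
    s_obj = g.object_strengths()
    s_att = g.attribute_strengths()
    P_ib = sp.diags(1.0 / s_obj) @ g.adjacency  # n x m
    P_bi = sp.diags(1.0 / s_att) @ g.adjacency.T  # m x n
    M = sp.bmat([[None, P_ib], [P_bi, None]], format="csr")
    return WalkModel(
        state_order=g.object_ids + g.attribute_ids,
        n_objects=g.n_objects,
        M=M,
        strengths=np.concatenate([s_obj, s_att]),
        total_weight=g.total_weight,
    )


def stationary_distribution(
    model: WalkModel,
    method: str = "closed_form",
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> WalkModel:
    """Solve ``v = v M`` with ``sum(v) = 1`` and attach ``v_star``.

    Methods
    -------
    ``closed_form``
        ``v*_x = s_x / (2W)`` — exact for the walk on a connected
        undirected graph.
    ``power_iteration``
        Iterates the lazy chain ``v <- v (I + M) / 2`` from the uniform
        vector; the lazy chain is aperiodic so the iteration converges to
        the common fixed point.
    ``eigenvector``
        Leading left eigenvector of ``M`` (eigenvalue 1), via dense or
        sparse eigensolver depending on problem size.
    """
    N = len(model.state_order)
    if method == "closed_form":
        v = model.strengths / (2.0 * model.total_weight)
    elif method == "power_iteration":
        v = np.full(N, 1.0 / N)
        M = model.M
        for _ in range(max_iter):
            v_next = 0.5 * v + 0.5 * (v @ M)
            if np.abs(v_next - v).max() < tol:
                v = v_next
                break
            v = v_next
        else:
            residual = float(np.abs(v @ M - v).max())
            raise ConvergenceError(
                f"no convergence in {max_iter} iterations "
                f"(residual {residual:.3e} > tol {tol:.3e})"
            )
        v = v / v.sum()
    elif method == "eigenvector":
        if N <= DENSE_STATE_LIMIT:
            w, vl = np.linalg.eig(model.M.toarray().T)
            k = int(np.argmin(np.abs(w - 1.0)))
            v = np.real(vl[:, k])
        else:
            w, vl = spla.eigs(model.M.T.tocsc(), k=1, sigma=1.0)
            v = np.real(vl[:, 0])
        v = np.abs(v)
        v = v / v.sum()
    else:
        raise ValueError(
            "method must be one of "
            "{'closed_form', 'power_iteration', 'eigenvector'}, "
            f"got {method!r}"
        )
    return replace(model, v_star=v, tol=tol)


def bpr_similarity(
    g: BipartiteGraph, tol: float = DEFAULT_TOL
) -> SimilarityMatrix:
    """Random-walk projection similarity for every object pair.

    Computes ``S_ij = v*_i sum_b P(i->b) P(b->j)`` from the walk model and
    asserts agreement (within ``tol`` scaled by the matrix magnitude) with
    the closed form ``sum_b A_ib A_jb / (2 W s_b)``.  The matrix is
    symmetric because the walk is reversible.
    """
    model = stationary_distribution(transition_matrix(g), "closed_form")
    n = g.n_objects
    v_obj = model.v_star[:n]
    P_ib = model.M[:n, n:]
    P_bi = model.M[n:, :n]
    S = np.asarray((sp.diags(v_obj) @ P_ib @ P_bi).todense())

    # closed-form cross-check, derived independently of the walk model
    s_att = g.attribute_strengths()
    W = g.total_weight
    S_closed = np.asarray(
        ((g.adjacency @ sp.diags(1.0 / s_att)) @ g.adjacency.T).todense()
    ) / (2.0 * W)
    scale = max(S_closed.max(), 1.0)
    if np.abs(S - S_closed).max() > tol * scale * 100:
        raise AssertionError(
            "walk-based and closed-form BPR disagree beyond tolerance"
        )

    S = (S + S.T) / 2.0  # remove numerical asymmetry
    return SimilarityMatrix(
        object_order=g.object_ids,
        values=S,
        method="BPR",
        symmetric=True,
        params={"tol": tol},
    )


def monte_carlo_similarity(
    g: BipartiteGraph, steps: int, seed: int
) -> SimilarityMatrix:
    """Monte-Carlo estimate of BPR from one long simulated walk.

    Runs a single walk of ``steps`` transitions from a uniformly random
    start and counts, for every ordered object pair ``(i, j)``, the
    windows in which the walker moves ``i -> b -> j``.  The long-run
    frequency of such a window per transition is exactly ``S_ij``, so

        S_hat_ij = (C_ij + C_ji) / (2 * steps)

    is a consistent, symmetric estimator of ``bpr_similarity`` (the
    diagonal window ``i -> b -> i`` is counted on both "orders", matching
    the factor the off-diagonal pairs get from symmetrization).
    """
    _require_connected(g)
    n, m = g.n_objects, g.n_attributes
    if steps < 10 * (n + m):
        raise ValueError(
            f"steps={steps} too small; need at least 10*(n+m) = {10 * (n + m)}"
        )
    rng = np.random.default_rng(seed)
    model = transition_matrix(g)
    M = model.M.tocsr()
    N = n + m
    # per-state neighbour lists and cumulative transition probabilities
    neighbors = [M.indices[M.indptr[x]:M.indptr[x + 1]] for x in range(N)]
    cumprobs = [
        np.cumsum(M.data[M.indptr[x]:M.indptr[x + 1]]) for x in range(N)
    ]
    states = np.empty(steps + 1, dtype=np.int64)
    x = int(rng.integers(N))
    states[0] = x
    draws = rng.random(steps)
    for t in range(steps):
        nbrs = neighbors[x]
        x = int(nbrs[np.searchsorted(cumprobs[x], draws[t])])
        states[t + 1] = x

    starts = states[:-2]  # window start positions 0 .. steps-2
    ends = states[2:]
    mask = starts < n  # windows beginning at an object are I -> B -> I
    C = np.zeros((n, n))
    np.add.at(C, (starts[mask], ends[mask]), 1.0)
    S_hat = (C + C.T) / (2.0 * steps)
    return SimilarityMatrix(
        object_order=g.object_ids,
        values=S_hat,
        method="BPR-MC",
        symmetric=True,
        params={"steps": steps, "seed": seed},
    )
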