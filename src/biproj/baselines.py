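"""Comparator one-mode projection measures.

Seven standard measures against which the random-walk projection is
benchmarked.  Three are resource-allocation recommenders (ProbS, HeatS and
their Hybrid interpolation) and four treat object rows of the adjacency
matrix as vectors or sets (Jaccard, Cosine, Euclidean, Pearson).

Conventions
-----------
* ProbS: ``W(i, j) = (1 / s_j) * sum_b A_ib A_jb / s_b`` — normalized by
  the *target* object's strength, so each column of a binary graph's
  ProbS matrix sums to 1 (the unit of resource placed on ``j`` is fully
  redistributed).
* HeatS is exactly the transpose of ProbS (normalized by the row).
* Hybrid replaces the leading normalizer with the geometric mean
  ``s_i^{1-lambda} s_j^{lambda}``; ``lambda = 1`` recovers ProbS and
  ``lambda = 0`` recovers HeatS.
* Euclidean similarity uses ``1 / (1 + d)``: bounded in (0, 1], equal to
  1 for identical attribute vectors, strictly decreasing in the distance.
* Pearson with a zero-variance attribute vector (an object linked to
  every attribute with equal weight) is set to 0 with a logged warning so
  batch projection never aborts.
* Jaccard always works on attribute *support sets*; the other measures
  use raw weights (1.0 everywhere for binary graphs).
"""

from __future__ import annotations

import logging

import numpy as np
import scipy.sparse as sp

from . import bpr as _bpr
from .graph_core import BipartiteGraph

logger = logging.getLogger(__name__)

__all__ = [
    "probs_similarity",
    "heats_similarity",
    "hybrid_similarity",
    "jaccard_similarity",
    "cosine_similarity",
    "euclidean_similarity",
    "pearson_similarity",
    "METHODS",
    "compute_similarity",
]


def _two_step(g: BipartiteGraph) -> np.ndarray:
    """``R_ij = sum_b A_ib A_jb / s_b`` — the common two-step-path kernel."""
    s_att = g.attribute_strengths()
    R = np.asarray(
        ((g.adjacency @ sp.diags(1.0 / s_att)) @ g.adjacency.T).todense()
    )
    # R is mathematically symmetric; enforce it bitwise so the
    # HeatS = ProbS^T identity holds exactly
    return (R + R.T) / 2.0


def _dense_rows(g: BipartiteGraph) -> np.ndarray:
    return np.asarray(g.adjacency.todense())


def probs_similarity(g: BipartiteGraph) -> _bpr.SimilarityMatrix:
    """Resource-allocation similarity, target-normalized (asymmetric)."""
    W = _two_step(g) / g.object_strengths()[np.newaxis, :]
    return _bpr.SimilarityMatrix(g.object_ids, W, "ProbS", symmetric=False)


def heats_similarity(g: BipartiteGraph) -> _bpr.SimilarityMatrix:
    """Heat-spreading similarity, source-normalized; transpose of ProbS."""
    W = _two_step(g) / g.object_strengths()[:, np.newaxis]
    return _bpr.SimilarityMatrix(g.object_ids, W, "HeatS", symmetric=False)


def hybrid_similarity(
    g: BipartiteGraph, lam: float = 0.5
) -> _bpr.SimilarityMatrix:
    """Geometric interpolation between HeatS (``lam=0``) and ProbS (``lam=1``)."""
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lambda must be in [0, 1], got {lam}")
    s = g.object_strengths()
    norm = np.outer(s ** (1.0 - lam), s ** lam)
    W = _two_step(g) / norm
    return _bpr.SimilarityMatrix(
        g.object_ids, W, "Hybrid", symmetric=False, params={"lambda": lam}
    )


def jaccard_similarity(g: BipartiteGraph) -> _bpr.SimilarityMatrix:
    """Attribute-set overlap ``|N_i ∩ N_j| / |N_i ∪ N_j|`` (weights ignored)."""
    B = (g.adjacency > 0).astype(np.float64)
    inter = np.asarray((B @ B.T).todense())
    k = np.asarray(B.sum(axis=1)).ravel()
    union = k[:, np.newaxis] + k[np.newaxis, :] - inter
    S = np.divide(inter, union, out=np.zeros_like(inter), where=union > 0)
    return _bpr.SimilarityMatrix(g.object_ids, S, "Jaccard", symmetric=True)


def cosine_similarity(g: BipartiteGraph) -> _bpr.SimilarityMatrix:
    """Cosine of the angle between attribute-weight row vectors."""
    X = _dense_rows(g)
    norms = np.linalg.norm(X, axis=1)
    S = (X @ X.T) / np.outer(norms, norms)
    return _bpr.SimilarityMatrix(g.object_ids, S, "Cosine", symmetric=True)


def euclidean_similarity(g: BipartiteGraph) -> _bpr.SimilarityMatrix:
    """``1 / (1 + d)`` with ``d`` the Euclidean row-vector distance."""
    X = _dense_rows(g)
    sq = np.sum(X * X, axis=1)
    d2 = sq[:, np.newaxis] + sq[np.newaxis, :] - 2.0 * (X @ X.T)
    d = np.sqrt(np.clip(d2, 0.0, None))
    return _bpr.SimilarityMatrix(
        g.object_ids, 1.0 / (1.0 + d), "Euclidean", symmetric=True
    )


def pearson_similarity(g: BipartiteGraph) -> _bpr.SimilarityMatrix:
    """Pearson correlation of attribute-weight row vectors.

    Population variances are used.  Rows with zero variance cannot be
    correlated; their similarities are set to 0 and a warning is logged.
    """
    X = _dense_rows(g)
    Xc = X - X.mean(axis=1, keepdims=True)
    sd = np.sqrt(np.mean(Xc * Xc, axis=1))
    constant = sd == 0
    if constant.any():
        bad = [g.object_ids[i] for i in np.flatnonzero(constant)]
        logger.warning(
            "constant attribute vector(s) %s: Pearson set to 0", bad[:5]
        )
    cov = (Xc @ Xc.T) / X.shape[1]
    denom = np.outer(sd, sd)
    S = np.divide(cov, denom, out=np.zeros_like(cov), where=denom > 0)
    S[constant, :] = 0.0
    S[:, constant] = 0.0
    np.clip(S, -1.0, 1.0, out=S)
    return _bpr.SimilarityMatrix(g.object_ids, S, "Pearson", symmetric=True)


#: name -> callable; Hybrid additionally accepts ``lam``.
METHODS = {
    "bpr": _bpr.bpr_similarity,
    "probs": probs_similarity,
    "heats": heats_similarity,
    "hybrid": hybrid_similarity,
    "jaccard": jaccard_similarity,
    "cosine": cosine_similarity,
    "euclidean": euclidean_similarity,
    "pearson": pearson_similarity,
}

#: recommendation aggregation the method calls for (resource-allocation
#: scores add up; distance-based scores are averaged)
DEFAULT_AGGREGATION = {
    "bpr": "sum",
    "probs": "sum",
    "heats": "sum",
    "hybrid": "sum",
    "jaccard": "average",
    "cosine": "average",
    "euclidean": "average",
    "pearson": "average",
}


def compute_similarity(
    g: BipartiteGraph, method: str, lam: float = 0.5, **kwargs
) -> _bpr.SimilarityMatrix:
    """Dispatch to one of the eight projection measures by name."""
    key = method.lower()
    if key not in METHODS:
        raise ValueError(
            f"unknown method {method!r}; choose from {sorted(METHODS)}"
        )
    if key == "hybrid":
        return hybrid_similarity(g, lam=lam, **kwargs)
    return METHODS[key](g, **kwargs)
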