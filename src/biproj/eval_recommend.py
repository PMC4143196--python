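"""Object-attribute (I-J) edge prediction protocol.

A random fraction of bipartite edges is held out as a *probe*; similarity
is recomputed on the remaining training graph; and for each attribute-side
consumer (*user* — e.g. a viewer in a user-movie graph, where the movies
are the projected objects) every unlinked object (*item*) is scored by
summing or averaging its similarity to the user's training items.  Two
quality summaries are computed:

* the ranking score ``<r>`` — mean over probe edges of
  ``rank of the held-out item / length of the candidate list``
  (lower is better; 0.5 is a random scorer);
* the hit rate ``HR-L`` — the share of probe edges whose item appears in
  the user's top-``L`` list.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from .bpr import SimilarityMatrix
from .graph_core import BipartiteGraph

logger = logging.getLogger(__name__)

__all__ = [
    "RecommendationEval",
    "probe_split",
    "recommend",
    "evaluate_recommendations",
    "ranking_score",
    "hit_rate",
]


@dataclass
class RecommendationEval:
    """Outcome of the probe-based recommendation protocol.

    ``r_values`` holds one normalized rank per scorable probe edge;
    ``positions`` the corresponding deterministic 1-based list positions
    (lexicographic tie-break) used for hit rates; ``unscorable`` counts
    probe edges whose user or item vanished from the training graph.
    """

    probe: list[tuple[str, str]]
    r_values: np.ndarray
    positions: np.ndarray
    unscorable: int
    hit_rates: dict[int, float] = field(default_factory=dict)

    @property
    def mean_r(self) -> float:
        return float(self.r_values.mean())


def probe_split(
    g: BipartiteGraph, fraction: float, seed: int
) -> tuple[BipartiteGraph, list[tuple[str, str]]]:
    """Hold out a uniformly random fraction of edges.

    Returns the training graph (nodes that lose every edge are dropped)
    and the probe as a list of ``(object, attribute)`` pairs.  The split
    is reproducible given ``seed``.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError(f"fraction must be in (0, 1), got {fraction}")
    edges = list(g.edges())
    n_probe = int(round(fraction * len(edges)))
    if n_probe >= len(edges):
        raise ValueError("fraction would remove every edge")
    rng = np.random.default_rng(seed)
    probe_idx = set(
        rng.choice(len(edges), size=n_probe, replace=False).tolist()
    )
    training_edges = [e for k, e in enumerate(edges) if k not in probe_idx]
    probe = [(edges[k][0], edges[k][1]) for k in sorted(probe_idx)]
    training = BipartiteGraph.from_edges(training_edges)
    dropped = (g.n_objects - training.n_objects) + (
        g.n_attributes - training.n_attributes
    )
    if dropped:
        logger.info("probe split dropped %d node(s) from training", dropped)
    return training, probe


def _user_scores(
    sim: SimilarityMatrix,
    training: BipartiteGraph,
    user: str,
    aggregation: str,
) -> tuple[list[str], np.ndarray]:
    """Scores for every candidate item not linked to ``user`` in training."""
    if aggregation not in ("sum", "average"):
        raise ValueError(
            f"aggregation must be 'sum' or 'average', got {aggregation!r}"
        )
    try:
        u = training.attribute_ids.index(user)
    except ValueError as exc:
        raise KeyError(f"unknown user {user!r}") from exc
    col = np.asarray(training.adjacency[:, u].todense()).ravel()
    liked = np.flatnonzero(col > 0)
    liked_labels = {training.object_ids[i] for i in liked}
    candidates = [o for o in sim.object_order if o not in liked_labels]
    liked_rows = np.array([sim.index(training.object_ids[i]) for i in liked])
    cand_cols = np.array([sim.index(c) for c in candidates])
    block = sim.values[np.ix_(liked_rows, cand_cols)]
    scores = block.mean(axis=0) if aggregation == "average" else block.sum(axis=0)
    return candidates, scores


def recommend(
    sim: SimilarityMatrix,
    training: BipartiteGraph,
    user: str,
    aggregation: str = "sum",
) -> list[tuple[str, float]]:
    """Ranked ``(item, score)`` list of unlinked items for one user.

    Ties are broken lexicographically by item label so the list is
    deterministic.
    """
    candidates, scores = _user_scores(sim, training, user, aggregation)
    order = sorted(
        range(len(candidates)), key=lambda k: (-scores[k], candidates[k])
    )
    return [(candidates[k], float(scores[k])) for k in order]


def evaluate_recommendations(
    sim: SimilarityMatrix,
    training: BipartiteGraph,
    probe: list[tuple[str, str]],
    aggregation: str = "sum",
    hr_lengths: tuple[int, ...] = (10, 20, 50),
) -> RecommendationEval:
    """Score every probe edge against per-user recommendation lists.

    For ``<r>`` the rank of the held-out item uses mean ranks over score
    ties (seed-independent for degenerate scorers); for hit rates the
    deterministic lexicographic list position is used.  Probe edges whose
    user or item is missing from the training graph are skipped and
    counted as unscorable.
    """
    att_set = set(training.attribute_ids)
    obj_set = set(sim.object_order)
    by_user: dict[str, list[str]] = {}
    unscorable = 0
    kept: list[tuple[str, str]] = []
    for item, user in probe:
        if user not in att_set or item not in obj_set:
            unscorable += 1
            continue
        by_user.setdefault(user, []).append(item)
        kept.append((item, user))
    if unscorable:
        logger.info("%d probe edge(s) unscorable (cold-start)", unscorable)

    r_values: list[float] = []
    positions: list[int] = []
    probe_order: list[tuple[str, str]] = []
    for user, items in by_user.items():
        candidates, scores = _user_scores(sim, training, user, aggregation)
        mean_ranks = rankdata(-scores, method="average")
        det_order = sorted(
            range(len(candidates)), key=lambda k: (-scores[k], candidates[k])
        )
        det_pos = {candidates[k]: p + 1 for p, k in enumerate(det_order)}
        idx = {c: k for k, c in enumerate(candidates)}
        for item in items:
            if item not in idx:  # linked in training (excluded universe)
                unscorable += 1
                continue
            r_values.append(mean_ranks[idx[item]] / len(candidates))
            positions.append(det_pos[item])
            probe_order.append((item, user))
    return RecommendationEval(
        probe=probe_order,
        r_values=np.asarray(r_values),
        positions=np.asarray(positions, dtype=int),
        unscorable=unscorable,
    )


def ranking_score(ev: RecommendationEval) -> float:
    """Mean normalized rank ``<r>`` over all scorable probe edges."""
    if ev.r_values.size == 0:
        raise ValueError("no scorable probe edges")
    return ev.mean_r


def hit_rate(ev: RecommendationEval, L: int) -> float:
    """Fraction of probe edges whose item lands in the top-``L`` list."""
    if L < 1:
        raise ValueError(f"L must be >= 1, got {L}")
    if ev.positions.size == 0:
        raise ValueError("no scorable probe edges")
    hr = float(np.mean(ev.positions <= L))
    ev.hit_rates[L] = hr
    return hr
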