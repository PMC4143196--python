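"""Object-object (I-I) edge prediction protocol.

The projection's whole point is to predict relations *between objects*.
Given an observed weighted unipartite graph over the same objects, every
unordered object pair is labelled positive when its observed weight is at
least a threshold ``tau`` (absent pairs have weight 0), similarity scores
rank all pairs globally, and the quality of the ranking is summarized by
the ROC curve and its area (AUC).  An AUC of 0.5 is a random predictor;
1.0 is a perfect one.

AUC is computed by the Mann-Whitney rank statistic with half credit for
ties — identical to integrating the tie-grouped ROC curve, which the
test-suite cross-checks against scikit-learn's trapezoid integration.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.stats import rankdata
from sklearn.metrics import roc_curve

from .bpr import SimilarityMatrix

__all__ = [
    "LinkPredictionEval",
    "read_unipartite_edgelist",
    "label_pairs",
    "mann_whitney_auc",
    "roc_auc",
    "threshold_sweep",
]


@dataclass
class LinkPredictionEval:
    """Labelled pair universe and (optionally) its ROC summary."""

    tau: float
    pairs: list[tuple[str, str]]
    scores: np.ndarray = field(repr=False)
    labels: np.ndarray = field(repr=False)
    roc: np.ndarray | None = field(default=None, repr=False)  # (fpr, tpr) rows
    auc: float | None = None


def read_unipartite_edgelist(path, delimiter: str = "\t") -> dict[frozenset, float]:
    """Read an undirected weighted edge list ``(u, v, weight)``.

    Edges listed in both directions must agree in weight; self-loops are
    rejected.
    """
    observed: dict[frozenset, float] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split(delimiter)
            if len(fields) != 3:
                raise ValueError(
                    f"{path}:{lineno}: expected 3 fields, got {len(fields)}"
                )
            u, v, w = fields[0], fields[1], float(fields[2])
            if u == v:
                raise ValueError(f"{path}:{lineno}: self-loop {u!r}")
            key = frozenset((u, v))
            if key in observed and observed[key] != w:
                raise ValueError(
                    f"{path}:{lineno}: conflicting weights for pair {u!r}-{v!r}"
                )
            observed[key] = w
    return observed


def label_pairs(
    sim: SimilarityMatrix,
    observed: dict[frozenset, float],
    tau: float,
) -> LinkPredictionEval:
    """Label every unordered object pair against the observed graph.

    Positives are pairs whose observed weight is ``>= tau`` (inclusive);
    all other pairs, including those absent from the observed graph, are
    negatives.  Asymmetric similarity matrices are symmetrized by the
    mean of the two directed entries.  The candidate universe is *all*
    pairs, so zero-similarity positives still count (as poorly ranked
    positives) rather than silently disappearing.
    """
    if tau < 0:
        raise ValueError(f"tau must be >= 0, got {tau}")
    known = set(sim.object_order)
    offenders = sorted({x for key in observed for x in key} - known)
    if offenders:
        raise ValueError(
            f"observed nodes missing from similarity matrix: {offenders[:10]}"
        )
    sym = sim.symmetrized()
    labels_order = sym.object_order
    n = len(labels_order)
    iu, ju = np.triu_indices(n, k=1)
    scores = sym.values[iu, ju]
    y = np.zeros(iu.size, dtype=int)
    for k, (i, j) in enumerate(zip(iu, ju)):
        w = observed.get(frozenset((labels_order[i], labels_order[j])), 0.0)
        if w >= tau:
            y[k] = 1
    pairs = [(labels_order[i], labels_order[j]) for i, j in zip(iu, ju)]
    return LinkPredictionEval(
        tau=tau, pairs=pairs, scores=scores, labels=y
    )


def mann_whitney_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC as ``P(score_pos > score_neg) + 0.5 P(tie)`` via mid-ranks."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError(
            "AUC undefined: need at least one positive and one negative"
        )
    ranks = rankdata(scores, method="average")
    rank_sum = float(ranks[labels == 1].sum())
    return (rank_sum - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)


def roc_auc(ev: LinkPredictionEval) -> LinkPredictionEval:
    """Attach the ROC curve and AUC to a labelled evaluation."""
    auc = mann_whitney_auc(ev.scores, ev.labels)
    fpr, tpr, _ = roc_curve(ev.labels, ev.scores)
    return replace(ev, roc=np.column_stack([fpr, tpr]), auc=auc)


def threshold_sweep(
    sim: SimilarityMatrix,
    observed: dict[frozenset, float],
    taus: list[float],
) -> dict[float, float | None]:
    """AUC for each ``tau``; thresholds yielding a single class map to None."""
    if not taus:
        raise ValueError("tau list must not be empty")
    out: dict[float, float | None] = {}
    for tau in taus:
        ev = label_pairs(sim, observed, tau)
        try:
            out[tau] = mann_whitney_auc(ev.scores, ev.labels)
        except ValueError:
            out[tau] = None
    return out
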