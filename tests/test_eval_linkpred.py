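import itertools

import numpy as np
import pytest
from sklearn.metrics import auc as sk_auc
from sklearn.metrics import roc_curve as sk_roc_curve

from biproj import synth
from biproj.baselines import compute_similarity
from biproj.bpr import SimilarityMatrix, bpr_similarity
from biproj.eval_linkpred import (
    label_pairs,
    mann_whitney_auc,
    read_unipartite_edgelist,
    roc_auc,
    threshold_sweep,
)


def sym_sim(order, values):
    V = np.asarray(values, dtype=float)
    return SimilarityMatrix(tuple(order), V, "toy", symmetric=True)


def brute_force_auc(scores, labels):
    """Independent oracle: enumerate every positive/negative comparison."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    total = 0.0
    for p, q in itertools.product(pos, neg):
        total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


class TestLabelPairs:
    def _toy(self):
        order = ["a", "b", "c", "d"]
        V = np.arange(16, dtype=float).reshape(4, 4)
        V = (V + V.T) / 2
        np.fill_diagonal(V, 0)
        sim = sym_sim(order, V)
        observed = {
            frozenset(("a", "b")): 3.0,
            frozenset(("a", "c")): 2.0,
            frozenset(("c", "d")): 0.5,
        }
        return sim, observed

    def test_threshold_selects_heavy_edges(self):
        sim, observed = self._toy()
        ev = label_pairs(sim, observed, tau=2.0)
        labelled = dict(zip(ev.pairs, ev.labels))
        assert labelled[("a", "b")] == 1 and labelled[("a", "c")] == 1
        assert labelled[("c", "d")] == 0 and labelled[("b", "c")] == 0
        assert len(ev.pairs) == 6  # full pair universe

    def test_tau_zero_all_edges_positive(self):
        sim, observed = self._toy()
        ev = label_pairs(sim, observed, tau=0.0)
        assert int(ev.labels.sum()) == 6  # weight >= 0 holds for every pair

    def test_tau_above_max_gives_single_class(self):
        sim, observed = self._toy()
        ev = label_pairs(sim, observed, tau=100.0)
        assert ev.labels.sum() == 0
        with pytest.raises(ValueError):
            roc_auc(ev)

    def test_unknown_observed_node_rejected(self):
        sim, observed = self._toy()
        observed[frozenset(("a", "zzz"))] = 1.0
        with pytest.raises(ValueError, match="zzz"):
            label_pairs(sim, observed, tau=1.0)

    def test_asymmetric_sim_symmetrized_by_mean(self):
        V = np.array([[0, 0.8], [0.2, 0]])
        sim = SimilarityMatrix(("a", "b"), V, "probs", symmetric=False)
        ev = label_pairs(sim, {frozenset(("a", "b")): 1.0}, tau=1.0)
        assert ev.scores[0] == pytest.approx(0.5)


class TestAuc:
    def test_separable_scores_auc_one(self):
        scores = np.array([0.9, 0.8, 0.7, 0.2, 0.1])
        labels = np.array([1, 1, 1, 0, 0])
        assert mann_whitney_auc(scores, labels) == 1.0

    def test_five_pair_toy(self):
        scores = np.array([0.9, 0.8, 0.4, 0.3, 0.1])
        labels = np.array([1, 0, 1, 0, 0])
        assert mann_whitney_auc(scores, labels) == pytest.approx(5 / 6)
        assert brute_force_auc(scores, labels) == pytest.approx(5 / 6)

    def test_matches_brute_force_with_ties(self):
        rng = np.random.default_rng(61)
        for _ in range(20):
            scores = rng.integers(0, 5, size=30).astype(float)  # many ties
            labels = rng.integers(0, 2, size=30)
            if labels.sum() in (0, 30):
                continue
            assert mann_whitney_auc(scores, labels) == pytest.approx(
                brute_force_auc(scores, labels), abs=1e-12
            )

    def test_matches_sklearn_roc_integration(self):
        rng = np.random.default_rng(67)
        scores = rng.random(200)
        labels = (rng.random(200) < 0.3).astype(int)
        fpr, tpr, _ = sk_roc_curve(labels, scores)
        assert mann_whitney_auc(scores, labels) == pytest.approx(
            sk_auc(fpr, tpr), abs=1e-12
        )

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(71)
        scores = rng.random(100)
        labels = (rng.random(100) < 0.4).astype(int)
        base = mann_whitney_auc(scores, labels)
        assert mann_whitney_auc(np.exp(5 * scores), labels) == pytest.approx(base)
        assert mann_whitney_auc(np.log(scores + 1), labels) == pytest.approx(base)

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(73)
        labels = np.array([1] * 50 + [0] * 200)
        aucs = [
            mann_whitney_auc(rng.random(250), labels) for _ in range(100)
        ]
        se = np.std(aucs) / np.sqrt(len(aucs))
        assert abs(np.mean(aucs) - 0.5) < 3 * se + 0.005

    def test_roc_curve_endpoints_and_monotonicity(self):
        rng = np.random.default_rng(79)
        scores = rng.random(50)
        labels = (rng.random(50) < 0.5).astype(int)
        ev = roc_auc(
            label_pairs_from_arrays(scores, labels)
        )
        roc = ev.roc
        assert tuple(roc[0]) == (0.0, 0.0) and tuple(roc[-1]) == (1.0, 1.0)
        assert np.all(np.diff(roc[:, 0]) >= 0)
        assert np.all(np.diff(roc[:, 1]) >= 0)


def label_pairs_from_arrays(scores, labels):
    from biproj.eval_linkpred import LinkPredictionEval

    n = len(scores)
    pairs = [(f"p{k}", f"q{k}") for k in range(n)]
    return LinkPredictionEval(
        tau=1.0, pairs=pairs, scores=np.asarray(scores),
        labels=np.asarray(labels),
    )


class TestThresholdSweep:
    def _setup(self):
        g, truth = synth.planted_blocks(40, 40, 4, 0.5, 0.05, seed=5)
        observed = {frozenset((a, b)): w for a, b, w in truth}
        return g, observed

    def test_single_tau_consistent_with_roc_auc(self):
        g, observed = self._setup()
        sim = bpr_similarity(g)
        ev = roc_auc(label_pairs(sim, observed, 1.0))
        sweep = threshold_sweep(sim, observed, [1.0])
        assert sweep[1.0] == pytest.approx(ev.auc)

    def test_undefined_taus_reported_as_none(self):
        g, observed = self._setup()
        sim = bpr_similarity(g)
        sweep = threshold_sweep(sim, observed, [0.0, 1.0, 99.0])
        assert sweep[0.0] is None  # everything positive
        assert sweep[99.0] is None  # nothing positive
        assert sweep[1.0] is not None

    def test_empty_tau_list_rejected(self):
        g, observed = self._setup()
        with pytest.raises(ValueError):
            threshold_sweep(bpr_similarity(g), observed, [])

    def test_method_ranking_stable_across_taus(self):
        """The threshold changes absolute AUCs, not which method wins."""
        g, truth = synth.planted_blocks(40, 40, 4, 0.5, 0.05, seed=6)
        # graded ground-truth weights: same-block pairs get weight 2 for
        # adjacent indices, 1 otherwise, so several taus are informative
        observed = {}
        for a, b, _ in truth:
            observed[frozenset((a, b))] = (
                2.0 if abs(int(a[1:]) - int(b[1:])) <= 8 else 1.0
            )
        taus = [1.0, 2.0]
        rankings = []
        for tau in taus:
            aucs = {}
            for method in ("bpr", "jaccard", "euclidean"):
                sim = compute_similarity(g, method)
                aucs[method] = threshold_sweep(sim, observed, [tau])[tau]
            rankings.append(
                tuple(sorted(aucs, key=aucs.get, reverse=True))
            )
        assert rankings[0] == rankings[1]


def test_read_unipartite_edgelist(tmp_path):
    p = tmp_path / "obs.tsv"
    p.write_text("# obs\na\tb\t2.0\nc\td\t1.0\n")
    observed = read_unipartite_edgelist(p)
    assert observed[frozenset(("a", "b"))] == 2.0
    p2 = tmp_path / "bad.tsv"
    p2.write_text("a\ta\t1.0\n")
    with pytest.raises(ValueError):
        read_unipartite_edgelist(p2)
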