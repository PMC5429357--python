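import numpy as np
import pytest
from scipy.stats import mannwhitneyu

import dtni
from dtni.evaluation import (EvaluationResult, GoldStandard, classify_edges,
                             compute_metrics, edge_confidence, roc_auroc,
                             starting_nodes)
from dtni.kinetics import KineticModel, Reaction
from dtni.network import Edge, InferredNetwork


class TestGoldStandard:
    def test_single_conversion_reaction(self):
        model = KineticModel(species={"A": 1.0, "B": 0.0},
                             reactions=[Reaction("r", [("A", 1)], [("B", 1)], 0.1)])
        gold = dtni.gold_standard_from_model(model)
        assert gold.edges == {("A", "B")}

    def test_bimolecular_binding_jacobian_sparsity(self):
        """A + B -> C: each reactant influences the product and the other
        reactant's consumption, never itself."""
        model = KineticModel(
            species={"A": 1.0, "B": 1.0, "C": 0.0},
            reactions=[Reaction("bind", [("A", 1), ("B", 1)], [("C", 1)], 1.0)])
        gold = dtni.gold_standard_from_model(model)
        assert gold.edges == {("A", "C"), ("B", "C"), ("A", "B"), ("B", "A")}

    def test_zeroth_order_synthesis_only_gives_empty_gold(self):
        model = KineticModel(species={"A": 0.0, "B": 0.0},
                             reactions=[Reaction("sA", [], [("A", 1)], 0.1),
                                        Reaction("sB", [], [("B", 1)], 0.2)])
        assert dtni.gold_standard_from_model(model).edges == set()

    def test_modifier_influences_product(self):
        model = KineticModel(
            species={"E": 1.0, "S": 1.0, "P": 0.0},
            reactions=[Reaction("cat", [("S", 1)], [("P", 1)], 0.5,
                                modifiers=["E"])])
        gold = dtni.gold_standard_from_model(model)
        assert ("E", "P") in gold.edges and ("E", "S") in gold.edges

    def test_symmetrize_and_restrict(self):
        gold = GoldStandard(["a", "b", "c"], {("a", "b")})
        assert gold.symmetrized().edges == {("a", "b"), ("b", "a")}
        assert gold.restrict(["a", "b"]).nodes == ["a", "b"]


class TestClassification:
    def gold(self):
        return GoldStandard(["a", "b", "c"], {("a", "b"), ("b", "c")})

    def test_perfect_network(self):
        net = InferredNetwork(["a", "b", "c"],
                              [Edge("a", "b", 1.0, 0.01),
                               Edge("b", "c", -1.0, 0.01)])
        ev = classify_edges(net, self.gold())
        assert (ev.TP, ev.FP, ev.FN) == (2, 0, 0)
        assert ev.sensitivity == 1.0 and ev.ppv == 1.0

    def test_empty_network(self):
        ev = classify_edges(InferredNetwork(["a", "b", "c"]), self.gold())
        assert (ev.TP, ev.FP) == (0, 0)
        assert ev.FN == 2

    def test_counts_sum_to_ordered_pairs(self):
        rng = np.random.default_rng(0)
        nodes = [f"n{i}" for i in range(7)]
        gold_edges = {(a, b) for a in nodes for b in nodes
                      if a != b and rng.random() < 0.2}
        gold = GoldStandard(nodes, gold_edges)
        edges = [Edge(a, b, 1.0, 0.01) for a in nodes for b in nodes
                 if a != b and rng.random() < 0.3]
        ev = classify_edges(InferredNetwork(nodes, edges), gold)
        assert ev.TP + ev.FP + ev.TN + ev.FN == 7 * 6

    def test_unknown_node_rejected(self):
        net = InferredNetwork(["a", "zzz"], [])
        with pytest.raises(ValueError, match="zzz"):
            classify_edges(net, self.gold())


class TestMetrics:
    def test_arithmetic(self):
        ev = compute_metrics(EvaluationResult(TP=3, FN=1, TN=8, FP=2))
        assert ev.sensitivity == pytest.approx(0.75)
        assert ev.specificity == pytest.approx(0.8)
        assert ev.geometric_mean == pytest.approx(np.sqrt(0.6))
        assert ev.ppv == pytest.approx(0.6)

    def test_symmetric_half_case(self):
        ev = compute_metrics(EvaluationResult(1, 1, 1, 1))
        assert ev.sensitivity == ev.specificity == ev.ppv == 0.5
        assert ev.geometric_mean == pytest.approx(0.5)

    def test_zero_denominator_flagged(self):
        ev = compute_metrics(EvaluationResult(TP=0, FP=0, TN=5, FN=0))
        assert ev.ppv == 0.0
        assert "ppv" in ev.undefined and "sensitivity" in ev.undefined


class TestRoc:
    def test_perfect_and_reversed_ranking(self):
        gold = GoldStandard(["a", "b", "c"], {("a", "b"), ("b", "c")})
        pairs = [(i, j) for i in gold.nodes for j in gold.nodes if i != j]
        perfect = {p: (1.0 if p in gold.edges else 0.0) for p in pairs}
        _, auroc = roc_auroc(perfect, gold)
        assert auroc == 1.0
        reversed_ = {p: -s for p, s in perfect.items()}
        _, auroc = roc_auroc(reversed_, gold)
        assert auroc == 0.0

    def test_equals_mann_whitney_on_random_instances(self):
        rng = np.random.default_rng(1)
        nodes = [f"n{i}" for i in range(8)]
        for _ in range(20):
            edges = {(a, b) for a in nodes for b in nodes
                     if a != b and rng.random() < 0.3}
            if not edges or len(edges) == len(nodes) * (len(nodes) - 1):
                continue
            gold = GoldStandard(nodes, edges)
            scores = {(a, b): rng.normal() for a in nodes for b in nodes if a != b}
            _, auroc = roc_auroc(scores, gold)
            pos = [scores[e] for e in edges]
            neg = [s for p, s in scores.items() if p not in edges]
            u = mannwhitneyu(pos, neg).statistic / (len(pos) * len(neg))
            assert auroc == pytest.approx(u, abs=1e-12)

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(2)
        nodes = [f"n{i}" for i in range(20)]
        edges = {(a, b) for a in nodes for b in nodes
                 if a != b and rng.random() < 0.15}
        gold = GoldStandard(nodes, edges)
        aurocs = []
        for _ in range(200):
            scores = {(a, b): rng.normal() for a in nodes for b in nodes if a != b}
            aurocs.append(roc_auroc(scores, gold)[1])
        assert abs(np.mean(aurocs) - 0.5) < 0.03

    def test_degenerate_gold_rejected(self):
        gold = GoldStandard(["a", "b"], set())
        with pytest.raises(ValueError, match="undefined"):
            roc_auroc({("a", "b"): 1.0, ("b", "a"): 0.0}, gold)

    def test_edge_confidence_orders_by_p_then_strength(self):
        p = np.array([[1.0, 0.2, 0.2], [0.1, 1.0, 0.2], [0.2, 0.2, 1.0]])
        A = np.array([[0.0, 1.0, 3.0], [2.0, 0.0, 0.5], [0.1, 0.2, 0.0]])
        genes = ["a", "b", "c"]
        scores = edge_confidence(p, A, genes)
        assert scores[("a", "b")] > scores[("c", "a")]  # smaller p wins
        assert scores[("c", "a")] > scores[("a", "c")]  # tie: larger |strength|


class TestStartingNodes:
    def net(self, edges):
        nodes = sorted({n for e in edges for n in e})
        return InferredNetwork(nodes, [Edge(s, t, 1.0, 0.01) for s, t in edges])

    def test_chain(self):
        assert starting_nodes(self.net([("a", "b"), ("b", "c")])) == ["a"]

    def test_cycle_has_none(self):
        assert starting_nodes(self.net([("a", "b"), ("b", "a")])) == []

    def test_empty_network(self):
        assert starting_nodes(InferredNetwork(["a", "b"], [])) == []

    def test_sorted_output(self):
        nodes = starting_nodes(self.net([("z", "m"), ("a", "m"), ("k", "m")]))
        assert nodes == ["a", "k", "z"]
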