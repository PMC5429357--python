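"""Gold-standard extraction and network-recovery metrics.

A *direct* interaction j -> i exists when species j appears in a
reaction that changes species i, without intermediaries — structurally,
the sparsity pattern of the kinetic model's Jacobian.  Inferred edges
are scored against this gold standard over all ordered gene pairs:
indirect interactions count as negatives for the direct-edge task.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .kinetics import KineticModel
from .network import InferredNetwork

__all__ = [
    "GoldStandard",
    "EvaluationResult",
    "gold_standard_from_model",
    "classify_edges",
    "compute_metrics",
    "edge_confidence",
    "roc_auroc",
    "starting_nodes",
]


@dataclass
class GoldStandard:
    """Directed set of true direct interactions."""

    nodes: list[str]
    edges: set[tuple[str, str]]

    def __post_init__(self) -> None:
        nodes = set(self.nodes)
        for src, tgt in self.edges:
            if src == tgt:
                raise ValueError(f"gold standard may not contain self-edge {src}")
            if src not in nodes or tgt not in nodes:
                raise ValueError(f"gold edge {src}->{tgt} references unknown node")

    def restrict(self, nodes) -> "GoldStandard":
        keep = set(nodes)
        return GoldStandard(list(nodes),
                            {(s, t) for s, t in self.edges if s in keep and t in keep})

    def symmetrized(self) -> "GoldStandard":
        return GoldStandard(list(self.nodes),
                            self.edges | {(t, s) for s, t in self.edges})


@dataclass
class EvaluationResult:
    """Confusion counts over ordered gene pairs and derived metrics.

    Zero-denominator metrics are reported as 0.0 and listed in
    ``undefined``.
    """

    TP: int
    FP: int
    TN: int
    FN: int
    sensitivity: float = 0.0
    specificity: float = 0.0
    geometric_mean: float = 0.0
    ppv: float = 0.0
    auroc: float | None = None
    undefined: list[str] = field(default_factory=list)

    def as_dict(self) -> dict:
        out = {k: getattr(self, k) for k in
               ("TP", "FP", "TN", "FN", "sensitivity", "specificity",
                "geometric_mean", "ppv")}
        if self.auroc is not None:
            out["auroc"] = self.auroc
        return out


def gold_standard_from_model(model: KineticModel) -> GoldStandard:
    """Structural Jacobian sparsity of a mass-action model.

    Edge j -> i iff species j appears as a reactant or modifier of a
    reaction whose net stoichiometry changes species i (i != j).  A
    model with only zeroth-order synthesis reactions therefore has an
    empty edge set.
    """
    edges: set[tuple[str, str]] = set()
    for rxn in model.reactions:
        influencers = {sp for sp, _ in rxn.reactants} | set(rxn.modifiers)
        net: dict[str, int] = {}
        for sp, m in rxn.reactants:
            net[sp] = net.get(sp, 0) - m
        for sp, m in rxn.products:
            net[sp] = net.get(sp, 0) + m
        affected = {sp for sp, change in net.items() if change != 0}
        for j in influencers:
            for i in affected:
                if i != j:
                    edges.add((j, i))
    return GoldStandard(list(model.species), edges)


def classify_edges(inferred: InferredNetwork, gold: GoldStandard) -> EvaluationResult:
    """Confusion counts of an inferred network against the gold standard,
    over all ordered pairs of gold nodes (counts sum to n(n-1))."""
    missing = set(inferred.nodes) - set(gold.nodes)
    if missing:
        raise ValueError(f"inferred nodes absent from gold standard: {sorted(missing)}")
    predicted = inferred.edge_set()
    tp = fp = tn = fn = 0
    for i in gold.nodes:
        for j in gold.nodes:
            if i == j:
                continue
            is_gold = (i, j) in gold.edges
            is_pred = (i, j) in predicted
            if is_pred and is_gold:
                tp += 1
            elif is_pred:
                fp += 1
            elif is_gold:
                fn += 1
            else:
                tn += 1
    return compute_metrics(EvaluationResult(tp, fp, tn, fn))


def compute_metrics(counts: EvaluationResult) -> EvaluationResult:
    """Fill sensitivity, specificity, geometric mean and PPV from the
    confusion counts (in place, returned for chaining)."""
    for name in ("TP", "FP", "TN", "FN"):
        if getattr(counts, name) < 0:
            raise ValueError(f"{name} must be non-negative")

    def ratio(num, den, name):
        if den == 0:
            counts.undefined.append(name)
            return 0.0
        return num / den

    counts.sensitivity = ratio(counts.TP, counts.TP + counts.FN, "sensitivity")
    counts.specificity = ratio(counts.TN, counts.TN + counts.FP, "specificity")
    counts.geometric_mean = float(np.sqrt(counts.sensitivity * counts.specificity))
    counts.ppv = ratio(counts.TP, counts.TP + counts.FP, "ppv")
    return counts


def edge_confidence(p_values: np.ndarray, strengths: np.ndarray,
                    genes) -> dict[tuple[str, str], float]:
    """Confidence score per ordered pair for ROC sweeping: edges are
    ranked by p-value ascending with |strength| descending as
    tie-breaker; larger score = more confident."""
    n = len(genes)
    p = np.asarray(p_values, dtype=float)
    s = np.abs(np.asarray(strengths, dtype=float))
    smax = s.max() if s.size else 1.0
    scores = {}
    for i in range(n):
        for j in range(n):
            if i != j:
                tie = (s[i, j] / smax if smax > 0 else 0.0) * 1e-9
                scores[(genes[j], genes[i])] = -p[i, j] + tie
    return scores


def roc_auroc(scores: dict[tuple[str, str], float], gold: GoldStandard
              ) -> tuple[np.ndarray, float]:
    """ROC curve and AUROC from per-pair confidence scores.

    The threshold sweeps over all distinct score values (ties share one
    operating point); AUROC is the trapezoidal area under TPR vs FPR,
    which equals the Mann-Whitney statistic on the edge scores.
    """
    pairs = [(i, j) for i in gold.nodes for j in gold.nodes if i != j]
    missing = [p for p in pairs if p not in scores]
    if missing:
        raise ValueError(f"scores missing for {len(missing)} ordered pairs, e.g. {missing[0]}")
    y = np.array([(p in gold.edges) for p in pairs], dtype=bool)
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUROC undefined: gold standard is empty or complete")
    s = np.array([scores[p] for p in pairs], dtype=float)

    order = np.argsort(-s, kind="stable")
    s_sorted, y_sorted = s[order], y[order]
    tps = np.cumsum(y_sorted)
    fps = np.cumsum(~y_sorted)
    distinct = np.flatnonzero(np.diff(s_sorted, append=-np.inf))
    tpr = np.concatenate([[0.0], tps[distinct] / n_pos])
    fpr = np.concatenate([[0.0], fps[distinct] / n_neg])
    auroc = float(np.trapezoid(tpr, fpr))
    curve = np.column_stack([fpr, tpr])
    return curve, auroc


def starting_nodes(network: InferredNetwork) -> list[str]:
    """Nodes with outgoing edges and no incoming edges (potential
    molecular initiating events), sorted lexicographically."""
    out_deg = {n: 0 for n in network.nodes}
    in_deg = {n: 0 for n in network.nodes}
    for e in network.edges:
        out_deg[e.source] += 1
        in_deg[e.target] += 1
    return sorted(n for n in network.nodes if out_deg[n] >= 1 and in_deg[n] == 0)
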