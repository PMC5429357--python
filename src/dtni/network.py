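"""Inferred-network container and edge-table IO (TSV, SIF, GraphML).

Edge direction convention, used everywhere in the package: an edge
``j -> i`` means "expression of gene j influences the derivative of gene
i" (interaction-matrix entry ``a_ij`` is nonzero).  A positive strength is
an activation, a negative one an inhibition.  The diagonal of the
interaction matrix is self-degradation and is never reported as an edge.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import networkx as nx

__all__ = ["Edge", "InferredNetwork", "write_edge_table", "read_edge_table"]

SIF_ACTIVATES = "activates"
SIF_INHIBITS = "inhibits"


class Edge(NamedTuple):
    source: str
    target: str
    strength: float
    p_value: float

    @property
    def sign(self) -> str:
        return "activation" if self.strength > 0 else "inhibition"


@dataclass
class InferredNetwork:
    """Directed network of signed, significance-annotated interactions."""

    nodes: list[str]
    edges: list[Edge] = field(default_factory=list)

    def __post_init__(self) -> None:
        nodes = set(self.nodes)
        for e in self.edges:
            if e.source == e.target:
                raise ValueError(f"self-edge {e.source}->{e.target} is not allowed")
            if e.source not in nodes or e.target not in nodes:
                raise ValueError(f"edge {e.source}->{e.target} references unknown node")
            if not 0.0 <= e.p_value <= 1.0:
                raise ValueError(f"p-value out of [0, 1]: {e.p_value}")

    def edge_set(self) -> set[tuple[str, str]]:
        return {(e.source, e.target) for e in self.edges}

    def sorted_edges(self) -> list[Edge]:
        """Deterministic edge order: |strength| descending, then
        lexicographic (source, target)."""
        return sorted(self.edges, key=lambda e: (-abs(e.strength), e.source, e.target))

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        for e in self.edges:
            g.add_edge(e.source, e.target, strength=e.strength,
                       sign=e.sign, p_value=e.p_value)
        return g

    def __len__(self) -> int:
        return len(self.edges)


def write_edge_table(network: InferredNetwork, path, format: str = "tsv") -> None:
    """Write a network as TSV (full annotation), SIF (Cytoscape simple
    interaction format, sign only) or GraphML."""
    fmt = format.lower()
    if fmt == "tsv":
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("source\ttarget\tstrength\tsign\tp_value\n")
            for e in network.sorted_edges():
                fh.write(f"{e.source}\t{e.target}\t{e.strength:.10g}\t{e.sign}\t{e.p_value:.10g}\n")
    elif fmt == "sif":
        with open(path, "w", encoding="utf-8") as fh:
            for e in network.sorted_edges():
                rel = SIF_ACTIVATES if e.strength > 0 else SIF_INHIBITS
                fh.write(f"{e.source}\t{rel}\t{e.target}\n")
    elif fmt == "graphml":
        nx.write_graphml(network.to_networkx(), path)
    else:
        raise ValueError(f"unknown edge format {format!r}; use tsv, sif or graphml")


def read_edge_table(path, format: str = "tsv") -> InferredNetwork:
    """Read a network back.  TSV and GraphML round-trip all annotation;
    SIF carries only source, sign and target (strength becomes +/-1 and
    p-values 0)."""
    fmt = format.lower()
    if fmt == "tsv":
        edges, nodes = [], []
        with open(path, encoding="utf-8") as fh:
            header = fh.readline().rstrip("\n").split("\t")
            idx = {name: i for i, name in enumerate(header)}
            for name in ("source", "target", "strength", "p_value"):
                if name not in idx:
                    raise ValueError(f"edge TSV missing column {name!r}")
            for line in fh:
                f = line.rstrip("\n").split("\t")
                edges.append(Edge(f[idx["source"]], f[idx["target"]],
                                  float(f[idx["strength"]]), float(f[idx["p_value"]])))
        for e in edges:
            for node in (e.source, e.target):
                if node not in nodes:
                    nodes.append(node)
        return InferredNetwork(nodes, edges)
    if fmt == "sif":
        edges, nodes = [], []
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                if not line.strip():
                    continue
                src, rel, tgt = line.rstrip("\n").split("\t")
                strength = 1.0 if rel == SIF_ACTIVATES else -1.0
                edges.append(Edge(src, tgt, strength, 0.0))
                for node in (src, tgt):
                    if node not in nodes:
                        nodes.append(node)
        return InferredNetwork(nodes, edges)
    if fmt == "graphml":
        g = nx.read_graphml(path)
        edges = [Edge(str(u), str(v), float(d["strength"]), float(d["p_value"]))
                 for u, v, d in g.edges(data=True)]
        return InferredNetwork([str(n) for n in g.nodes], edges)
    raise ValueError(f"unknown edge format {format!r}; use tsv, sif or graphml")
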