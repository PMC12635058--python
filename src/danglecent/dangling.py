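"""Dangling centrality: node importance via link-removal perturbation.

A node's dangling centrality is the relative drop in the graph's global
reciprocal-connectivity score when every edge incident to the node is
deleted (the node itself stays, at degree zero):

    phi_c(i) = (phi_c(G) - phi_c(G_i)) / phi_c(G)

where phi_c(.) is half the sum of reciprocal finite geodesic distances over
ordered node pairs.  The score lies in [0, 1]: 0 for a node whose links
carry no connectivity (an isolated node), 1 for a node whose removal
disconnects every pair (the centre of a star).  Because the ratio is scale
free, the undirected halving applied to both terms cancels.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Sequence

from .graph_io import UndirectedGraph
from .shortest_paths import reciprocal_sum, spdm

__all__ = ["DanglingResult", "remove_node_links", "dangling_node", "dangling_all"]


@dataclass(frozen=True)
class NodeDangling:
    """Per-node perturbation outcome."""

    label: str
    perturbed_score: float  # phi_c(G_i)
    dangling: float         # phi_c(i)


@dataclass(frozen=True)
class DanglingResult:
    """Global score plus the per-node perturbed scores and dangling values."""

    global_score: float  # phi_c(G)
    per_node: tuple[NodeDangling, ...]

    def values(self) -> dict[str, float]:
        return {r.label: r.dangling for r in self.per_node}

    def as_records(self) -> list[dict[str, object]]:
        """Rows for :func:`danglecent.graph_io.write_table` (with ranks)."""
        order = sorted(
            range(len(self.per_node)),
            key=lambda i: (-self.per_node[i].dangling, self.per_node[i].label),
        )
        rank = {i: pos + 1 for pos, i in enumerate(order)}
        return [
            {
                "node": r.label,
                "phi_global": self.global_score,
                "phi_perturbed": r.perturbed_score,
                "phi_dangling": r.dangling,
                "rank": rank[i],
            }
            for i, r in enumerate(self.per_node)
        ]


def remove_node_links(graph: UndirectedGraph, label: str) -> UndirectedGraph:
    """Delete all edges incident to ``label``, keeping the node at degree 0."""
    if not graph.has_node(label):
        raise KeyError(f"unknown node label {label!r}")
    kept = [e for e in graph.sorted_edges() if label not in e]
    return UndirectedGraph(graph.labels, kept)


def _exact_scores(graph: UndirectedGraph, labels: Sequence[str]) -> tuple[Fraction, list[Fraction]]:
    """Halved global score and per-node halved perturbed scores, exact."""
    base = reciprocal_sum(spdm(graph)) / 2
    perturbed = [reciprocal_sum(spdm(remove_node_links(graph, lab))) / 2 for lab in labels]
    return base, perturbed


def dangling_node(graph: UndirectedGraph, label: str) -> float:
    """Dangling centrality of a single node; requires at least one edge."""
    if not graph.has_node(label):
        raise KeyError(f"unknown node label {label!r}")
    base, (pert,) = _exact_scores(graph, [label])
    if base == 0:
        raise ZeroDivisionError(
            "dangling centrality undefined on an edgeless graph (global score is 0)"
        )
    return float((base - pert) / base)


def dangling_all(
    graph: UndirectedGraph, subset: Sequence[str] | None = None
) -> DanglingResult:
    """Dangling centrality for every node (or a subset), one BFS sweep each.

    The global score is computed once; each node is then perturbed by
    deleting its links and the all-pairs distances of the perturbed graph
    are recomputed from scratch.  Output order follows the input label
    order (or the subset order given).
    """
    labels = graph.labels if subset is None else tuple(subset)
    for lab in labels:
        if not graph.has_node(lab):
            raise KeyError(f"unknown node label {lab!r}")
    base, perturbed = _exact_scores(graph, labels)
    if base == 0:
        raise ZeroDivisionError(
            "dangling centrality undefined on an edgeless graph (global score is 0)"
        )
    per_node = tuple(
        NodeDangling(lab, float(p), float((base - p) / base))
        for lab, p in zip(labels, perturbed)
    )
    return DanglingResult(global_score=float(base), per_node=per_node)
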