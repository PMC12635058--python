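"""All-pairs shortest-path distances and global reciprocal connectivity.

The distance matrix (geodesic edge counts from BFS at every source) feeds
both closeness centrality and the dangling-centrality perturbation score.
The global score is half the sum of 1/d over ordered node pairs with finite
positive distance — unreachable pairs and the zero diagonal contribute
nothing.  Reciprocals are accumulated in exact rational arithmetic so that
e.g. three pairs at distance 3 contribute exactly 1, not 3 x 0.333....
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np

from .graph_io import UndirectedGraph

__all__ = ["DistanceMatrix", "UNREACHABLE", "spdm", "reciprocal_connectivity"]

#: Sentinel stored in DistanceMatrix.dist where no path exists.
UNREACHABLE: int = -1


@dataclass(frozen=True)
class DistanceMatrix:
    """n x n geodesic distance matrix with an explicit unreachable marker.

    ``dist[i, j]`` is the minimum number of edges between ``labels[i]`` and
    ``labels[j]``, or :data:`UNREACHABLE` when no path exists.  The diagonal
    is 0 and the matrix is symmetric.
    """

    labels: tuple[str, ...]
    dist: np.ndarray

    def finite_mask(self) -> np.ndarray:
        """Boolean mask of reachable (finite-distance) entries."""
        return self.dist != UNREACHABLE

    def is_unreachable(self, i: int, j: int) -> bool:
        return self.dist[i, j] == UNREACHABLE

    def row_sums(self) -> np.ndarray:
        """Per-node sum of finite distances to all other nodes."""
        d = np.where(self.finite_mask(), self.dist, 0)
        return d.sum(axis=1)

    def to_text(self, path, *, delimiter: str = "\t") -> None:
        """Dump as delimited text with ``inf`` for unreachable entries."""
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(delimiter.join(("node", *self.labels)) + "\n")
            for i, lab in enumerate(self.labels):
                row = ("inf" if self.dist[i, j] == UNREACHABLE else str(int(self.dist[i, j]))
                       for j in range(len(self.labels)))
                fh.write(delimiter.join((lab, *row)) + "\n")


def spdm(graph: UndirectedGraph) -> DistanceMatrix:
    """Compute the shortest-path distance matrix by BFS from every node."""
    import networkx as nx

    labels = graph.labels
    n = len(labels)
    dist = np.full((n, n), UNREACHABLE, dtype=np.int64)
    if n == 0:
        return DistanceMatrix(labels, dist)
    g = graph.to_networkx()
    index = {lab: i for i, lab in enumerate(labels)}
    for src in labels:
        i = index[src]
        for dst, d in nx.single_source_shortest_path_length(g, src).items():
            dist[i, index[dst]] = d
    return DistanceMatrix(labels, dist)


def reciprocal_sum(dm: DistanceMatrix) -> Fraction:
    """Exact sum of 1/d over all ordered pairs with finite positive distance."""
    d = dm.dist
    n = d.shape[0]
    total = Fraction(0)
    for i in range(n):
        for j in range(n):
            if i != j and d[i, j] != UNREACHABLE:
                total += Fraction(1, int(d[i, j]))
    return total


def reciprocal_connectivity(dm: DistanceMatrix, *, undirected_halving: bool = True) -> float:
    """Global reciprocal-connectivity score of a distance matrix.

    Sums ``1/d`` over every ordered pair of distinct nodes with finite
    distance, skipping unreachable pairs, and divides by 2 when
    ``undirected_halving`` is set (each undirected connection would
    otherwise be counted once per direction).
    """
    total = reciprocal_sum(dm)
    if undirected_halving:
        total /= 2
    return float(total)
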