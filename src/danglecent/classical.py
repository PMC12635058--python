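"""The five classical centrality metrics under this package's conventions.

These deliberately differ from common graph-library defaults in two ways:

* betweenness accumulates geodesic fractions over *ordered* source-target
  pairs (so it equals exactly twice the standard Freeman/Brandes value on
  undirected graphs) and is unnormalized;
* closeness is the raw reciprocal of the sum of finite geodesic distances
  (no (n-1) scaling), with unreachable pairs excluded;
* eigenvector centrality is the power method started from the all-ones
  vector with Euclidean normalization each step, reporting the dominant
  eigenvalue as the final pre-normalization norm, and offers a
  fixed-iteration mode;
* Katz centrality solves (I - alpha A^T) x = beta 1 directly and rejects
  alpha >= 1/lambda.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .graph_io import UndirectedGraph
from .shortest_paths import UNREACHABLE, spdm

__all__ = [
    "CentralityVector",
    "degree_centrality",
    "closeness_centrality",
    "betweenness_centrality",
    "eigenvector_centrality",
    "katz_centrality",
    "default_katz_alpha",
]


@dataclass(frozen=True)
class CentralityVector:
    """One metric's value per node, tagged with the metric name and params."""

    metric: str
    values: dict[str, float]
    params: dict[str, float] = field(default_factory=dict)

    def as_array(self, order: tuple[str, ...] | None = None) -> np.ndarray:
        labs = order if order is not None else tuple(self.values)
        return np.array([self.values[lab] for lab in labs], dtype=float)

    def __getitem__(self, label: str) -> float:
        return self.values[label]


def degree_centrality(graph: UndirectedGraph) -> CentralityVector:
    """Number of incident edges per node."""
    return CentralityVector(
        "dc", {lab: float(graph.degree(lab)) for lab in graph.labels}
    )


def closeness_centrality(graph: UndirectedGraph) -> CentralityVector:
    """1 / (sum of finite geodesic distances to all other nodes).

    Unreachable pairs are excluded from the sum; a node with no finite
    distances at all (isolated, or alone) scores 0.
    """
    dm = spdm(graph)
    values: dict[str, float] = {}
    for i, lab in enumerate(dm.labels):
        row = dm.dist[i]
        finite = row[(row != UNREACHABLE) & (np.arange(len(row)) != i)]
        s = int(finite.sum())
        values[lab] = 1.0 / s if s > 0 else 0.0
    return CentralityVector("cc", values)


def betweenness_centrality(graph: UndirectedGraph) -> CentralityVector:
    """Ordered-pair geodesic betweenness (Brandes accumulation, doubled).

    value(u) = sum over ordered pairs (s, t), s != t != u, of the fraction
    of shortest s-t paths passing through u; endpoints excluded, no
    normalization.  On undirected graphs this is exactly twice the
    standard Freeman betweenness.
    """
    labels = graph.labels
    bc = {lab: 0.0 for lab in labels}
    # Brandes' two-pass accumulation over unordered pairs, then double.
    for s in labels:
        stack: list[str] = []
        pred: dict[str, list[str]] = {v: [] for v in labels}
        sigma: dict[str, float] = {v: 0.0 for v in labels}
        dist: dict[str, int] = {v: -1 for v in labels}
        sigma[s] = 1.0
        dist[s] = 0
        queue = deque([s])
        while queue:
            v = queue.popleft()
            stack.append(v)
            for w in graph.neighbors(v):
                if dist[w] < 0:
                    dist[w] = dist[v] + 1
                    queue.append(w)
                if dist[w] == dist[v] + 1:
                    sigma[w] += sigma[v]
                    pred[w].append(v)
        delta: dict[str, float] = {v: 0.0 for v in labels}
        while stack:
            w = stack.pop()
            for v in pred[w]:
                delta[v] += sigma[v] / sigma[w] * (1.0 + delta[w])
            if w != s:
                bc[w] += delta[w]
    # each unordered pair counted once per endpoint as source -> already x2
    return CentralityVector("bc", bc)


def eigenvector_centrality(
    graph: UndirectedGraph,
    *,
    fixed_iterations: int | None = None,
    tol: float = 1e-10,
    max_iterations: int = 10_000,
) -> tuple[CentralityVector, float]:
    """Power-method eigenvector centrality and the dominant eigenvalue.

    Iterates ``w = A v``, ``lambda = ||w||_2``, ``v = w / lambda`` from the
    all-ones start vector.  With ``fixed_iterations`` set, exactly that
    many multiplications are performed; otherwise iteration stops when the
    max absolute change of the vector drops below ``tol``.

    Returns
    -------
    (CentralityVector, float)
        The unit-norm vector and lambda, the Euclidean norm of the last
        pre-normalization product.
    """
    if graph.n_edges == 0:
        raise ValueError("eigenvector centrality undefined on an edgeless graph")
    a = graph.adjacency_matrix().astype(float)
    v = np.ones(graph.n_nodes)
    lam = 0.0
    if fixed_iterations is not None:
        if fixed_iterations < 1:
            raise ValueError("fixed_iterations must be >= 1")
        for _ in range(fixed_iterations):
            w = a @ v
            lam = float(np.linalg.norm(w))
            v = w / lam
    else:
        v = v / np.linalg.norm(v)
        for _ in range(max_iterations):
            w = a @ v
            lam = float(np.linalg.norm(w))
            if lam == 0.0:
                raise ValueError("power iteration collapsed to the zero vector")
            w /= lam
            if np.max(np.abs(w - v)) < tol:
                v = w
                break
            v = w
        else:
            raise RuntimeError(
                f"power iteration did not converge in {max_iterations} steps; "
                f"last lambda={lam:.6g}, residual={np.max(np.abs(a @ v - lam * v)):.3g}"
            )
    values = {lab: float(v[i]) for i, lab in enumerate(graph.labels)}
    params: dict[str, float] = {"tol": tol} if fixed_iterations is None else {
        "fixed_iterations": float(fixed_iterations)
    }
    return CentralityVector("evc", values, params), lam


def default_katz_alpha(graph: UndirectedGraph) -> float:
    """alpha = 0.2 when that is below 1/lambda, else 0.85/lambda."""
    _, lam = eigenvector_centrality(graph)
    return 0.2 if lam > 0 and 0.2 < 1.0 / lam else 0.85 / lam


def katz_centrality(
    graph: UndirectedGraph, alpha: float = 0.2, beta: float = 1.0
) -> CentralityVector:
    """Katz centrality beta (I - alpha A^T)^{-1} 1 by direct linear solve.

    Requires ``0 <= alpha < 1/lambda`` (lambda the dominant adjacency
    eigenvalue); at or beyond 1/lambda the resolvent series diverges and
    the system is singular.
    """
    if alpha < 0:
        raise ValueError("alpha must be non-negative")
    max_deg = max((graph.degree(l) for l in graph.labels), default=0)
    # lambda <= max degree, so alpha * max_deg < 1 is already safe; only
    # borderline choices need the power-method eigenvalue.
    if alpha > 0 and graph.n_edges > 0 and alpha * max_deg >= 1.0:
        _, lam = eigenvector_centrality(graph)
        if lam > 0 and alpha >= 1.0 / lam:
            raise ValueError(
                f"alpha={alpha} >= 1/lambda={1.0 / lam:.6g}: Katz centrality diverges; "
                "choose alpha < 1/lambda"
            )
    a = graph.adjacency_matrix().astype(float)
    n = graph.n_nodes
    x = np.linalg.solve(np.eye(n) - alpha * a.T, beta * np.ones(n))
    return CentralityVector(
        "katz",
        {lab: float(x[i]) for i, lab in enumerate(graph.labels)},
        {"alpha": alpha, "beta": beta},
    )
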