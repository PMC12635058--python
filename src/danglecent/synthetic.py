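"""Deterministic graph generators for property testing and closed-form checks.

The Erdos-Renyi stream is fixed by contract: a seeded generator draws one
uniform variate per upper-triangle cell in row-major order, so identical
(n, p, seed) always yields an identical edge list.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .graph_io import UndirectedGraph

__all__ = ["GeneratorSpec", "generate"]

_FAMILIES = ("star", "complete", "path", "cycle", "erdos_renyi")


@dataclass(frozen=True)
class GeneratorSpec:
    """Recipe for one deterministic synthetic graph."""

    family: str
    n: int
    p: float = 0.0  # erdos_renyi only
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; choose from {_FAMILIES}")
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if not (0.0 <= self.p <= 1.0):
            raise ValueError("p must be in [0, 1]")


def generate(spec: GeneratorSpec) -> UndirectedGraph:
    """Build the graph described by ``spec``; labels are "0".."n-1".

    ``star`` puts node 0 at the centre; ``path`` and ``cycle`` connect
    consecutive labels; ``erdos_renyi`` includes each upper-triangle pair
    (i, j), i < j, traversed row-major, when the seeded uniform draw for
    that cell is below ``p``.
    """
    n = spec.n
    labels = [str(i) for i in range(n)]
    edges: list[tuple[str, str]] = []
    if spec.family == "star":
        edges = [("0", str(i)) for i in range(1, n)]
    elif spec.family == "complete":
        edges = [(str(i), str(j)) for i in range(n) for j in range(i + 1, n)]
    elif spec.family == "path":
        edges = [(str(i), str(i + 1)) for i in range(n - 1)]
    elif spec.family == "cycle":
        edges = [(str(i), str(i + 1)) for i in range(n - 1)]
        if n > 2:
            edges.append((str(n - 1), "0"))
    elif spec.family == "erdos_renyi":
        rng = np.random.default_rng(spec.seed)
        for i in range(n):
            for j in range(i + 1, n):
                if rng.random() < spec.p:
                    edges.append((str(i), str(j)))
    return UndirectedGraph(labels, edges)
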