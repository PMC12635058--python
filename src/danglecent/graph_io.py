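"""Reading, sanitizing and writing graphs and result tables.

Graphs arrive as plain-text edge lists (SNAP-style tab/whitespace files with
``#`` comment headers, or comma-separated files with trailing rating/timestamp
columns) or as square 0/1 adjacency matrices.  Everything is reduced to a
simple undirected graph: self-loops dropped, duplicate and reciprocal edges
collapsed, external node labels preserved verbatim.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

__all__ = [
    "UndirectedGraph",
    "SanitizeLog",
    "GraphParseError",
    "read_edge_list",
    "read_adjacency_matrix",
    "builtin_graph",
    "write_edge_list",
    "write_table",
]


class GraphParseError(ValueError):
    """Raised for malformed graph input files."""


@dataclass(frozen=True)
class SanitizeLog:
    """Record of what sanitization changed while reading a graph."""

    symmetrized: bool = False
    dropped_selfloops: int = 0
    dropped_duplicates: int = 0
    ignored_columns: int = 0

    def __post_init__(self) -> None:
        for name in ("dropped_selfloops", "dropped_duplicates", "ignored_columns"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


class UndirectedGraph:
    """A simple unweighted undirected graph with opaque string node labels.

    Node labels are kept exactly as given; an internal label -> index map
    backs all matrix/vector computations.  Self-loops and duplicate edges are
    rejected at construction (use :func:`read_edge_list` to sanitize raw
    input and count the drops).
    """

    __slots__ = ("_labels", "_index", "_adj", "n_selfloops_dropped", "n_duplicates_dropped")

    def __init__(
        self,
        labels: Iterable[str],
        edges: Iterable[tuple[str, str]],
        *,
        n_selfloops_dropped: int = 0,
        n_duplicates_dropped: int = 0,
    ) -> None:
        self._labels: tuple[str, ...] = tuple(str(x) for x in labels)
        if len(set(self._labels)) != len(self._labels):
            raise ValueError("node labels must be unique")
        self._index: dict[str, int] = {lab: i for i, lab in enumerate(self._labels)}
        self._adj: dict[str, set[str]] = {lab: set() for lab in self._labels}
        seen: set[frozenset[str]] = set()
        for u, v in edges:
            u, v = str(u), str(v)
            if u not in self._index or v not in self._index:
                raise ValueError(f"edge ({u!r}, {v!r}) references unknown node")
            if u == v:
                raise ValueError(f"self-loop on {u!r} not allowed; sanitize input first")
            key = frozenset((u, v))
            if key in seen:
                raise ValueError(f"duplicate edge ({u!r}, {v!r}); sanitize input first")
            seen.add(key)
            self._adj[u].add(v)
            self._adj[v].add(u)
        self.n_selfloops_dropped = n_selfloops_dropped
        self.n_duplicates_dropped = n_duplicates_dropped

    # -- basic queries -------------------------------------------------

    @property
    def labels(self) -> tuple[str, ...]:
        return self._labels

    @property
    def n_nodes(self) -> int:
        return len(self._labels)

    @property
    def n_edges(self) -> int:
        return sum(len(s) for s in self._adj.values()) // 2

    def edges(self) -> set[frozenset[str]]:
        """The edge set as unordered label pairs."""
        return {frozenset((u, v)) for u, nbrs in self._adj.items() for v in nbrs}

    def sorted_edges(self) -> list[tuple[str, str]]:
        """Edges as sorted (u, v) tuples in deterministic order."""
        return sorted(tuple(sorted(e)) for e in self.edges())

    def neighbors(self, label: str) -> frozenset[str]:
        return frozenset(self._adj[label])

    def degree(self, label: str) -> int:
        return len(self._adj[label])

    def has_node(self, label: str) -> bool:
        return label in self._index

    def index_of(self, label: str) -> int:
        return self._index[label]

    def __contains__(self, label: object) -> bool:
        return label in self._index

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, UndirectedGraph):
            return NotImplemented
        return self._labels == other._labels and self.edges() == other.edges()

    def __hash__(self) -> int:  # labels ordered, edges unordered
        return hash((self._labels, frozenset(self.edges())))

    def __repr__(self) -> str:
        return f"UndirectedGraph(n_nodes={self.n_nodes}, n_edges={self.n_edges})"

    def to_networkx(self):
        """Export as a :class:`networkx.Graph` (nodes in label order)."""
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self._labels)
        g.add_edges_from(tuple(sorted(e)) for e in self.edges())
        return g

    def adjacency_matrix(self):
        """Dense 0/1 adjacency matrix in label order."""
        import numpy as np

        n = self.n_nodes
        a = np.zeros((n, n), dtype=int)
        for e in self.edges():
            u, v = tuple(e)
            i, j = self._index[u], self._index[v]
            a[i, j] = a[j, i] = 1
        return a


def _sanitize_edges(
    raw: Sequence[tuple[str, str]],
) -> tuple[list[str], list[tuple[str, str]], int, int]:
    """Collapse self-loops and duplicates; return labels in first-seen order."""
    labels: list[str] = []
    seen_nodes: set[str] = set()
    edges: list[tuple[str, str]] = []
    seen_edges: set[frozenset[str]] = set()
    selfloops = dups = 0
    for u, v in raw:
        for x in (u, v):
            if x not in seen_nodes:
                seen_nodes.add(x)
                labels.append(x)
        if u == v:
            selfloops += 1
            continue
        key = frozenset((u, v))
        if key in seen_edges:
            dups += 1
            continue
        seen_edges.add(key)
        edges.append((u, v))
    return labels, edges, selfloops, dups


def _detect_delimiter(sample_lines: Sequence[str]) -> str | None:
    """Try tab, then comma, then any whitespace (returned as None)."""
    for delim in ("\t", ","):
        if all(len(line.split(delim)) >= 2 for line in sample_lines):
            return delim
    return None


def read_edge_list(
    path,
    *,
    delimiter: str | None = "auto",
    directed_policy: str = "symmetrize",
) -> tuple[UndirectedGraph, SanitizeLog]:
    """Parse a plain-text edge list into a sanitized undirected graph.

    Parameters
    ----------
    path
        File with one edge per line; lines starting with ``#`` are comments.
    delimiter
        ``"auto"`` tries tab, then comma, then arbitrary whitespace; or pass
        an explicit single character.
    directed_policy
        ``"symmetrize"`` collapses reciprocal directed pairs into one
        undirected edge (counted as duplicates); ``"reject"`` raises if any
        reciprocal pair is present.

    Returns
    -------
    (UndirectedGraph, SanitizeLog)
        The graph plus counts of dropped self-loops, collapsed duplicates
        and ignored extra columns (e.g. trust ratings, timestamps).
    """
    if directed_policy not in ("symmetrize", "reject"):
        raise ValueError(f"unknown directed_policy {directed_policy!r}")
    with open(path, "r", encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    data = [(i + 1, ln.strip()) for i, ln in enumerate(lines)
            if ln.strip() and not ln.lstrip().startswith("#")]
    if not data:
        raise GraphParseError(f"{path}: no edge data found")

    if delimiter == "auto":
        delim = _detect_delimiter([ln for _, ln in data[:50]])
    else:
        delim = delimiter

    raw: list[tuple[str, str]] = []
    directed_seen: set[tuple[str, str]] = set()
    ignored_cols = 0
    reciprocal = False
    for lineno, ln in data:
        fields = ln.split(delim) if delim is not None else re.split(r"\s+", ln)
        fields = [f.strip() for f in fields if f.strip() != ""]
        if len(fields) < 2:
            raise GraphParseError(f"{path}:{lineno}: expected at least two fields, got {ln!r}")
        u, v = fields[0], fields[1]
        ignored_cols += len(fields) - 2
        if (v, u) in directed_seen and (u, v) not in directed_seen and u != v:
            reciprocal = True
        directed_seen.add((u, v))
        raw.append((u, v))
    if directed_policy == "reject" and reciprocal:
        raise GraphParseError(f"{path}: reciprocal directed pair found and policy is 'reject'")

    labels, edges, selfloops, dups = _sanitize_edges(raw)
    graph = UndirectedGraph(
        labels, edges, n_selfloops_dropped=selfloops, n_duplicates_dropped=dups
    )
    log = SanitizeLog(
        symmetrized=reciprocal,
        dropped_selfloops=selfloops,
        dropped_duplicates=dups,
        ignored_columns=ignored_cols,
    )
    return graph, log


def read_adjacency_matrix(path) -> UndirectedGraph:
    """Read a square symmetric 0/1 adjacency matrix from delimited text.

    An optional header row/column is detected by a non-numeric first token
    and supplies the node labels; otherwise nodes are labelled by row index
    starting at 0.  Diagonal ones (self-loops) are dropped and counted.
    """
    with open(path, "r", encoding="utf-8") as fh:
        lines = [ln.strip() for ln in fh.read().splitlines() if ln.strip()]
    if not lines:
        raise GraphParseError(f"{path}: empty file")

    def tokens(ln: str) -> list[str]:
        return [t for t in re.split(r"[,\s]+", ln) if t]

    rows = [tokens(ln) for ln in lines]
    labels: list[str] | None = None
    if rows and not _is_number(rows[0][0]) and len(rows[0]) >= 1 and all(
        not _is_number(t) for t in rows[0]
    ):
        header = rows[0]
        rows = rows[1:]
        # header row may or may not be echoed as a leading label column
        if rows and not _is_number(rows[0][0]):
            labels = [r[0] for r in rows]
            rows = [r[1:] for r in rows]
        else:
            labels = header
    n = len(rows)
    if labels is None:
        labels = [str(i) for i in range(n)]
    if any(len(r) != n for r in rows):
        raise GraphParseError(f"{path}: matrix is not square ({n} rows)")
    if len(labels) != n:
        raise GraphParseError(f"{path}: header/label count does not match matrix size")

    selfloops = 0
    edges: list[tuple[str, str]] = []
    vals = [[int(float(t)) for t in r] for r in rows]
    for i in range(n):
        for j in range(n):
            if vals[i][j] not in (0, 1):
                raise GraphParseError(f"{path}: entry ({i},{j}) is not 0/1")
            if vals[i][j] != vals[j][i]:
                raise GraphParseError(f"{path}: asymmetric at cell ({i},{j})")
        if vals[i][i] == 1:
            selfloops += 1
        for j in range(i + 1, n):
            if vals[i][j] == 1:
                edges.append((labels[i], labels[j]))
    return UndirectedGraph(labels, edges, n_selfloops_dropped=selfloops)


def _is_number(tok: str) -> bool:
    try:
        float(tok)
    except ValueError:
        return False
    return True


# -- built-in worked-example graphs -----------------------------------

_FIVE_NODE_EDGES = [("0", "1"), ("0", "2"), ("0", "3"), ("1", "2"), ("3", "4")]
# 10-edge six-node graph (1-based labels); the sparse variant drops edge (2,4)
_SIX_NODE_EDGES = [
    ("1", "2"), ("1", "5"), ("2", "3"), ("2", "4"), ("2", "5"),
    ("3", "4"), ("3", "6"), ("4", "5"), ("4", "6"), ("5", "6"),
]


def builtin_graph(which: str) -> UndirectedGraph:
    """Return one of the built-in small worked-example graphs.

    ``"five_node"``
        5 nodes / 5 edges, labels ``0``..``4``, edges
        {0-1, 0-2, 0-3, 1-2, 3-4}.
    ``"six_node"``
        6 nodes / 10 edges, labels ``1``..``6``; the canonical matrix used
        by all six-node worked values.
    ``"six_node_sparse"``
        The 9-edge variant of the same graph (edge 2-4 absent), degree
        sequence [2, 3, 3, 3, 4, 3].
    """
    if which == "five_node":
        return UndirectedGraph([str(i) for i in range(5)], _FIVE_NODE_EDGES)
    if which == "six_node":
        return UndirectedGraph([str(i) for i in range(1, 7)], _SIX_NODE_EDGES)
    if which == "six_node_sparse":
        edges = [e for e in _SIX_NODE_EDGES if e != ("2", "4")]
        return UndirectedGraph([str(i) for i in range(1, 7)], edges)
    raise ValueError(f"unknown builtin graph {which!r}")


# -- writers -----------------------------------------------------------

def write_edge_list(graph: UndirectedGraph, path, *, delimiter: str = "\t") -> None:
    """Write the graph as a sorted edge list (isolated nodes as comments)."""
    isolated = [lab for lab in graph.labels if graph.degree(lab) == 0]
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# undirected simple graph: {graph.n_nodes} nodes, {graph.n_edges} edges\n")
        for lab in isolated:
            fh.write(f"# isolated: {lab}\n")
        for u, v in graph.sorted_edges():
            fh.write(f"{u}{delimiter}{v}\n")


def write_table(
    rows: Sequence[Mapping[str, object]],
    path,
    *,
    delimiter: str = "\t",
    precision: int = 6,
) -> None:
    """Write labeled records as delimited text with a header row.

    All records must share the same field set; floats are printed with
    ``precision`` significant digits.
    """
    if not rows:
        raise ValueError("write_table: no records to write")
    fields = list(rows[0].keys())
    for i, r in enumerate(rows):
        if list(r.keys()) != fields:
            raise ValueError(f"write_table: record {i} has fields {list(r.keys())}, expected {fields}")

    def fmt(x: object) -> str:
        if isinstance(x, bool):
            return str(x)
        if isinstance(x, float):
            return f"{x:.{precision}g}"
        return str(x)

    with open(path, "w", encoding="utf-8") as fh:
        fh.write(delimiter.join(fields) + "\n")
        for r in rows:
            fh.write(delimiter.join(fmt(r[f]) for f in fields) + "\n")
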