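"""Agreement between centrality rankings: Pearson, Spearman, Kendall tau-b.

Spearman uses average ranks for ties; Kendall is the tie-corrected tau-b,
(C - D) / sqrt((n0 - t_x)(n0 - t_y)).  Coefficients are computed on the
raw metric values, never on rounded displays.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .classical import CentralityVector

__all__ = [
    "ConcordanceEntry",
    "ConcordanceReport",
    "RankTable",
    "pearson",
    "spearman",
    "kendall_tau_b",
    "concordance_report",
    "rank_nodes",
]

#: Deterministic metric ordering for reports.
_METRIC_ORDER = ("dc", "bc", "cc", "evc", "katz")


class UndefinedCoefficientError(ValueError):
    """A correlation coefficient is undefined (zero variance / all ties)."""


def _check(x: Sequence[float], y: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
    xa, ya = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    if xa.shape != ya.shape or xa.ndim != 1:
        raise ValueError("inputs must be equal-length 1-d sequences")
    if len(xa) < 3:
        raise ValueError("need at least 3 observations")
    return xa, ya


def pearson(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation coefficient."""
    xa, ya = _check(x, y)
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        raise UndefinedCoefficientError("pearson undefined for zero-variance input")
    return float(stats.pearsonr(xa, ya).statistic)


def spearman(x: Sequence[float], y: Sequence[float]) -> float:
    """Rank correlation with average ranks assigned to ties."""
    xa, ya = _check(x, y)
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        raise UndefinedCoefficientError("spearman undefined for zero-variance input")
    return float(stats.spearmanr(xa, ya).statistic)


def kendall_tau_b(x: Sequence[float], y: Sequence[float]) -> float:
    """Kendall correlation with the tau-b tie correction in the denominator."""
    xa, ya = _check(x, y)
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        raise UndefinedCoefficientError("kendall tau-b undefined for all-tied input")
    return float(stats.kendalltau(xa, ya, variant="b").statistic)


_METHODS = {"pearson": pearson, "spearman": spearman, "kendall": kendall_tau_b}


@dataclass(frozen=True)
class ConcordanceEntry:
    metric_a: str
    metric_b: str
    method: str
    coefficient: float
    n: int


@dataclass(frozen=True)
class ConcordanceReport:
    """Correlation of a reference metric against every other metric."""

    reference: str
    entries: tuple[ConcordanceEntry, ...]

    def coefficient(self, metric: str, method: str) -> float:
        for e in self.entries:
            if e.metric_b == metric and e.method == method:
                return e.coefficient
        raise KeyError(f"no entry for metric={metric!r}, method={method!r}")

    def as_records(self) -> list[dict[str, object]]:
        return [
            {"method": e.method, "metric": e.metric_b, "coefficient": e.coefficient, "n": e.n}
            for e in self.entries
        ]


def _metric_sort_key(name: str) -> tuple[int, str]:
    try:
        return (_METRIC_ORDER.index(name), name)
    except ValueError:
        return (len(_METRIC_ORDER), name)


def concordance_report(
    vectors: Mapping[str, CentralityVector] | Sequence[CentralityVector],
    reference: str,
) -> ConcordanceReport:
    """All three coefficients of the reference metric vs every other one.

    All vectors must cover the same node set; entries are ordered
    dc, bc, cc, evc, katz (then alphabetically for anything else), with
    the three methods pearson, spearman, kendall per metric.
    """
    if not isinstance(vectors, Mapping):
        vectors = {v.metric: v for v in vectors}
    if reference not in vectors:
        raise KeyError(f"reference metric {reference!r} not among {sorted(vectors)}")
    ref = vectors[reference]
    ref_nodes = set(ref.values)
    for name, vec in vectors.items():
        diff = ref_nodes.symmetric_difference(vec.values)
        if diff:
            raise ValueError(f"metric {name!r} node set differs from reference: {sorted(diff)}")
    order = tuple(sorted(ref.values))  # any fixed label order; correlation is order-free
    ref_arr = ref.as_array(order)
    entries: list[ConcordanceEntry] = []
    others = sorted((m for m in vectors if m != reference), key=_metric_sort_key)
    for method in ("pearson", "spearman", "kendall"):
        for name in others:
            coef = _METHODS[method](ref_arr, vectors[name].as_array(order))
            entries.append(ConcordanceEntry(reference, name, method, coef, len(order)))
    return ConcordanceReport(reference, tuple(entries))


@dataclass(frozen=True)
class RankTable:
    """Descending-value node ranks; exact ties share the average rank."""

    rows: tuple[tuple[str, float, float], ...]  # (label, value, rank)

    def rank_of(self, label: str) -> float:
        for lab, _, r in self.rows:
            if lab == label:
                return r
        raise KeyError(label)

    def top(self) -> str:
        return self.rows[0][0]


def rank_nodes(vector: CentralityVector) -> RankTable:
    """Rank nodes by descending metric value (average rank on ties).

    Display order is by rank, breaking exact ties by ascending label.
    """
    labels = sorted(vector.values)
    vals = np.array([vector.values[lab] for lab in labels])
    ranks = stats.rankdata(-vals, method="average")
    rows = sorted(zip(labels, vals, ranks), key=lambda t: (t[2], t[0]))
    return RankTable(tuple((lab, float(v), float(r)) for lab, v, r in rows))
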