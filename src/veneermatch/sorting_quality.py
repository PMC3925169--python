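"""Neighbor-search statistic scoring how well clusters recover sheets.

Each cluster list (specimens ordered by descending membership) is
scanned position by position. For a neighborhood width ``i``, an
indicator function fires when at least one of the next ``i`` entries
after a position shares that position's source sheet. The fraction of
firing positions, as a percentage of the cluster length, is the
cumulative probability of encountering at least one same-sheet neighbor
within width ``i``; sweeping ``i = 1..i_max`` yields a non-decreasing
*neighbor curve* per cluster.

The default window is one-sided (successors only) and truncated at the
list end; truncated positions still count in the denominator. Under
uniform random sheet labels over S sheets this makes the width-1 value
converge to 100/S, the analytic null the benchmarks module reproduces.
A two-sided mode (predecessors and successors) is available and flagged
in output metadata.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DegenerateDataError, DegenerateTestWarning, ParameterError
from .fuzzy_clustering import ClusterList

DEFAULT_I_MAX = 10


@dataclass
class NeighborCurve:
    """Cumulative same-sheet neighbor probabilities for one cluster."""

    cluster_index: int
    widths: np.ndarray
    probabilities: np.ndarray  # percent, aligned with widths
    cluster_length: int
    sheet_counts: dict
    two_sided: bool = False

    def median(self) -> float:
        return float(np.median(self.probabilities))


def _label_sequence(cluster, sheet_map=None) -> list:
    if isinstance(cluster, ClusterList):
        if sheet_map is None:
            raise ParameterError("sheet_map required when passing a ClusterList")
        return [sheet_map[s] for s in cluster.ordered_specimens]
    return list(cluster)


def same_sheet_indicator(
    cluster, sheet_map=None, position: int = 0, width: int = 1,
    two_sided: bool = False,
) -> int:
    """1 iff a same-sheet specimen sits within ``width`` entries after
    ``position`` (and before it, in two-sided mode); else 0.

    The window is truncated at the list boundaries.
    """
    labels = _label_sequence(cluster, sheet_map)
    L = len(labels)
    if not 0 <= position < L:
        raise IndexError(f"position {position} out of range for length {L}")
    if width < 1:
        raise ParameterError("width must be at least 1")
    after = labels[position + 1 : position + 1 + width]
    hit = labels[position] in after
    if two_sided and not hit:
        before = labels[max(0, position - width) : position]
        hit = labels[position] in before
    return int(hit)


def neighbor_curve(
    cluster, sheet_map=None, i_max: int = DEFAULT_I_MAX, two_sided: bool = False,
    cluster_index: int | None = None,
) -> NeighborCurve:
    """Cumulative probability curve over neighborhood widths 1..i_max.

    ``cluster`` is a :class:`ClusterList` (with ``sheet_map``) or a plain
    sequence of sheet labels already in list order. The probability at
    width i is ``100 * (# positions whose indicator fires) / length``.
    """
    labels = _label_sequence(cluster, sheet_map)
    L = len(labels)
    if L < 2:
        raise DegenerateDataError("neighbor curve undefined for singleton cluster")
    if i_max < 1:
        raise ParameterError("i_max must be at least 1")
    codes = pd.factorize(np.asarray(labels, dtype=object))[0]
    success = np.zeros(L, dtype=bool)
    probs = np.empty(i_max)
    for k in range(1, i_max + 1):
        if k < L:
            match = codes[:-k] == codes[k:]
            success[:-k] |= match
            if two_sided:
                success[k:] |= match
        probs[k - 1] = 100.0 * success.sum() / L
    if cluster_index is None:
        cluster_index = cluster.cluster_index if isinstance(cluster, ClusterList) else -1
    return NeighborCurve(
        cluster_index=cluster_index,
        widths=np.arange(1, i_max + 1),
        probabilities=probs,
        cluster_length=L,
        sheet_counts=dict(Counter(labels)),
        two_sided=two_sided,
    )


def experimental_curves(
    cluster_lists, sheet_map, i_max: int = DEFAULT_I_MAX, two_sided: bool = False,
) -> list[NeighborCurve]:
    """Neighbor curves for every non-singleton cluster of a partition."""
    curves = []
    for cl in cluster_lists:
        if len(cl) < 2:
            continue
        curves.append(neighbor_curve(cl, sheet_map, i_max=i_max, two_sided=two_sided))
    return curves


def pooled_curve(curves: list[NeighborCurve]) -> np.ndarray:
    """Length-weighted mean probability curve across clusters (percent)."""
    if not curves:
        raise ParameterError("no curves to pool")
    weights = np.array([c.cluster_length for c in curves], dtype=float)
    probs = np.vstack([c.probabilities for c in curves])
    return (weights @ probs) / weights.sum()


def compare_medians(
    experimental: list[NeighborCurve],
    benchmark: list[NeighborCurve],
    normality_alpha: float = 0.05,
) -> dict:
    """Test whether two groups of curves differ in median probability.

    Each curve is reduced to the median of its probabilities. Normality
    of the pooled within-group residuals is checked with the Lilliefors
    test (statsmodels); if not rejected a one-way ANOVA compares the
    groups, otherwise a Kruskal-Wallis rank test is used as fallback.
    Returns a report dict with the test name, statistic, degrees of
    freedom and p-value.
    """
    if len(experimental) < 2 or len(benchmark) < 2:
        raise ParameterError("need at least 2 curves in each group")
    a = np.array([c.median() for c in experimental])
    b = np.array([c.median() for c in benchmark])
    report = {
        "group_medians": {"experimental": a.tolist(), "benchmark": b.tolist()},
        "n": [len(a), len(b)],
    }
    if np.ptp(np.concatenate([a, b])) == 0:
        warnings.warn(
            "all median probabilities identical; comparison is degenerate",
            DegenerateTestWarning,
            stacklevel=2,
        )
        report.update(test="degenerate", statistic=0.0, df=None, p=1.0)
        return report

    residuals = np.concatenate([a - a.mean(), b - b.mean()])
    normal = True
    lilliefors_p = None
    if np.ptp(residuals) > 0 and len(residuals) >= 4:
        from statsmodels.stats.diagnostic import lilliefors

        _, lilliefors_p = lilliefors(residuals, dist="norm")
        normal = lilliefors_p >= normality_alpha
    report["lilliefors_p"] = lilliefors_p
    report["normal"] = bool(normal)
    if normal:
        stat, p = stats.f_oneway(a, b)
        report.update(
            test="one-way ANOVA",
            statistic=float(stat),
            df=[1, len(a) + len(b) - 2],
            p=float(p),
        )
    else:
        stat, p = stats.kruskal(a, b)
        report.update(test="Kruskal-Wallis", statistic=float(stat), df=[1], p=float(p))
    return report


def curves_frame(curves: list[NeighborCurve], kind: str = "experimental") -> pd.DataFrame:
    """Tidy table of curves: cluster, width, probability_pct, metadata."""
    rows = []
    for c in curves:
        for w, p in zip(c.widths, c.probabilities):
            rows.append(
                {
                    "kind": kind,
                    "cluster": c.cluster_index,
                    "width": int(w),
                    "probability_pct": p,
                    "cluster_length": c.cluster_length,
                    "two_sided": c.two_sided,
                }
            )
    return pd.DataFrame(rows)
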