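"""Ensemble statistics over independent MD simulations.

Snapshots within one 10-ns simulation are correlated, so construct-level
hypothesis tests treat the mean (or median) of each independent simulation
as a single data point and compare constructs with the Wilcoxon rank-sum
test.  Distribution views pool every snapshot from all simulations of a
construct with equal weight into one histogram annotated with its median
and, optionally, the value observed in the starting crystal structure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .traj_metrics import MetricSeries

#: combined sample size at or below which the rank-sum p-value is exact
EXACT_MAX_COMBINED_N = 50


@dataclass
class Histogram:
    """Pooled-snapshot histogram with its median and an optional crystal-
    structure reference value."""

    edges: np.ndarray
    counts: np.ndarray
    density: np.ndarray  # per-bin probability; sums to 1
    median: float
    n_pooled: int
    reference_value: float | None = None

    def __post_init__(self):
        self.edges = np.asarray(self.edges, dtype=float)
        self.counts = np.asarray(self.counts, dtype=int)
        self.density = np.asarray(self.density, dtype=float)
        if int(self.counts.sum()) != self.n_pooled:
            raise ValueError("histogram counts must sum to the pooled total")


@dataclass
class GroupComparison:
    """Per-simulation summaries of two constructs with the rank-sum result."""

    labels: tuple[str, str]
    summaries_a: np.ndarray
    summaries_b: np.ndarray
    statistic: float
    p_value: float
    method: str  # 'exact' | 'normal-approximation'


def _pool(series: list[MetricSeries]) -> np.ndarray:
    if not series:
        raise ValueError("at least one series required")
    return np.concatenate([np.asarray(s.values, dtype=float) for s in series])


def pooled_histogram(series: list[MetricSeries],
                     n_bins: int | None = None,
                     bin_width: float | None = None,
                     reference_value: float | None = None) -> Histogram:
    """Histogram of all snapshots pooled with equal weight.

    Bin width defaults to the Freedman–Diaconis rule on the pooled values
    (falling back to a single bin for constant data); either ``n_bins`` or
    ``bin_width`` overrides it.  The recorded median is the median of the
    pooled values, and the reference overlay is stored untouched.
    """
    values = _pool(series)
    lo, hi = float(values.min()), float(values.max())
    if bin_width is not None:
        if bin_width <= 0:
            raise ValueError("bin_width must be positive")
        edges = np.arange(lo, hi + bin_width, bin_width)
        if len(edges) < 2:
            edges = np.array([lo, lo + bin_width])
    elif n_bins is not None:
        edges = np.linspace(lo, hi if hi > lo else lo + 1.0, n_bins + 1)
    else:
        iqr = np.subtract(*np.percentile(values, [75, 25]))
        if iqr > 0:
            fd = 2.0 * iqr / len(values) ** (1.0 / 3.0)
            edges = np.arange(lo, hi + fd, fd)
        else:
            edges = np.array([lo, hi if hi > lo else lo + 1.0])
    counts, edges = np.histogram(values, bins=edges)
    return Histogram(edges=edges, counts=counts,
                     density=counts / counts.sum(),
                     median=float(np.median(values)),
                     n_pooled=len(values), reference_value=reference_value)


def per_simulation_summary(series: list[MetricSeries],
                           statistic: str = "mean") -> np.ndarray:
    """One scalar per independent simulation, order preserved."""
    if statistic == "mean":
        fn = np.mean
    elif statistic == "median":
        fn = np.median
    else:
        raise ValueError(f"unknown statistic {statistic!r}")
    return np.array([float(fn(s.values)) for s in series])


def wilcoxon_rank_sum(a, b, labels: tuple[str, str] = ("A", "B")) -> GroupComparison:
    """Two-sided Wilcoxon rank-sum (Mann–Whitney) comparison of two groups.

    The p-value is exact when the combined sample size is at most 50 and the
    data are tie-free; otherwise the normal approximation with tie and
    continuity corrections is used (the approximation is what applies at the
    study's two groups of 32 simulations).  Identical pooled values give
    p = 1 with a warning.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        warnings.warn("all values identical across both groups; p = 1",
                      stacklevel=2)
        u = len(a) * len(b) / 2.0
        return GroupComparison(labels, a, b, u, 1.0, "degenerate")
    has_ties = len(np.unique(pooled)) < len(pooled)
    if len(pooled) <= EXACT_MAX_COMBINED_N and not has_ties:
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        method = "exact"
    else:
        res = stats.mannwhitneyu(a, b, alternative="two-sided",
                                 method="asymptotic", use_continuity=True)
        method = "normal-approximation"
    return GroupComparison(labels, a, b, float(res.statistic),
                           float(res.pvalue), method)


def compare_constructs(series_a: list[MetricSeries], series_b: list[MetricSeries],
                       statistic: str = "mean",
                       labels: tuple[str, str] = ("A", "B")) -> GroupComparison:
    """Per-simulation summaries of each construct, then rank-sum comparison."""
    return wilcoxon_rank_sum(per_simulation_summary(series_a, statistic),
                             per_simulation_summary(series_b, statistic),
                             labels=labels)


def fraction_at_least(series: list[MetricSeries], threshold: float) -> float:
    """Fraction of pooled snapshots with value >= threshold (inclusive)."""
    values = _pool(series)
    return float(np.mean(values >= threshold))
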