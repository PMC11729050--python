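"""Cohort-level descriptive and inferential statistics.

Conventions: two-sided Student-t confidence intervals for means; Pearson
chi-square without continuity correction for contingency tables; Mann-Whitney
U with full midrank enumeration for small samples (both n <= 8) and the
tie-corrected normal approximation otherwise.  No multiple-testing
correction is applied.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .panel import CohortRecord
from .patterns import SampleResult

__all__ = [
    "SummaryInterval",
    "ContingencyTable",
    "t_confidence_interval",
    "chi_square_independence",
    "mann_whitney_u",
    "pattern_lineage_summary",
    "CohortSummary",
]


@dataclass(frozen=True)
class SummaryInterval:
    mean: float
    sd: float
    n: int
    level: float
    lower: float
    upper: float

    @property
    def rounded(self) -> tuple[float, float]:
        return (round(self.lower, 2), round(self.upper, 2))


def t_confidence_interval(
    mean: float, sd: float, n: int, level: float = 0.95
) -> SummaryInterval:
    """Two-sided Student-t interval for a mean from (mean, sd, n)."""
    if n < 2:
        raise ValueError("need n >= 2 for a t interval")
    if sd < 0:
        raise ValueError("sd must be non-negative")
    tcrit = sps.t.ppf(1 - (1 - level) / 2, df=n - 1)
    half = tcrit * sd / math.sqrt(n)
    return SummaryInterval(mean, sd, n, level, mean - half, mean + half)


@dataclass(frozen=True)
class ContingencyTable:
    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...]
    counts: tuple[tuple[int, ...], ...]

    def __post_init__(self) -> None:
        if not self.row_labels or not self.col_labels:
            raise ValueError("labels must be non-empty")
        if len(self.counts) != len(self.row_labels) or any(
            len(r) != len(self.col_labels) for r in self.counts
        ):
            raise ValueError("counts dimensions inconsistent with labels")
        if any(c < 0 for row in self.counts for c in row):
            raise ValueError("counts must be non-negative")
        if self.total == 0:
            raise ValueError("empty table")

    @property
    def total(self) -> int:
        return sum(c for row in self.counts for c in row)

    def to_array(self) -> np.ndarray:
        return np.asarray(self.counts, dtype=float)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.to_array().astype(int),
            index=list(self.row_labels),
            columns=list(self.col_labels),
        )


def chi_square_independence(table: ContingencyTable) -> tuple[float, int, float]:
    """Pearson chi-square test of independence (no continuity correction)."""
    arr = table.to_array()
    if (arr.sum(axis=1) == 0).any() or (arr.sum(axis=0) == 0).any():
        raise ValueError("table has an all-zero row or column")
    expected = np.outer(arr.sum(axis=1), arr.sum(axis=0)) / arr.sum()
    if (expected < 5).any():
        warnings.warn(
            "some expected counts are below 5; the chi-square "
            "approximation may be poor",
            stacklevel=2,
        )
    stat, p, df, _ = sps.chi2_contingency(arr, correction=False)
    return float(stat), int(df), float(p)


def _u_statistic(x_ranksum: float, n1: int) -> float:
    return x_ranksum - n1 * (n1 + 1) / 2.0


def mann_whitney_u(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-tailed Mann-Whitney U test; returns (U of x, p).

    Both samples of size <= 8: exact two-tailed p by full enumeration of all
    label assignments with midranks (correct under ties).  Larger samples:
    tie-corrected normal approximation.
    """
    x = list(map(float, x))
    y = list(map(float, y))
    if not x or not y:
        raise ValueError("both samples must be non-empty")
    n1, n2 = len(x), len(y)
    pooled = np.array(x + y)
    ranks = sps.rankdata(pooled)
    u_obs = _u_statistic(float(ranks[:n1].sum()), n1)
    if n1 <= 8 and n2 <= 8:
        mu = n1 * n2 / 2.0
        dev_obs = abs(u_obs - mu)
        hits = total = 0
        for idx in combinations(range(n1 + n2), n1):
            u = _u_statistic(float(ranks[list(idx)].sum()), n1)
            total += 1
            if abs(u - mu) >= dev_obs - 1e-12:
                hits += 1
        return u_obs, hits / total
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(res.pvalue)


@dataclass(frozen=True)
class CohortSummary:
    """Pattern x group contingency table with per-group arm-count summaries."""

    table: ContingencyTable
    intervals: dict[str, SummaryInterval | None] = field(default_factory=dict)
    percent_altered: float = 0.0
    percent_altered_by_group: dict[str, float] = field(default_factory=dict)
    n_pattern1: int = 0
    n_altered: int = 0


def pattern_lineage_summary(
    results: Sequence[SampleResult],
    annotations: Sequence[CohortRecord],
    group_field: str = "lineage",
) -> CohortSummary:
    """Tabulate pattern classes against a grouping annotation.

    Returns pattern x group counts, per-group mean/SD/95% CI of altered-arm
    counts (absent when n < 2), and the percentage of altered samples
    (Patterns 2-4) overall and per group.  Percentages are reported at one
    decimal; intervals at two.
    """
    ann_by_id = {a.sample_id: a for a in annotations}
    unmatched = [r.sample_id for r in results if r.sample_id not in ann_by_id]
    if unmatched:
        raise ValueError(f"results without annotations: {unmatched[:5]}")
    groups = sorted({getattr(ann_by_id[r.sample_id], group_field) for r in results})
    patterns = [1, 2, 3, 4]
    counts = [
        [
            sum(
                1
                for r in results
                if r.pattern == p
                and getattr(ann_by_id[r.sample_id], group_field) == g
            )
            for g in groups
        ]
        for p in patterns
    ]
    table = ContingencyTable(
        tuple(f"pattern_{p}" for p in patterns),
        tuple(groups),
        tuple(tuple(row) for row in counts),
    )
    intervals: dict[str, SummaryInterval | None] = {}
    percent_by_group: dict[str, float] = {}
    for g in groups:
        arm_counts = [
            r.altered_arms
            for r in results
            if getattr(ann_by_id[r.sample_id], group_field) == g
        ]
        altered = sum(1 for r in results
                      if getattr(ann_by_id[r.sample_id], group_field) == g
                      and r.pattern != 1)
        percent_by_group[g] = round(100.0 * altered / len(arm_counts), 1)
        if len(arm_counts) >= 2:
            mean = float(np.mean(arm_counts))
            sd = float(np.std(arm_counts, ddof=1))
            intervals[g] = t_confidence_interval(mean, sd, len(arm_counts))
        else:
            intervals[g] = None
    n_altered = sum(1 for r in results if r.pattern != 1)
    return CohortSummary(
        table=table,
        intervals=intervals,
        percent_altered=round(100.0 * n_altered / len(results), 1),
        percent_altered_by_group=percent_by_group,
        n_pattern1=sum(1 for r in results if r.pattern == 1),
        n_altered=n_altered,
    )
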