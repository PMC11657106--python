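"""Descriptive statistics and group comparisons over a cohort table.

The cohort table is the DataFrame produced by
:func:`hrdscore.classify.build_cohort`. Percentages are rounded
half-away-from-zero to one decimal, matching how clinical reports print
them. Quartiles use linear interpolation between order statistics by
default; the convention is configurable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GroupSummary",
    "median_iqr",
    "compare_groups",
    "percent",
    "crosstab",
    "subgroup_report",
    "gis_histogram",
]

SIGNIFICANCE_LEVEL = 0.05


@dataclass(frozen=True)
class GroupSummary:
    group: str
    n: int
    n_valid: int
    median: Optional[float]
    q1: Optional[float]
    q3: Optional[float]
    prop_above_cutoff: Optional[float]


def median_iqr(
    values: Sequence[float], method: str = "linear"
) -> tuple[float, float, float]:
    """(median, Q1, Q3) of a non-empty list.

    ``method`` is any quantile convention accepted by :func:`numpy.quantile`.
    """
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("median_iqr of empty list")
    q1, med, q3 = np.quantile(arr, [0.25, 0.5, 0.75], method=method)
    return float(med), float(q1), float(q3)


def compare_groups(
    a: Sequence[float],
    b: Sequence[float],
    welch: bool = False,
    alpha: float = SIGNIFICANCE_LEVEL,
) -> tuple[float, float, bool]:
    """Two-sample t-test: (t, two-sided p, significant at ``alpha``).

    Pooled-variance Student's test by default; ``welch=True`` drops the
    equal-variance assumption. Fully degenerate input (zero variance in both
    groups with equal means) yields t = 0, p = 1.
    """
    a = np.asarray(list(a), dtype=float)
    b = np.asarray(list(b), dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    with warnings.catch_warnings():
        # near-constant input warns before we handle the degenerate case
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(a, b, equal_var=not welch)
    t, p = float(res.statistic), float(res.pvalue)
    if np.isnan(t):  # zero variance in both groups
        if np.isclose(a.mean(), b.mean()):
            t, p = 0.0, 1.0
        else:
            t, p = np.inf if a.mean() > b.mean() else -np.inf, 0.0
    return t, p, p < alpha


def percent(numerator: int, denominator: int) -> float:
    """100 * num / den, rounded half-away-from-zero to one decimal."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    value = Decimal(100) * Decimal(numerator) / Decimal(denominator)
    return float(value.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class Crosstab:
    counts: pd.DataFrame      # with All margins
    row_pct: pd.DataFrame     # % within each row
    col_pct: pd.DataFrame     # % within each column

    @property
    def n(self) -> int:
        return int(self.counts.loc["All", "All"])


def crosstab(cohort: pd.DataFrame, row_axis: str, col_axis: str) -> Crosstab:
    """Contingency table of two cohort columns with marginals and within-row
    / within-column percentages."""
    for axis in (row_axis, col_axis):
        if axis not in cohort.columns:
            raise KeyError(f"unknown axis {axis!r}")
    counts = pd.crosstab(
        cohort[row_axis], cohort[col_axis], margins=True, margins_name="All"
    )
    core = counts.drop(index="All", columns="All")
    row_pct = core.div(core.sum(axis=1), axis=0) * 100
    col_pct = core.div(core.sum(axis=0), axis=1) * 100
    return Crosstab(counts=counts, row_pct=row_pct, col_pct=col_pct)


def _summary(level: str, sub: pd.DataFrame, cutoff: float) -> GroupSummary:
    valid = sub[sub["valid"].astype(bool)]
    gis_vals = valid["gis"].astype(float)
    if len(valid):
        med, q1, q3 = median_iqr(gis_vals)
        prop = float((gis_vals >= cutoff).mean())
    else:
        med = q1 = q3 = prop = None
    return GroupSummary(
        group=level,
        n=len(sub),
        n_valid=len(valid),
        median=med,
        q1=q1,
        q3=q3,
        prop_above_cutoff=prop,
    )


def subgroup_report(
    cohort: pd.DataFrame,
    axis: str,
    cutoff: float = 42,
    min_n: int = 1,
) -> list[GroupSummary]:
    """Per-level GIS summaries along one cohort column, ordered by n
    descending; levels with fewer than ``min_n`` samples pool into "other".
    """
    if axis not in cohort.columns:
        raise KeyError(f"unknown axis {axis!r}")
    sizes = cohort[axis].value_counts()
    small = set(sizes[sizes < min_n].index)
    labels = cohort[axis].where(~cohort[axis].isin(small), "other")
    out = [
        _summary(str(level), cohort[labels == level], cutoff)
        for level in labels.value_counts().index
    ]
    out.sort(key=lambda s: (-s.n, s.group))
    return out


def gis_histogram(
    cohort: pd.DataFrame, bin_width: int = 2, upper: int = 100
) -> pd.DataFrame:
    """Plot-ready histogram table of valid GIS values (default width-2 bins
    over 0-100)."""
    valid = cohort[cohort["valid"].astype(bool)]
    edges = np.arange(0, upper + bin_width, bin_width)
    counts, _ = np.histogram(valid["gis"].astype(float), bins=edges)
    return pd.DataFrame(
        {"bin_start": edges[:-1], "bin_end": edges[1:], "count": counts}
    )
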