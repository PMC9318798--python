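"""Age trends and within-age outliers for serum concentration panels.

The trend statistic is deliberately simple, matching common practice for
sparse age-binned biomonitoring data: the per-month *median* concentration
is computed for each completed month of age (0-11), and an unweighted
ordinary least-squares line of median on month index summarises change over
infancy.  A slope near zero (|slope| < 0.1 ng/mL per month by default) is
read as "flat" -- serum concentration roughly constant over the first year
despite rapid growth in body mass.

Outliers are flagged within an age group: a value more than ``z_threshold``
sample standard deviations (n-1 denominator) from its group mean.
"""
from __future__ import annotations

import logging
import statistics
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import CohortTable

__all__ = [
    "AgeSeries",
    "TrendFit",
    "OutlierReport",
    "group_median",
    "group_stats",
    "build_age_series",
    "ols_fit",
    "classify_flatness",
    "flag_outliers",
    "trend_table",
]

logger = logging.getLogger(__name__)

MONTHS = tuple(range(12))


@dataclass(frozen=True)
class AgeSeries:
    """Per-month median concentrations for one analyte."""

    analyte: str
    months: tuple[int, ...]
    medians: tuple[float, ...]
    counts: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.months) != len(self.medians) or len(self.months) != len(self.counts):
            raise ValueError("months, medians and counts must be parallel")
        if any(b <= a for a, b in zip(self.months, self.months[1:])):
            raise ValueError("months must be strictly increasing")
        if any(c < 1 for c in self.counts):
            raise ValueError("every reported month needs at least one observation")


@dataclass(frozen=True)
class TrendFit:
    """Least-squares line of per-month medians on age (month index)."""

    analyte: str
    slope: float      # ng/mL per month
    intercept: float  # ng/mL at month 0
    n_points: int

    def predict(self, month: float) -> float:
        return self.intercept + self.slope * month


@dataclass(frozen=True)
class OutlierReport:
    """Values more than ``threshold`` group SDs from their age-group mean."""

    analyte: str
    age_months: int
    group_mean: float
    group_sd: float
    threshold: float
    flagged: tuple[tuple[float, float], ...] = field(default=())  # (value, z)


def group_median(values: Sequence[float]) -> float:
    """Middle sorted value; even-sized groups average the middle pair."""
    if len(values) == 0:
        raise ValueError("cannot take the median of an empty group")
    return float(statistics.median(values))


def group_stats(values: Sequence[float]) -> tuple[float, float]:
    """Arithmetic mean and sample (n-1) standard deviation."""
    if len(values) < 2:
        raise ValueError("sample standard deviation needs at least 2 values")
    return float(statistics.mean(values)), float(statistics.stdev(values))


def build_age_series(
    table: CohortTable,
    analyte: str,
    median_overrides: Mapping[int, float] | None = None,
) -> AgeSeries:
    """Per-month medians (and counts) for one analyte.

    ``median_overrides`` maps month -> authoritative median for months whose
    individual values are known to be unreliable (used with the packaged
    cohort, whose provenance documents two such columns).
    """
    recs = table.subset(analyte)
    by_month: dict[int, list[float]] = {}
    for r in recs:
        by_month.setdefault(r.age_months, []).append(r.value)
    if len(by_month) < 2:
        raise ValueError(
            f"{analyte}: need records in at least 2 distinct months, have {len(by_month)}"
        )
    months = tuple(sorted(by_month))
    overrides = dict(median_overrides or {})
    medians = tuple(
        float(overrides[m]) if m in overrides else group_median(by_month[m])
        for m in months
    )
    counts = tuple(len(by_month[m]) for m in months)
    return AgeSeries(analyte=analyte, months=months, medians=medians, counts=counts)


def ols_fit(series: AgeSeries) -> TrendFit:
    """Unweighted least squares of median concentration on month index."""
    if len(series.months) < 2:
        raise ValueError("OLS needs at least 2 populated months")
    slope, intercept = np.polyfit(series.months, series.medians, deg=1)
    return TrendFit(
        analyte=series.analyte,
        slope=float(slope),
        intercept=float(intercept),
        n_points=len(series.months),
    )


def classify_flatness(fit: TrendFit, threshold: float = 0.1) -> str:
    """Label a trend ``flat`` when |slope| < threshold (ng/mL per month),
    otherwise ``increasing``/``declining`` by sign; the boundary is not flat."""
    if threshold <= 0:
        raise ValueError("flatness threshold must be > 0")
    if abs(fit.slope) < threshold:
        return "flat"
    return "increasing" if fit.slope > 0 else "declining"


def flag_outliers(
    table: CohortTable,
    analyte: str,
    z_threshold: float = 3.0,
    scope: str = "age_group",
    min_group: int = 3,
) -> list[OutlierReport]:
    """Flag values more than ``z_threshold`` sample SDs from the group mean.

    ``scope='age_group'`` evaluates each month separately; ``'pooled'``
    treats all records of the analyte as one group.  Groups smaller than
    ``min_group`` are skipped with a log notice (too few values for a
    meaningful SD), never an error.
    """
    if scope not in ("age_group", "pooled"):
        raise ValueError(f"scope must be 'age_group' or 'pooled', got {scope!r}")
    recs = table.subset(analyte)
    groups: dict[int, list[float]] = {}
    if scope == "pooled":
        groups[-1] = [r.value for r in recs]
    else:
        for r in recs:
            groups.setdefault(r.age_months, []).append(r.value)
    reports = []
    for month in sorted(groups):
        values = groups[month]
        if len(values) < min_group:
            logger.info(
                "%s month %s: skipped (only %d values, need %d)",
                analyte, month, len(values), min_group,
            )
            continue
        mean, sd = group_stats(values)
        flagged: list[tuple[float, float]] = []
        if sd > 0:
            flagged = [
                (v, (v - mean) / sd) for v in values if abs(v - mean) / sd > z_threshold
            ]
        reports.append(
            OutlierReport(
                analyte=analyte,
                age_months=month,
                group_mean=mean,
                group_sd=sd,
                threshold=z_threshold,
                flagged=tuple(flagged),
            )
        )
    return reports


def trend_table(
    table: CohortTable,
    analytes: Sequence[str],
    median_overrides: Mapping[str, Mapping[int, float]] | None = None,
) -> pd.DataFrame:
    """Per-month medians, counts, slope and intercept for several analytes.

    Layout mirrors the conventional summary: one column per analyte, rows
    ``median_m<month>``, ``n_m<month>``, then ``slope`` and ``intercept``.
    """
    overrides = median_overrides or {}
    columns = {}
    for analyte in analytes:
        series = build_age_series(table, analyte, overrides.get(analyte))
        fit = ols_fit(series)
        col: dict[str, float] = {}
        for m, med, n in zip(series.months, series.medians, series.counts):
            col[f"median_m{m}"] = med
            col[f"n_m{m}"] = n
        col["slope"] = fit.slope
        col["intercept"] = fit.intercept
        columns[analyte] = col
    return pd.DataFrame(columns)
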