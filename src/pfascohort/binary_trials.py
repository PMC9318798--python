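"""Small-sample detection-prevalence estimation from binary trials.

Each assayed infant is a binary trial: serum concentration above the LOD
(detect) or below it (non-detect).  With k detects out of n tested and a
uniform prior on the population detection probability p, the posterior is
Beta(k+1, n-k+1), giving the rule-of-succession point estimate

    E[p | k, n] = (k + 1) / (n + 2)

and posterior standard deviation sqrt[(k+1)(n-k+1) / ((n+2)^2 (n+3))].
Two-sided intervals use the normal approximation point +/- z * sd, clipped
to [0, 1].

For a sample in which *every* infant tested positive, the detection
probability consistent with the all-positive outcome at even odds solves
p^n = 1/2, i.e. p = 0.5^(1/n); the tail analogues alpha^(1/n) and
(1-alpha)^(1/n) bound it at confidence level 1 - 2*alpha.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import DetectionCount

__all__ = [
    "DetectionEstimate",
    "AllPositiveEstimate",
    "posterior_mean",
    "posterior_sd",
    "detection_interval",
    "all_positive_median",
    "all_positive_interval",
    "expected_percent_table",
    "render_percent",
    "grid_posterior_summary",
    "grid_all_positive_root",
]


@dataclass(frozen=True)
class DetectionEstimate:
    """Posterior summary of a population detection probability."""

    analyte: str
    point: float
    sd: float
    ci_low: float
    ci_high: float
    level: float
    k: int | None = None
    n: int | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.ci_low <= self.point <= self.ci_high <= 1):
            raise ValueError(
                f"{self.analyte}: interval must satisfy 0 <= low <= point <= high <= 1"
            )
        if self.sd < 0:
            raise ValueError("posterior sd must be >= 0")


@dataclass(frozen=True)
class AllPositiveEstimate:
    """Even-odds detection probability and tail interval for an all-positive sample."""

    n: int
    p_median: float
    ci_low: float
    ci_high: float
    level: float

    def __post_init__(self) -> None:
        if not (0 < self.ci_low < self.p_median < self.ci_high < 1):
            raise ValueError("endpoints must strictly bracket p_median inside (0, 1)")


def _check_kn(k: int, n: int) -> None:
    if k < 0 or n < 0 or k > n:
        raise ValueError(f"need 0 <= k <= n, got k={k}, n={n}")


def posterior_mean(k: int, n: int) -> float:
    """Rule-of-succession estimate (k+1)/(n+2) of the detection probability."""
    _check_kn(k, n)
    return (k + 1) / (n + 2)


def posterior_sd(k: int, n: int) -> float:
    """Posterior standard deviation of p under the uniform prior."""
    _check_kn(k, n)
    a, b = k + 1, n - k + 1
    return math.sqrt(a * b / ((n + 2) ** 2 * (n + 3)))


def detection_interval(
    k: int, n: int, level: float = 0.90, analyte: str = ""
) -> DetectionEstimate:
    """Normal-approximation posterior interval, clipped to [0, 1].

    At the default 90% level the multiplier is the familiar z = 1.645.
    """
    if not 0 < level < 1:
        raise ValueError(f"level must be in (0, 1), got {level}")
    point = posterior_mean(k, n)
    sd = posterior_sd(k, n)
    z = stats.norm.ppf(0.5 + level / 2)
    lo = max(0.0, point - z * sd)
    hi = min(1.0, point + z * sd)
    return DetectionEstimate(
        analyte=analyte, point=point, sd=sd, ci_low=lo, ci_high=hi,
        level=level, k=k, n=n,
    )


def all_positive_median(n: int) -> float:
    """p with even odds of an all-positive sample of size n: 0.5**(1/n)."""
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    return 0.5 ** (1 / n)


def all_positive_interval(n: int, level: float = 0.90) -> AllPositiveEstimate:
    """Tail-probability interval (alpha^(1/n), (1-alpha)^(1/n)) around the
    even-odds probability, with alpha = (1 - level)/2."""
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if not 0 < level < 1:
        raise ValueError(f"level must be in (0, 1), got {level}")
    alpha = (1 - level) / 2
    return AllPositiveEstimate(
        n=n,
        p_median=all_positive_median(n),
        ci_low=alpha ** (1 / n),
        ci_high=(1 - alpha) ** (1 / n),
        level=level,
    )


def render_percent(p: float) -> float:
    """Render a probability as a percent under the reporting convention:
    round half-up to the integer percent, except probabilities below 2.5%
    which keep one decimal (so a 1.94% estimate prints as 1.9, not 2)."""
    pct = Decimal(str(p * 100))
    if p * 100 < 2.5:
        return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))
    return float(pct.quantize(Decimal("1"), rounding=ROUND_HALF_UP))


def expected_percent_table(
    counts: Sequence[DetectionCount], level: float = 0.90
) -> pd.DataFrame:
    """Expected population detection percentages for a panel of count data.

    One row per analyte with full-precision posterior columns plus the
    rendered percent columns (``expected_percent``, ``ci_low_percent``,
    ``ci_high_percent``).
    """
    rows = []
    for c in counts:
        est = detection_interval(c.k, c.n, level=level, analyte=c.analyte)
        rows.append(
            {
                "analyte": c.analyte,
                "n": c.n,
                "k": c.k,
                "expected_percent": render_percent(est.point),
                "ci_low_percent": render_percent(est.ci_low),
                "ci_high_percent": render_percent(est.ci_high),
                "level": level,
                "point_raw": est.point,
                "sd_raw": est.sd,
                "ci_low_raw": est.ci_low,
                "ci_high_raw": est.ci_high,
            }
        )
    columns = [
        "analyte", "n", "k", "expected_percent", "ci_low_percent",
        "ci_high_percent", "level", "point_raw", "sd_raw",
        "ci_low_raw", "ci_high_raw",
    ]
    return pd.DataFrame(rows, columns=columns)


# ---------------------------------------------------------------------------
# Brute-force verification utilities (dense-grid integration / bisection).
# These deliberately avoid the closed forms above so they can serve as an
# independent cross-check in the test suite.

def grid_posterior_summary(k: int, n: int, grid: int = 200_001) -> tuple[float, float]:
    """Posterior mean and sd of p by trapezoidal integration of
    p^k (1-p)^(n-k) on a uniform grid over [0, 1]."""
    _check_kn(k, n)
    p = np.linspace(0.0, 1.0, grid)
    log_dens = np.zeros_like(p)
    with np.errstate(divide="ignore"):
        if k:
            log_dens += k * np.log(p, where=p > 0, out=np.full_like(p, -np.inf))
        if n - k:
            log_dens += (n - k) * np.log1p(-p, where=p < 1, out=np.full_like(p, -np.inf))
    dens = np.exp(log_dens - log_dens.max())
    norm = np.trapezoid(dens, p)
    mean = np.trapezoid(p * dens, p) / norm
    second = np.trapezoid(p * p * dens, p) / norm
    return float(mean), float(math.sqrt(second - mean * mean))


def grid_all_positive_root(n: int, tail: float = 0.5, tol: float = 1e-12) -> float:
    """Solve p^n = tail for p by bisection (no logarithms, no closed form)."""
    if n < 1 or not 0 < tail < 1:
        raise ValueError("need n >= 1 and tail in (0, 1)")
    lo, hi = 0.0, 1.0
    while hi - lo > tol:
        mid = (lo + hi) / 2
        if mid ** n < tail:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2
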