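"""Growth analytics: doubling times, growth-curve regression, comparisons.

The doubling time of a culture over an interval is

    DT = (t1 - t0) * log(2) / (log(N1) - log(N0))

(the base of the logarithm cancels).  A series' doubling time is the
arithmetic mean over consecutive intervals.  Negative values indicate a
shrinking culture and are returned as-is; callers may filter.

Cross-series comparisons use the standard tools: ordinary least squares
for growth-rate slopes, the ANCOVA slope-homogeneity F-test (as in
GraphPad Prism) for slope equality, one-way ANOVA for group means, and
the paired t-test for matched observations.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy import stats as sps

__all__ = [
    "GrowthSeries",
    "RegressionResult",
    "AnovaResult",
    "SlopeComparison",
    "interval_doubling_time",
    "mean_doubling_time",
    "fit_growth_regression",
    "slopes_equal_test",
    "one_way_anova",
    "paired_t_test",
]

LOG2 = math.log(2.0)


@dataclass(frozen=True)
class GrowthSeries:
    """(time, count) observations for one cell line."""

    times_hr: tuple[float, ...]
    counts: tuple[float, ...]
    cell_type: str = ""

    def __post_init__(self):
        t = np.asarray(self.times_hr, dtype=float)
        n = np.asarray(self.counts, dtype=float)
        if t.size != n.size:
            raise ValueError("times and counts must have equal length")
        if t.size and np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(n <= 0):
            raise ValueError("counts must be positive")
        object.__setattr__(self, "times_hr", tuple(float(x) for x in t))
        object.__setattr__(self, "counts", tuple(float(x) for x in n))

    def __len__(self) -> int:
        return len(self.times_hr)


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int
    residual_variance: float
    stderr: float = float("nan")

    def __post_init__(self):
        if not (-1e-12 <= self.r_squared <= 1 + 1e-12):
            raise ValueError("r_squared must lie in [0, 1]")
        if self.n < 3:
            raise ValueError("regression needs n >= 3")


@dataclass(frozen=True)
class AnovaResult:
    f_statistic: float
    df_between: int
    df_within: int
    p_value: float
    group_means: tuple[float, ...]

    def __post_init__(self):
        if self.f_statistic < 0:
            raise ValueError("F must be non-negative")
        if not (0 <= self.p_value <= 1):
            raise ValueError("p-value must lie in [0, 1]")


@dataclass(frozen=True)
class SlopeComparison:
    f_statistic: float
    df_num: int
    df_den: int
    p_value: float
    slope_a: float
    slope_b: float


# ---------------------------------------------------------------------------
# Doubling time


def interval_doubling_time(t0: float, t1: float, n0: float, n1: float) -> float:
    """Doubling time over one interval: (t1-t0)*log2 / (log n1 - log n0).

    Positive for growth, negative for shrinkage.  Equal counts make the
    quantity undefined (division by zero) and raise.
    """
    if t1 <= t0:
        raise ValueError("need t1 > t0")
    if n0 <= 0 or n1 <= 0:
        raise ValueError("counts must be positive")
    if n1 == n0:
        raise ZeroDivisionError("equal counts: doubling time undefined")
    return (t1 - t0) * LOG2 / (math.log(n1) - math.log(n0))


def mean_doubling_time(series: GrowthSeries) -> float:
    """Arithmetic mean of per-interval doubling times over consecutive pairs.

    Degenerate intervals (equal consecutive counts) are excluded with a
    warning; if every interval is degenerate this raises.
    """
    if len(series) < 2:
        raise ValueError("need at least two time points")
    dts = []
    for (t0, t1, n0, n1) in zip(
        series.times_hr[:-1], series.times_hr[1:], series.counts[:-1], series.counts[1:]
    ):
        if n1 == n0:
            warnings.warn(
                f"degenerate interval [{t0}, {t1}] hr (equal counts) excluded",
                stacklevel=2,
            )
            continue
        dts.append(interval_doubling_time(t0, t1, n0, n1))
    if not dts:
        raise ValueError("all intervals degenerate; doubling time undefined")
    return float(np.mean(dts))


# ---------------------------------------------------------------------------
# Regression and comparisons


def fit_growth_regression(
    series: GrowthSeries,
    count_scale: float = 1000.0,
    log_counts: bool = False,
) -> RegressionResult:
    """Ordinary least squares of cell count on time.

    Counts are divided by ``count_scale`` (default: thousands, the usual
    growth-curve axis convention) before fitting; set ``log_counts`` to
    fit log2 counts instead, the natural scale for exponential growth.
    """
    if len(series) < 3:
        raise ValueError("regression needs at least 3 points")
    t = np.asarray(series.times_hr)
    y = np.asarray(series.counts) / count_scale
    if log_counts:
        y = np.log2(y)
    res = sps.linregress(t, y)
    resid = y - (res.slope * t + res.intercept)
    n = len(series)
    ssy = float(np.sum((y - y.mean()) ** 2))
    r2 = 0.0 if ssy == 0 else float(res.rvalue**2)
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=r2,
        p_value=float(res.pvalue) if ssy > 0 else 1.0,
        n=n,
        residual_variance=float(np.sum(resid**2) / (n - 2)),
        stderr=float(res.stderr),
    )


def _series_arrays(obj) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(obj, GrowthSeries):
        return np.asarray(obj.times_hr, float), np.asarray(obj.counts, float)
    t, y = obj
    return np.asarray(t, float), np.asarray(y, float)


def slopes_equal_test(a, b, count_scale: float = 1.0) -> SlopeComparison:
    """ANCOVA slope-homogeneity F-test between two (time, count) datasets.

    Fits a full model with separate slopes and intercepts per dataset and
    a reduced model forcing a common slope, then compares residual sums
    of squares with an F(1, n-4) test — the test GraphPad Prism reports
    when asking "are the slopes significantly different?".
    """
    ta, ya = _series_arrays(a)
    tb, yb = _series_arrays(b)
    ya = ya / count_scale
    yb = yb / count_scale
    if np.ptp(ta) == 0 or np.ptp(tb) == 0:
        raise ValueError("degenerate design: all times identical within a series")
    t = np.concatenate([ta, tb])
    y = np.concatenate([ya, yb])
    g = np.concatenate([np.zeros(ta.size), np.ones(tb.size)])
    x_full = np.column_stack([np.ones_like(t), g, t, g * t])
    x_red = x_full[:, :3]
    fit_full = sm.OLS(y, x_full).fit()
    fit_red = sm.OLS(y, x_red).fit()
    df_den = int(t.size - 4)
    if df_den <= 0:
        raise ValueError("not enough points for the slope comparison")
    ssr_full = float(fit_full.ssr)
    ssr_red = float(fit_red.ssr)
    if ssr_full <= 0:
        # perfectly fitting full model: either exact common slope (F=0)
        # or exact separation (F -> inf)
        if ssr_red <= 1e-12 * max(1.0, float(np.sum(y**2))):
            f_stat, p = 0.0, 1.0
        else:
            f_stat, p = float("inf"), 0.0
    else:
        f_stat = (ssr_red - ssr_full) / (ssr_full / df_den)
        f_stat = max(0.0, float(f_stat))
        p = float(sps.f.sf(f_stat, 1, df_den))
    return SlopeComparison(
        f_statistic=f_stat,
        df_num=1,
        df_den=df_den,
        p_value=p,
        slope_a=float(fit_full.params[2]),
        slope_b=float(fit_full.params[2] + fit_full.params[3]),
    )


def one_way_anova(groups: list) -> AnovaResult:
    """Classical one-way ANOVA across two or more groups of observations.

    Degenerate input with zero within-group variance but differing means
    reports F = inf, p = 0 explicitly; identical constant groups give
    F = 0, p = 1.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need at least 2 groups")
    if any(a.size < 2 for a in arrays):
        raise ValueError("each group needs at least 2 values")
    k = len(arrays)
    n = sum(a.size for a in arrays)
    grand = np.concatenate(arrays).mean()
    ssb = sum(a.size * (a.mean() - grand) ** 2 for a in arrays)
    ssw = sum(float(np.sum((a - a.mean()) ** 2)) for a in arrays)
    df_b, df_w = k - 1, n - k
    means = tuple(float(a.mean()) for a in arrays)
    if ssw == 0:
        if ssb == 0:
            return AnovaResult(0.0, df_b, df_w, 1.0, means)
        return AnovaResult(float("inf"), df_b, df_w, 0.0, means)
    f_stat, p = sps.f_oneway(*arrays)
    return AnovaResult(float(f_stat), df_b, df_w, float(p), means)


def paired_t_test(x, y) -> tuple[float, float]:
    """Paired t-test: one-sample t on the element-wise differences.

    Swapping x and y negates t and leaves p unchanged.  Zero-variance
    differences are handled explicitly: identical samples give
    (t=0, p=1); a constant non-zero shift gives (t=+-inf, p=0).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D of equal length")
    if x.size < 2:
        raise ValueError("need at least 2 pairs")
    d = x - y
    if np.ptp(d) == 0:
        if d[0] == 0:
            return 0.0, 1.0
        return math.copysign(float("inf"), d[0]), 0.0
    res = sps.ttest_rel(x, y)
    return float(res.statistic), float(res.pvalue)
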