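"""Per-pixel linear trend, F-test significance and five-way classification.

The slope is the closed-form least-squares slope against the year index
i = 1..n.  Significance uses the regression F statistic with (1, n-2)
degrees of freedom, equivalent to a two-sided t test on the slope.
Classes combine the slope sign with p-value thresholds 0.01 and 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum

import numpy as np
import pandas as pd
from scipy import stats

from tercab.gridio import AnnualStack, Grid

__all__ = [
    "TrendClass",
    "TrendResult",
    "TrendSummary",
    "pixel_slope",
    "slope_f_test",
    "classify_trend",
    "trend_stack",
    "trend_summary",
]

# Relative tolerance below which residual variance counts as a perfect fit.
_PERFECT_FIT_RTOL = 1e-12


class TrendClass(IntEnum):
    """Five-way trend class; codes are stable raster values."""

    ESD = 1  # extremely significant decrease  (slope < 0, p < 0.01)
    SD = 2   # significant decrease            (slope < 0, 0.01 <= p < 0.05)
    NSC = 3  # no significant change           (p >= 0.05)
    SI = 4   # significant increase            (slope > 0, 0.01 <= p < 0.05)
    ESI = 5  # extremely significant increase  (slope > 0, p < 0.01)


SIGNIFICANT_CLASSES = (TrendClass.ESI, TrendClass.SI, TrendClass.SD, TrendClass.ESD)


def _check_series(series: np.ndarray) -> np.ndarray:
    y = np.asarray(series, dtype=float)
    if y.ndim != 1:
        raise ValueError("series must be 1-D")
    if y.size < 3:
        raise ValueError(f"need at least 3 observations, got {y.size}")
    if np.isnan(y).any():
        raise ValueError("series contains missing values; exclude the pixel instead")
    return y


def pixel_slope(series) -> float:
    """Least-squares slope of a yearly series against i = 1..n.

    Computed from the closed form
    ``(n * sum(i*y) - sum(i) * sum(y)) / (n * sum(i^2) - sum(i)^2)``.
    """
    y = _check_series(series)
    n = y.size
    i = np.arange(1, n + 1, dtype=float)
    num = n * np.sum(i * y) - np.sum(i) * np.sum(y)
    den = n * np.sum(i * i) - np.sum(i) ** 2
    return float(num / den)


def slope_f_test(series) -> tuple[float, float]:
    """Regression F statistic and upper-tail p for the per-pixel trend.

    Degrees of freedom are (1, n-2); F equals the square of the slope's t
    statistic.  A perfect (zero-residual, non-constant) fit returns
    ``(inf, 0.0)``; a constant series returns ``(0.0, 1.0)``.
    """
    y = _check_series(series)
    n = y.size
    i = np.arange(1, n + 1, dtype=float)
    sxx = np.sum((i - i.mean()) ** 2)
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0.0:
        return 0.0, 1.0
    slope = pixel_slope(y)
    ssr = slope * slope * sxx
    sse = max(sst - ssr, 0.0)
    if sse <= _PERFECT_FIT_RTOL * sst:
        return float("inf"), 0.0
    f = ssr / (sse / (n - 2))
    p = float(stats.f.sf(f, 1, n - 2))
    return float(f), p


def classify_trend(slope: float, p: float) -> TrendClass:
    """Map (slope, p) to the five-way class; zero slope is never significant."""
    if p >= 0.05 or slope == 0.0:
        return TrendClass.NSC
    if slope > 0:
        return TrendClass.ESI if p < 0.01 else TrendClass.SI
    return TrendClass.ESD if p < 0.01 else TrendClass.SD


@dataclass
class TrendResult:
    """Per-pixel trend grids: slope, F, p and class code (0 = nodata)."""

    slope: Grid
    f: Grid
    p: Grid
    klass: Grid

    @property
    def valid(self) -> np.ndarray:
        return self.klass.values > 0


def trend_stack(stack: AnnualStack) -> TrendResult:
    """Vectorised per-pixel trend over an annual stack.

    Pixels that are nodata in any year are excluded entirely (class 0).
    """
    if len(stack) < 3:
        raise ValueError("trend analysis needs at least 3 years")
    arr = stack.to_array()
    n = arr.shape[0]
    excluded = stack.combined_mask()
    y = np.where(excluded[None, :, :], 0.0, arr)

    i = np.arange(1, n + 1, dtype=float)[:, None, None]
    iy_sum = np.sum(i * y, axis=0)
    y_sum = np.sum(y, axis=0)
    i_sum = float(np.sum(np.arange(1, n + 1)))
    ii_sum = float(np.sum(np.arange(1, n + 1) ** 2))
    den = n * ii_sum - i_sum ** 2
    slope = (n * iy_sum - i_sum * y_sum) / den

    sxx = den / n  # sum((i - mean(i))^2)
    sst = np.sum((y - y_sum[None] / n) ** 2, axis=0)
    ssr = slope * slope * sxx
    sse = np.maximum(sst - ssr, 0.0)

    with np.errstate(divide="ignore", invalid="ignore"):
        f = ssr / (sse / (n - 2))
    p = np.ones_like(slope)
    const = sst == 0.0
    perfect = ~const & (sse <= _PERFECT_FIT_RTOL * sst)
    regular = ~const & ~perfect
    p[regular] = stats.f.sf(f[regular], 1, n - 2)
    p[perfect] = 0.0
    f[const] = 0.0
    f[perfect] = np.inf
    slope[const] = 0.0

    klass = np.full(slope.shape, 0, dtype=np.int16)
    v = ~excluded
    kl = np.full(slope.shape, int(TrendClass.NSC), dtype=np.int16)
    kl[(slope > 0) & (p < 0.05)] = TrendClass.SI
    kl[(slope > 0) & (p < 0.01)] = TrendClass.ESI
    kl[(slope < 0) & (p < 0.05)] = TrendClass.SD
    kl[(slope < 0) & (p < 0.01)] = TrendClass.ESD
    klass[v] = kl[v]

    slope[excluded] = np.nan
    f[excluded] = np.nan
    p[excluded] = np.nan
    t = stack.template
    return TrendResult(
        slope=t.like(slope),
        f=t.like(f),
        p=t.like(p),
        klass=t.like(klass, nodata=0),
    )


@dataclass
class TrendSummary:
    """Area (km^2) and proportion (%) per trend class on the valid mask."""

    table: pd.DataFrame  # index: class abbreviation; columns: area_km2, proportion_pct

    @property
    def significant_area_km2(self) -> float:
        names = [c.name for c in SIGNIFICANT_CLASSES]
        return float(self.table.loc[names, "area_km2"].sum())

    @property
    def total_area_km2(self) -> float:
        return float(self.table["area_km2"].sum())

    @classmethod
    def from_areas(cls, areas) -> "TrendSummary":
        """Build a summary from per-class areas (e.g. a published table)."""
        areas = pd.Series(areas, dtype=float)
        order = [c.name for c in TrendClass]
        areas = areas.reindex(order).fillna(0.0)
        total = areas.sum()
        prop = areas / total * 100.0 if total > 0 else areas * 0.0
        return cls(pd.DataFrame({"area_km2": areas, "proportion_pct": prop}))


def trend_summary(klass: Grid, pixel_area_km2: float) -> TrendSummary:
    """Tabulate class areas and percentages from a classified grid."""
    codes = klass.values
    areas = {}
    for c in TrendClass:
        areas[c.name] = float(np.count_nonzero(codes == c.value)) * pixel_area_km2
    return TrendSummary.from_areas(areas)
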