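"""Pearson and partial correlation between carbon balance and climate.

Per pixel, the partial correlation between the response and one climate
variable controls for the other; significance uses a two-sided t test with
n - m - 1 degrees of freedom (m = number of independent variables, default
2). Six classes combine the coefficient sign with the 0.01/0.05 thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum

import numpy as np
import pandas as pd
from scipy import stats

from tercab.gridio import AnnualStack, Grid

__all__ = [
    "CorrelationClass",
    "CorrelationMaps",
    "pearson",
    "partial_correlation",
    "partial_t_test",
    "classify_correlation",
    "correlation_maps",
    "correlation_summary",
]


class CorrelationClass(IntEnum):
    ESNC = 1  # extremely significant negative correlation
    SNC = 2   # significant negative correlation
    INC = 3   # insignificant negative correlation
    IPC = 4   # insignificant positive correlation
    SPC = 5   # significant positive correlation
    ESPC = 6  # extremely significant positive correlation


def pearson(x, y) -> float:
    """Product-moment correlation coefficient of two equal-length series."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D series of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    dx = x - x.mean()
    dy = y - y.mean()
    den = np.sqrt(np.sum(dx * dx) * np.sum(dy * dy))
    if den == 0.0:
        raise ValueError("zero variance: correlation undefined")
    return float(np.sum(dx * dy) / den)


def partial_correlation(x, y, z) -> float:
    """First-order partial correlation of x and y controlling for z.

    ``(r_xy - r_xz r_yz) / sqrt((1 - r_xz^2)(1 - r_yz^2))``; equals the
    Pearson correlation of the residuals of x and y on z. Returns NaN
    when either control correlation is degenerate (|r| = 1).
    """
    r_xy = pearson(x, y)
    r_xz = pearson(x, z)
    r_yz = pearson(y, z)
    den = (1.0 - r_xz ** 2) * (1.0 - r_yz ** 2)
    if den <= 0.0:
        return float("nan")
    return float((r_xy - r_xz * r_yz) / np.sqrt(den))


def partial_t_test(r: float, n: int, m: int = 2) -> tuple[float, float]:
    """t statistic and two-sided p for a partial correlation coefficient.

    ``t = r * sqrt((n - m - 1) / (1 - r^2))`` with n - m - 1 degrees of
    freedom. |r| = 1 returns ``(±inf, 0.0)``.
    """
    df = n - m - 1
    if df < 1:
        raise ValueError(f"need n - m - 1 >= 1, got n={n}, m={m}")
    if abs(r) >= 1.0:
        return float(np.sign(r)) * float("inf"), 0.0
    t = r * np.sqrt(df / (1.0 - r * r))
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return float(t), min(p, 1.0)


def classify_correlation(r: float, p: float) -> CorrelationClass:
    """Six-way class from the coefficient sign and the 0.01/0.05 thresholds."""
    if r >= 0:
        if p < 0.01:
            return CorrelationClass.ESPC
        if p < 0.05:
            return CorrelationClass.SPC
        return CorrelationClass.IPC
    if p < 0.01:
        return CorrelationClass.ESNC
    if p < 0.05:
        return CorrelationClass.SNC
    return CorrelationClass.INC


def _pearson_fields(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pearson r along axis 0 of two (n, ...) arrays; NaN where degenerate."""
    da = a - a.mean(axis=0)
    db = b - b.mean(axis=0)
    den = np.sqrt(np.sum(da * da, axis=0) * np.sum(db * db, axis=0))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.sum(da * db, axis=0) / den
    r = np.where(den == 0.0, np.nan, r)
    return r


@dataclass
class CorrelationMaps:
    """Per-pixel partial-correlation output for one climate variable."""

    r_partial: Grid
    t: Grid
    p: Grid
    klass: Grid  # CorrelationClass codes; 0 = excluded/degenerate


def correlation_maps(response: AnnualStack, climate: AnnualStack,
                     control: AnnualStack, m: int = 2) -> CorrelationMaps:
    """Partial correlation of a response stack with one climate stack,
    controlling for a second, with per-pixel t test and classification."""
    n = len(response)
    if not (response.years == climate.years == control.years):
        raise ValueError("stacks must cover identical years")
    df = n - m - 1
    if df < 1:
        raise ValueError(f"need n - m - 1 >= 1, got n={n}, m={m}")
    x = response.to_array()
    y = climate.to_array()
    z = control.to_array()
    excluded = (response.combined_mask() | climate.combined_mask()
                | control.combined_mask())

    r_xy = _pearson_fields(x, y)
    r_xz = _pearson_fields(x, z)
    r_yz = _pearson_fields(y, z)
    den = (1.0 - r_xz ** 2) * (1.0 - r_yz ** 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(den > 0.0, (r_xy - r_xz * r_yz) / np.sqrt(den), np.nan)
        r = np.clip(r, -1.0, 1.0)
        t = r * np.sqrt(df / (1.0 - r * r))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.where(np.abs(r) >= 1.0, 0.0, p)
    t = np.where(np.abs(r) >= 1.0, np.sign(r) * np.inf, t)

    bad = excluded | np.isnan(r)
    klass = np.zeros(r.shape, dtype=np.int16)
    ok = ~bad
    kl = np.full(r.shape, int(CorrelationClass.IPC), dtype=np.int16)
    kl[(r >= 0) & (p < 0.05)] = CorrelationClass.SPC
    kl[(r >= 0) & (p < 0.01)] = CorrelationClass.ESPC
    kl[r < 0] = CorrelationClass.INC
    kl[(r < 0) & (p < 0.05)] = CorrelationClass.SNC
    kl[(r < 0) & (p < 0.01)] = CorrelationClass.ESNC
    klass[ok] = kl[ok]

    for arr in (r, t, p):
        arr[bad] = np.nan
    tmpl = response.template
    return CorrelationMaps(
        r_partial=tmpl.like(r), t=tmpl.like(t), p=tmpl.like(p),
        klass=tmpl.like(klass, nodata=0),
    )


def correlation_summary(maps: CorrelationMaps, pixel_area_km2: float) -> pd.DataFrame:
    """Class areas (km^2) and proportions (%) over the valid mask."""
    codes = maps.klass.values
    rows = []
    n_valid = int(np.count_nonzero(codes > 0))
    for c in CorrelationClass:
        count = int(np.count_nonzero(codes == c.value))
        rows.append({
            "klass": c.name,
            "area_km2": count * pixel_area_km2,
            "proportion_pct": 100.0 * count / n_valid if n_valid else 0.0,
        })
    return pd.DataFrame(rows).set_index("klass")
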