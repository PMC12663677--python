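"""Residual-trend attribution of carbon-balance change.

Per pixel, the observed carbon-balance series is regressed on temperature
and precipitation (cb_cc = a*T + b*P + c); the residual series cb_ha =
cb_obs - cb_cc is attributed to human activity. The trends (least-squares
slopes) of the observed, climate-predicted and residual series determine
one of six driver scenarios; for same-sign scenarios the contribution of
each driver is its slope as a share of the observed slope (summing to
100%), otherwise the dominant driver takes 100%.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import IntEnum

import numpy as np
import pandas as pd

from tercab import trend
from tercab.gridio import AnnualStack, Grid

__all__ = [
    "DriverScenario",
    "AttributionFit",
    "AttributionMaps",
    "fit_climate_model",
    "classify_driver",
    "contribution_levels",
    "attribute_stack",
    "attribution_summary",
    "CONTRIBUTION_BINS",
]

logger = logging.getLogger(__name__)

NO_CHANGE_TOL = 1e-12
CONTRIBUTION_BINS = ((0, 20), (20, 40), (40, 60), (60, 80), (80, 100))


class DriverScenario(IntEnum):
    NO_CHANGE = 0
    IMPROVE_CC_HA = 1  # slope_obs>0, both drivers positive
    IMPROVE_CC = 2     # slope_obs>0, climate positive, human negative
    IMPROVE_HA = 3     # slope_obs>0, climate negative, human positive
    DEGRADE_CC_HA = 4  # slope_obs<0, both drivers negative
    DEGRADE_CC = 5     # slope_obs<0, climate negative, human positive
    DEGRADE_HA = 6     # slope_obs<0, climate positive, human negative


@dataclass
class AttributionFit:
    """Least-squares climate model of one pixel's carbon-balance series."""

    a: float  # Mg/hm^2 per deg C
    b: float  # Mg/hm^2 per m precipitation
    c: float  # Mg/hm^2 intercept
    cb_cc: np.ndarray  # predicted series
    cb_ha: np.ndarray  # residual series (cb_obs - cb_cc)


def fit_climate_model(cb, T, P) -> AttributionFit:
    """Fit cb = a*T + b*P + c by least squares for one pixel.

    Raises on rank deficiency (e.g. constant T and P series).
    """
    cb = np.asarray(cb, dtype=float)
    T = np.asarray(T, dtype=float)
    P = np.asarray(P, dtype=float)
    if not (cb.shape == T.shape == P.shape) or cb.ndim != 1:
        raise ValueError("cb, T, P must be 1-D series of equal length")
    if cb.size < 4:
        raise ValueError("need at least 4 observations for a 3-parameter fit")
    X = np.column_stack([T, P, np.ones_like(T)])
    coef, _, rank, _ = np.linalg.lstsq(X, cb, rcond=None)
    if rank < 3:
        raise np.linalg.LinAlgError("rank-deficient climate design matrix")
    cb_cc = X @ coef
    return AttributionFit(a=float(coef[0]), b=float(coef[1]), c=float(coef[2]),
                          cb_cc=cb_cc, cb_ha=cb - cb_cc)


def classify_driver(slope_obs: float, slope_cc: float, slope_ha: float,
                    tol: float = NO_CHANGE_TOL
                    ) -> tuple[DriverScenario, float, float]:
    """Driver scenario and (climate %, human %) contributions from slopes.

    Same-sign scenarios split 100% by slope ratios; mixed-sign scenarios
    assign 100% to the driver whose slope shares the observed sign.
    |slope_obs| < tol yields NO_CHANGE with NaN contributions.
    """
    if abs(slope_obs) < tol:
        return DriverScenario.NO_CHANGE, float("nan"), float("nan")
    if slope_obs > 0:
        if slope_cc >= 0 and slope_ha >= 0:
            scenario = DriverScenario.IMPROVE_CC_HA
        elif slope_ha < 0:
            return DriverScenario.IMPROVE_CC, 100.0, 0.0
        else:
            return DriverScenario.IMPROVE_HA, 0.0, 100.0
    else:
        if slope_cc <= 0 and slope_ha <= 0:
            scenario = DriverScenario.DEGRADE_CC_HA
        elif slope_ha > 0:
            return DriverScenario.DEGRADE_CC, 100.0, 0.0
        else:
            return DriverScenario.DEGRADE_HA, 0.0, 100.0
    cc = 100.0 * slope_cc / slope_obs
    ha = 100.0 * slope_ha / slope_obs
    if not (0.0 <= cc <= 100.0 and 0.0 <= ha <= 100.0):
        logger.debug("clipping contributions cc=%.3f ha=%.3f", cc, ha)
    return scenario, float(np.clip(cc, 0.0, 100.0)), float(np.clip(ha, 0.0, 100.0))


def contribution_levels(contrib: float) -> str:
    """Bin a contribution percentage into the five 20%-wide levels.

    Bins are left-closed: [0,20), [20,40), [40,60), [60,80), [80,100].
    """
    if not (0.0 <= contrib <= 100.0):
        raise ValueError(f"contribution must be in [0, 100], got {contrib}")
    for lo, hi in CONTRIBUTION_BINS[:-1]:
        if contrib < hi:
            return f"{lo}-{hi}"
    return "80-100"


@dataclass
class AttributionMaps:
    """Per-pixel attribution grids; nodata where the fit is undefined."""

    slope_obs: Grid
    slope_cc: Grid
    slope_ha: Grid
    scenario: Grid      # DriverScenario codes; -1 = excluded
    contrib_cc: Grid    # %
    contrib_ha: Grid    # %
    a: Grid
    b: Grid
    c: Grid


def attribute_stack(cb: AnnualStack, T: AnnualStack, P: AnnualStack,
                    tol: float = NO_CHANGE_TOL) -> AttributionMaps:
    """Residual-trend attribution over co-registered annual stacks."""
    if not (cb.years == T.years == P.years):
        raise ValueError("stacks must cover identical years")
    n = len(cb)
    if n < 4:
        raise ValueError("need at least 4 years")
    y = cb.to_array()
    t = T.to_array()
    p = P.to_array()
    excluded = cb.combined_mask() | T.combined_mask() | P.combined_mask()
    shape = excluded.shape
    flat = (~excluded).ravel()
    yf = y.reshape(n, -1)[:, flat]
    tf = t.reshape(n, -1)[:, flat]
    pf = p.reshape(n, -1)[:, flat]

    # centered normal equations per pixel: well-conditioned 2x2 solve
    t_mean = tf.mean(axis=0)
    p_mean = pf.mean(axis=0)
    y_mean = yf.mean(axis=0)
    tc = tf - t_mean
    pc = pf - p_mean
    yc = yf - y_mean
    stt = np.sum(tc * tc, axis=0)
    spp = np.sum(pc * pc, axis=0)
    stp = np.sum(tc * pc, axis=0)
    sty = np.sum(tc * yc, axis=0)
    spy = np.sum(pc * yc, axis=0)
    det = stt * spp - stp * stp
    solvable = det > 1e-12 * np.maximum(stt * spp, 1e-300)
    coef = np.full((int(flat.sum()), 3), np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        coef[:, 0] = np.where(solvable, (spp * sty - stp * spy) / det, np.nan)
        coef[:, 1] = np.where(solvable, (stt * spy - stp * sty) / det, np.nan)
    coef[:, 2] = y_mean - coef[:, 0] * t_mean - coef[:, 1] * p_mean
    if (~solvable).any():
        logger.warning("%d pixels excluded: rank-deficient climate design",
                       int((~solvable).sum()))

    cb_cc = coef[:, 0] * tf + coef[:, 1] * pf + coef[:, 2]
    cb_ha = yf - cb_cc

    def _slopes(series: np.ndarray) -> np.ndarray:
        i = np.arange(1, n + 1, dtype=float)[:, None]
        num = n * np.sum(i * series, axis=0) - i.sum() * series.sum(axis=0)
        den = n * np.sum(i * i) - i.sum() ** 2
        return num / den

    s_obs = _slopes(yf)
    s_cc = _slopes(cb_cc)
    s_ha = _slopes(cb_ha)

    scen = np.full(flat.sum(), int(DriverScenario.NO_CHANGE), dtype=np.int16)
    ccp = np.full(flat.sum(), np.nan)
    hap = np.full(flat.sum(), np.nan)
    defined = solvable & (np.abs(s_obs) >= tol)
    pos = defined & (s_obs > 0)
    neg = defined & (s_obs < 0)

    both_pos = pos & (s_cc >= 0) & (s_ha >= 0)
    cc_only_p = pos & (s_ha < 0)
    ha_only_p = pos & ~both_pos & ~cc_only_p
    both_neg = neg & (s_cc <= 0) & (s_ha <= 0)
    cc_only_n = neg & (s_ha > 0)
    ha_only_n = neg & ~both_neg & ~cc_only_n
    scen[both_pos] = DriverScenario.IMPROVE_CC_HA
    scen[cc_only_p] = DriverScenario.IMPROVE_CC
    scen[ha_only_p] = DriverScenario.IMPROVE_HA
    scen[both_neg] = DriverScenario.DEGRADE_CC_HA
    scen[cc_only_n] = DriverScenario.DEGRADE_CC
    scen[ha_only_n] = DriverScenario.DEGRADE_HA
    ratio = both_pos | both_neg
    with np.errstate(invalid="ignore", divide="ignore"):
        ccp[ratio] = np.clip(100.0 * s_cc[ratio] / s_obs[ratio], 0.0, 100.0)
        hap[ratio] = np.clip(100.0 * s_ha[ratio] / s_obs[ratio], 0.0, 100.0)
    ccp[cc_only_p | cc_only_n] = 100.0
    hap[cc_only_p | cc_only_n] = 0.0
    ccp[ha_only_p | ha_only_n] = 0.0
    hap[ha_only_p | ha_only_n] = 100.0
    scen[~solvable] = -1

    def _unflat(vals, fill=np.nan, dtype=float):
        out = np.full(shape[0] * shape[1], fill, dtype=dtype)
        out[flat] = vals
        return out.reshape(shape)

    tmpl = cb.template
    for arr in (s_obs, s_cc, s_ha):
        arr[~solvable] = np.nan
    return AttributionMaps(
        slope_obs=tmpl.like(_unflat(s_obs)),
        slope_cc=tmpl.like(_unflat(s_cc)),
        slope_ha=tmpl.like(_unflat(s_ha)),
        scenario=tmpl.like(_unflat(scen, fill=-1, dtype=np.int16), nodata=-1),
        contrib_cc=tmpl.like(_unflat(ccp)),
        contrib_ha=tmpl.like(_unflat(hap)),
        a=tmpl.like(_unflat(coef[:, 0])),
        b=tmpl.like(_unflat(coef[:, 1])),
        c=tmpl.like(_unflat(coef[:, 2])),
    )


def attribution_summary(maps: AttributionMaps, pixel_area_km2: float) -> pd.DataFrame:
    """Improved/degraded area shares with mean contributions and bin shares."""
    scen = maps.scenario.values
    ccp = maps.contrib_cc.filled(np.nan)
    hap = maps.contrib_ha.filled(np.nan)
    improved = np.isin(scen, [DriverScenario.IMPROVE_CC_HA,
                              DriverScenario.IMPROVE_CC,
                              DriverScenario.IMPROVE_HA])
    degraded = np.isin(scen, [DriverScenario.DEGRADE_CC_HA,
                              DriverScenario.DEGRADE_CC,
                              DriverScenario.DEGRADE_HA])
    n_defined = int(improved.sum() + degraded.sum())
    rows = []
    for label, sel in (("improved", improved), ("degraded", degraded)):
        row = {
            "direction": label,
            "area_km2": float(sel.sum()) * pixel_area_km2,
            "share_pct": 100.0 * sel.sum() / n_defined if n_defined else np.nan,
            "mean_contrib_cc_pct": float(np.nanmean(ccp[sel])) if sel.any() else np.nan,
            "mean_contrib_ha_pct": float(np.nanmean(hap[sel])) if sel.any() else np.nan,
        }
        for lo, hi in CONTRIBUTION_BINS:
            top = 100.0 + 1e-9 if hi == 100 else hi
            in_cc = sel & (ccp >= lo) & (ccp < top)
            in_ha = sel & (hap >= lo) & (hap < top)
            denom = sel.sum()
            row[f"cc_{lo}-{hi}_pct"] = 100.0 * in_cc.sum() / denom if denom else np.nan
            row[f"ha_{lo}-{hi}_pct"] = 100.0 * in_ha.sum() / denom if denom else np.nan
        rows.append(row)
    return pd.DataFrame(rows).set_index("direction")
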