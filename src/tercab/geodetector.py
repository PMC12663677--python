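"""Stratified-variance factor detection (q statistic) and interactions.

The q statistic measures how much a stratification of the study area
explains the spatial variance of a response:

    q = 1 - sum_h(N_h * var_h) / (N * var)

with population (N-weighted) variances, so q = 1 - SSW/SST. Interactions
overlay two stratifications (Cartesian pairs of labels) and compare q12
against q1, q2 and q1 + q2.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from tercab.gridio import Grid

__all__ = [
    "discretize",
    "q_statistic",
    "interaction_q",
    "classify_interaction",
    "InteractionReport",
    "factor_report",
]

logger = logging.getLogger(__name__)

INTERACTION_TYPES = (
    "nonlinear weaken",
    "single-factor nonlinear weaken",
    "two-factor enhancement",
    "independent",
    "nonlinear enhancement",
)


def _as_values(x) -> np.ndarray:
    if isinstance(x, Grid):
        return x.filled(np.nan).ravel()
    return np.asarray(x, dtype=float).ravel()


def discretize(factor, k: int = 5, method: str = "quantile",
               categorical: bool = False) -> np.ndarray:
    """Stratum labels (0..k-1) for a factor; -1 marks invalid cells.

    Categorical factors pass through unchanged (their codes become labels).
    If the factor has fewer distinct values than ``k``, k is reduced with a
    warning.
    """
    vals = _as_values(factor)
    out = np.full(vals.shape, -1, dtype=np.int64)
    valid = ~np.isnan(vals)
    if categorical:
        out[valid] = vals[valid].astype(np.int64)
        return out
    if k < 2:
        raise ValueError("k must be >= 2")
    v = vals[valid]
    distinct = np.unique(v)
    if distinct.size < k:
        warnings.warn(f"only {distinct.size} distinct values; reducing k from {k}",
                      stacklevel=2)
        k = max(distinct.size, 1)
    if method == "quantile":
        labels = pd.qcut(v, q=k, labels=False, duplicates="drop")
    elif method == "equal-interval":
        labels = pd.cut(v, bins=k, labels=False, include_lowest=True)
    else:
        raise ValueError(f"unknown discretization method {method!r}")
    out[valid] = np.asarray(labels, dtype=np.int64)
    return out


def q_statistic(y, strata) -> float:
    """Variance-explained q of a stratification; NaN when undefined.

    Cells with NaN response or negative stratum label are dropped. Returns
    NaN (flagged via log) if fewer than 2 cells remain or the overall
    variance is zero.
    """
    y = _as_values(y)
    strata = np.asarray(strata).ravel()
    if y.shape != strata.shape:
        raise ValueError("y and strata must have equal length")
    ok = ~np.isnan(y) & (strata >= 0)
    y = y[ok]
    s = strata[ok]
    n = y.size
    if n < 2:
        logger.warning("q undefined: fewer than 2 valid cells")
        return float("nan")
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0.0:
        logger.warning("q undefined: zero overall variance")
        return float("nan")
    _, inv, counts = np.unique(s, return_inverse=True, return_counts=True)
    group_sum = np.bincount(inv, weights=y)
    group_mean = group_sum / counts
    ssw = float(np.sum((y - group_mean[inv]) ** 2))
    return 1.0 - ssw / sst


def overlay_strata(strata1, strata2) -> np.ndarray:
    """Cartesian-pair stratification; invalid where either input is."""
    s1 = np.asarray(strata1).ravel()
    s2 = np.asarray(strata2).ravel()
    if s1.shape != s2.shape:
        raise ValueError("stratifications must have equal length")
    ok = (s1 >= 0) & (s2 >= 0)
    out = np.full(s1.shape, -1, dtype=np.int64)
    span = int(s2[ok].max()) + 1 if ok.any() else 1
    out[ok] = s1[ok] * span + s2[ok]
    return out


def classify_interaction(q1: float, q2: float, q12: float,
                         tol: float = 1e-9) -> str:
    """Interaction type from single-factor and overlay q values."""
    lo, hi = min(q1, q2), max(q1, q2)
    if q12 < lo:
        return "nonlinear weaken"
    if q12 <= hi:
        return "single-factor nonlinear weaken"
    if abs(q12 - (q1 + q2)) <= tol:
        return "independent"
    if q12 < q1 + q2:
        return "two-factor enhancement"
    return "nonlinear enhancement"


@dataclass
class InteractionReport:
    q1: float
    q2: float
    q12: float
    interaction_type: str


def interaction_q(y, strata1, strata2) -> InteractionReport:
    """q of the overlay of two stratifications, with interaction type."""
    q1 = q_statistic(y, strata1)
    q2 = q_statistic(y, strata2)
    overlay = overlay_strata(strata1, strata2)
    q12 = q_statistic(y, overlay)
    # singleton-only overlay degenerates to q = 1 exactly
    yv = _as_values(y)
    ok = ~np.isnan(yv) & (overlay >= 0)
    if ok.any():
        _, counts = np.unique(overlay[ok], return_counts=True)
        if (counts == 1).all():
            logger.warning("overlay produced only singleton strata; q12 degenerate")
    return InteractionReport(q1=q1, q2=q2, q12=q12,
                             interaction_type=classify_interaction(q1, q2, q12))


def factor_report(y_by_year: dict[int, Grid | np.ndarray],
                  factors: dict[int | str, dict],
                  k: int = 5, method: str = "quantile",
                  interactions: bool = True
                  ) -> tuple[pd.DataFrame, dict[int, pd.DataFrame]]:
    """Per-year q per factor with multiyear means and ranks, plus pairwise
    interaction matrices.

    ``factors`` maps a factor name to ``{"grid": Grid or {year: Grid},
    "categorical": bool}``. Static factors are re-used for every year.
    Returns ``(q_table, {year: interaction_matrix})``.
    """
    names = list(factors)
    rows = []
    inter: dict[int, pd.DataFrame] = {}
    for year, y in y_by_year.items():
        yv = _as_values(y)
        strata = {}
        for name in names:
            spec = factors[name]
            grid = spec["grid"]
            if isinstance(grid, dict):
                grid = grid[year]
            strata[name] = discretize(grid, k=k, method=method,
                                      categorical=bool(spec.get("categorical")))
        for name in names:
            rows.append({"factor": name, "year": year,
                         "q": q_statistic(yv, strata[name])})
        if interactions:
            mat = pd.DataFrame(np.nan, index=names, columns=names)
            for i, n1 in enumerate(names):
                for n2 in names[:i + 1]:
                    rep = interaction_q(yv, strata[n1], strata[n2])
                    mat.loc[n1, n2] = rep.q12
                    mat.loc[n2, n1] = rep.q12
            inter[year] = mat
    q_table = pd.DataFrame(rows)
    means = q_table.groupby("factor", sort=False)["q"].mean()
    q_table["multiyear_mean_q"] = q_table["factor"].map(means)
    ranks = means.rank(ascending=False, method="min").astype(int)
    q_table["rank"] = q_table["factor"].map(ranks)
    return q_table, inter
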