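"""Carbon-balance assembly: CB = CS + NEP * dt per pixel-year.

NEP (g C m^-2 yr^-1) converts to Mg/hm^2 by * 0.01, so carbon balance and
storage share the Mg/hm^2 scale. Interannual summaries report per-year
totals (Tg), means (Mg/hm^2), per-class means and OLS rates of change over
user-specified year windows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from tercab import trend
from tercab.gridio import AnnualStack, Grid, ensure_coregistered
from tercab.lulc import CLASS_NAMES

__all__ = [
    "NEP_G_TO_MG_PER_HM2",
    "carbon_balance",
    "carbon_balance_stack",
    "InterannualSummary",
    "interannual_summary",
]

# 1 g C m^-2 = 0.01 Mg/hm^2
NEP_G_TO_MG_PER_HM2 = 0.01
HM2_PER_TG_AT_1MG = 1e6  # Mg -> Tg


def carbon_balance(cs_density: Grid, nep: Grid, delta_t: float = 1.0) -> Grid:
    """Per-pixel carbon balance (Mg/hm^2); negative values allowed."""
    if delta_t <= 0:
        raise ValueError("delta_t must be positive")
    ensure_coregistered(cs_density, nep)
    cb = cs_density.filled(np.nan) + NEP_G_TO_MG_PER_HM2 * nep.filled(np.nan) * delta_t
    return cs_density.like(cb)


def carbon_balance_stack(cs_stack: AnnualStack, nep_stack: AnnualStack,
                         delta_t: float = 1.0) -> AnnualStack:
    """Yearwise carbon balance; each year uses that year's storage and NEP."""
    if cs_stack.years != nep_stack.years:
        raise ValueError("storage and NEP stacks must cover identical years")
    grids = [carbon_balance(cs, ne, delta_t)
             for cs, ne in zip(cs_stack.grids, nep_stack.grids)]
    return AnnualStack(list(cs_stack.years), grids)


@dataclass
class InterannualSummary:
    yearly: pd.DataFrame      # index year; total_Tg, mean_Mg_per_hm2
    per_class: pd.DataFrame   # index year; one mean column per class name
    window_slopes: pd.DataFrame  # per window: slope of mean and of total


def interannual_summary(cb: AnnualStack, lulc: AnnualStack,
                        pixel_area_hm2: float,
                        windows: list[tuple[int, int]] | None = None
                        ) -> InterannualSummary:
    """Per-year totals/means, per-class means, and windowed OLS slopes.

    ``windows`` are inclusive (start_year, end_year) pairs; the slope is the
    least-squares rate of change of the regional mean (Mg/hm^2 yr^-1) and of
    the regional total (Tg yr^-1) within the window.
    """
    if cb.years != lulc.years:
        raise ValueError("carbon-balance and land-use stacks must share years")
    yearly_rows = []
    class_rows = []
    for year, cb_grid, lulc_grid in zip(cb.years, cb.grids, lulc.grids):
        vals = cb_grid.filled(np.nan)
        valid = ~np.isnan(vals)
        total_mg = float(np.nansum(vals)) * pixel_area_hm2
        mean = float(np.nanmean(vals)) if valid.any() else np.nan
        yearly_rows.append({"year": year,
                            "total_Tg": total_mg / HM2_PER_TG_AT_1MG,
                            "mean_Mg_per_hm2": mean})
        row = {"year": year}
        codes = lulc_grid.values
        for code in np.unique(codes[lulc_grid.valid]):
            sel = valid & (codes == code)
            row[CLASS_NAMES.get(int(code), str(int(code)))] = (
                float(vals[sel].mean()) if sel.any() else np.nan)
        class_rows.append(row)
    yearly = pd.DataFrame(yearly_rows).set_index("year")
    per_class = pd.DataFrame(class_rows).set_index("year")

    win_rows = []
    for (y0, y1) in (windows or []):
        if y0 not in cb.years or y1 not in cb.years or y1 <= y0:
            raise ValueError(f"window {y0}-{y1} outside available years "
                             f"{cb.years[0]}-{cb.years[-1]}")
        sel = yearly.loc[y0:y1]
        win_rows.append({
            "start": y0, "end": y1,
            "mean_slope_Mg_per_hm2_yr": trend.pixel_slope(sel["mean_Mg_per_hm2"].to_numpy()),
            "total_slope_Tg_yr": trend.pixel_slope(sel["total_Tg"].to_numpy()),
        })
    window_slopes = pd.DataFrame(win_rows)
    return InterannualSummary(yearly=yearly, per_class=per_class,
                              window_slopes=window_slopes)
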