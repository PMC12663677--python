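"""Net ecosystem productivity from NPP and modelled soil respiration.

Annual soil respiration (kg C m^-2 yr^-1) follows an empirical model in
annual mean temperature (deg C), annual precipitation (m) and topsoil
organic carbon density (kg C m^-2):

    Rs = 1.55 * exp(0.031 T) * P / (P + 0.68) * SOC / (SOC + 2.23)

Heterotrophic respiration is the fitted power law Rh = 0.6163 * Rs^0.7918
(same kg unit), and NEP = NPP - Rh with Rh converted to g C m^-2 yr^-1.
Positive NEP marks a carbon sink, negative a source.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum

import numpy as np

from tercab.gridio import Grid, ensure_coregistered

__all__ = [
    "SinkSourceClass",
    "NEPGrid",
    "soil_respiration",
    "heterotrophic_respiration",
    "nep",
    "classify_sink_source",
]

RS_COEF = 1.55
RS_TEMP_RATE = 0.031
RS_PRECIP_HALF = 0.68
RS_SOC_HALF = 2.23
RH_COEF = 0.6163
RH_EXP = 0.7918
KG_TO_G = 1000.0


class SinkSourceClass(IntEnum):
    SOURCE = -1
    NEUTRAL = 0
    SINK = 1


def _validate_nonnegative(name: str, arr: np.ndarray) -> None:
    if np.any(arr[~np.isnan(arr)] < 0):
        raise ValueError(f"{name} must be non-negative")


def soil_respiration(T, P, SOC):
    """Annual soil respiration (kg C m^-2 yr^-1) from T (deg C), P (m),
    SOC (kg C m^-2). Strictly increasing in each argument on P, SOC > 0."""
    T = np.asarray(T, dtype=float)
    P = np.asarray(P, dtype=float)
    SOC = np.asarray(SOC, dtype=float)
    _validate_nonnegative("precipitation", P)
    _validate_nonnegative("SOC", SOC)
    rs = (RS_COEF * np.exp(RS_TEMP_RATE * T)
          * P / (P + RS_PRECIP_HALF)
          * SOC / (SOC + RS_SOC_HALF))
    return rs if rs.ndim else float(rs)


def heterotrophic_respiration(rs):
    """Heterotrophic respiration (kg C m^-2 yr^-1) from soil respiration."""
    rs = np.asarray(rs, dtype=float)
    _validate_nonnegative("Rs", rs)
    rh = RH_COEF * rs ** RH_EXP
    return rh if rh.ndim else float(rh)


@dataclass
class NEPGrid:
    """Per-pixel respiration chain: NPP in, Rs/Rh intermediate, NEP out.

    Units: npp and nep in g C m^-2 yr^-1; rs and rh in kg C m^-2 yr^-1.
    """

    npp: Grid
    rs: Grid
    rh: Grid
    nep: Grid


def nep(npp: Grid, T: Grid, P: Grid, SOC: Grid,
        precip_unit: str = "m") -> NEPGrid:
    """Compute NEP = NPP - Rh per pixel on co-registered grids.

    ``precip_unit`` may be ``"m"`` or ``"mm"`` (converted / 1000). Nodata in
    any input propagates. NEP may be negative (carbon source).
    """
    ensure_coregistered(npp, T, P, SOC)
    if precip_unit not in {"m", "mm"}:
        raise ValueError(f"unsupported precipitation unit {precip_unit!r}")
    p_m = P.filled(np.nan)
    if precip_unit == "mm":
        p_m = p_m / 1000.0
    rs = soil_respiration(T.filled(np.nan), p_m, SOC.filled(np.nan))
    rh = heterotrophic_respiration(rs)
    nep_vals = npp.filled(np.nan) - rh * KG_TO_G
    return NEPGrid(
        npp=npp.like(npp.filled(np.nan)),
        rs=npp.like(rs),
        rh=npp.like(rh),
        nep=npp.like(nep_vals),
    )


def classify_sink_source(nep_grid: Grid) -> Grid:
    """Sink (+1) where NEP > 0, source (-1) where NEP < 0, neutral (0)."""
    vals = nep_grid.filled(np.nan)
    out = np.zeros(vals.shape, dtype=np.int16)
    out[vals > 0] = SinkSourceClass.SINK
    out[vals < 0] = SinkSourceClass.SOURCE
    # nodata flagged with a sentinel outside the class codes
    out[np.isnan(vals)] = -9999
    return nep_grid.like(out, nodata=-9999)
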