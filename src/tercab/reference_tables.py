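"""Published reference tables shipped with the package.

These are printed summary tables for a tropical-island study region
(2000-2022) used as default parameters and as fixed inputs for the
acceptance checks: the per-class four-pool carbon densities, the 2000-2022
land-use transfer matrix (km^2), and the five-class trend-significance
area tables for carbon storage, NEP and carbon balance.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = [
    "load_carbon_density_frame",
    "load_transfer_frame",
    "load_trend_areas",
]


def _data_path(name: str):
    return resources.files("tercab").joinpath("data", name)


def load_carbon_density_frame() -> pd.DataFrame:
    """Default carbon-density table: class code, name, Ca/Cb/Cs/Cd (Mg/hm^2)."""
    with resources.as_file(_data_path("carbon_density.csv")) as p:
        return pd.read_csv(p)


def load_transfer_frame() -> pd.DataFrame:
    """Published 7x7 land-use transfer matrix, km^2 (rows=start, cols=end)."""
    with resources.as_file(_data_path("lulc_transfer_2000_2022.csv")) as p:
        return pd.read_csv(p, index_col="class")


def load_trend_areas(variable: str) -> pd.Series:
    """Published five-class trend areas (km^2) for one analysed variable.

    ``variable`` is one of ``carbon_storage``, ``nep``, ``carbon_balance``.
    """
    with resources.as_file(_data_path("trend_class_areas.csv")) as p:
        df = pd.read_csv(p)
    sub = df[df["variable"] == variable]
    if sub.empty:
        raise KeyError(f"no trend-area table for {variable!r}; "
                       f"available: {sorted(df['variable'].unique())}")
    return sub.set_index("klass")["area_km2"]
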