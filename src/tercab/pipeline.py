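"""End-to-end pipeline: chain the analysis stages from a JSON config.

A config either embeds synthetic-scene parameters (``"scene"``) or names
input raster paths per variable and year (``"inputs"``). Stages are run in
dependency order; only the requested stages write outputs. Every run writes
a JSON log recording the seed, package/library versions and parameters, so
identical config + seed reproduces identical outputs.
"""

from __future__ import annotations

import json
import logging
import platform
from pathlib import Path

import numpy as np
import pandas as pd

import tercab
from tercab import attribution, balance, correlation, geodetector, storage, trend
from tercab import nep as nep_mod
from tercab.gridio import AnnualStack, read_grid, write_grid
from tercab.lulc import LULCClass
from tercab.synthetic import SceneConfig, generate_scene

__all__ = ["STAGES", "run_pipeline"]

logger = logging.getLogger(__name__)

STAGES = ("simulate", "storage", "nep", "balance", "trend", "corr",
          "attribute", "geodetect", "transfer", "report")


def _load_config(config) -> dict:
    if isinstance(config, (str, Path)):
        return json.loads(Path(config).read_text())
    return dict(config)


def _read_stack(pattern: str, years: list[int], name: str) -> AnnualStack:
    missing = [y for y in years if not Path(pattern.format(year=y)).exists()]
    if missing:
        raise ValueError(f"{name}: missing input rasters for years {missing}")
    return AnnualStack(years, [read_grid(pattern.format(year=y)) for y in years])


class _Data:
    """Lazily assembled inputs shared by the stages."""

    def __init__(self, cfg: dict, seed: int | None):
        self.cfg = cfg
        self.precip_unit = cfg.get("precip_unit", "m")
        if "scene" in cfg:
            scene_cfg = dict(cfg["scene"])
            if seed is not None:
                scene_cfg["seed"] = seed
            self.scene_config = SceneConfig.from_dict(scene_cfg)
            self.seed = self.scene_config.seed
            scene = generate_scene(self.scene_config)
            self.scene = scene
            self.years = list(scene.lulc.years)
            self.lulc = scene.lulc
            self.temperature = scene.temperature
            self.precipitation = scene.precipitation
            self.npp = scene.npp
            self.soc = scene.soc
            self.covariates = scene.covariates
            self.pixel_area_hm2 = self.scene_config.pixel_area_hm2
        elif "inputs" in cfg:
            self.scene = None
            self.seed = seed if seed is not None else int(cfg.get("seed", 0))
            inputs = cfg["inputs"]
            self.years = [int(y) for y in cfg["years"]]
            self.lulc = _read_stack(inputs["lulc"], self.years, "lulc")
            self.temperature = _read_stack(inputs["temperature"], self.years,
                                           "temperature")
            self.precipitation = _read_stack(inputs["precipitation"], self.years,
                                             "precipitation")
            self.npp = _read_stack(inputs["npp"], self.years, "npp")
            self.soc = read_grid(inputs["soc"])
            self.covariates = {name: read_grid(path)
                               for name, path in inputs.get("covariates", {}).items()}
            self.pixel_area_hm2 = float(cfg["pixel_area_hm2"])
        else:
            raise ValueError("config must contain either 'scene' or 'inputs'")
        self.pixel_area_km2 = self.pixel_area_hm2 / 100.0
        if "density_table" in cfg:
            self.density_table = storage.CarbonDensityTable.from_csv(cfg["density_table"])
        else:
            self.density_table = storage.CarbonDensityTable.default()
        self._cache: dict[str, object] = {}

    # derived products, computed once
    def storage_stack(self) -> AnnualStack:
        if "storage" not in self._cache:
            grids = [storage.density_map(g, self.density_table)
                     for g in self.lulc.grids]
            self._cache["storage"] = AnnualStack(list(self.years), grids)
        return self._cache["storage"]

    def nep_stack(self) -> AnnualStack:
        if "nep" not in self._cache:
            water = [g.like(np.where(g.values == LULCClass.WATER, np.nan,
                                     g.filled(np.nan)))
                     for g in self.lulc.grids]
            grids = []
            for i, year in enumerate(self.years):
                result = nep_mod.nep(self.npp[i], self.temperature[i],
                                     self.precipitation[i], self.soc,
                                     precip_unit=self.precip_unit)
                vals = result.nep.filled(np.nan)
                vals[np.isnan(water[i].values)] = np.nan  # mask open water
                grids.append(result.nep.like(vals))
            self._cache["nep"] = AnnualStack(list(self.years), grids)
        return self._cache["nep"]

    def cb_stack(self) -> AnnualStack:
        if "cb" not in self._cache:
            self._cache["cb"] = balance.carbon_balance_stack(
                self.storage_stack(), self.nep_stack())
        return self._cache["cb"]


def run_pipeline(config, outdir: str | Path, seed: int | None = None,
                 log_level: str = "INFO") -> dict:
    """Run the configured stages; returns the JSON-serialisable run log."""
    logging.basicConfig(level=getattr(logging, log_level.upper(), logging.INFO))
    cfg = _load_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages = list(cfg.get("stages", ["report"]))
    unknown = [s for s in stages if s not in STAGES]
    if unknown:
        raise ValueError(f"unknown stages {unknown}; valid: {STAGES}")
    if "report" in stages:
        stages = [s for s in STAGES if s != "report"]

    data = _Data(cfg, seed)
    outputs: list[str] = []

    def _write(grid, name):
        p = write_grid(grid, outdir / name)
        outputs.append(str(p))

    def _csv(frame: pd.DataFrame, name: str):
        p = outdir / name
        frame.to_csv(p)
        outputs.append(str(p))

    if "simulate" in stages:
        if data.scene is None:
            raise ValueError("'simulate' stage requires synthetic-scene config")
        paths = data.scene.write(outdir / "scene")
        outputs.append(str(outdir / "scene"))
        logger.info("simulated scene with seed %d", data.seed)

    if "storage" in stages:
        per_year = []
        for year, lulc_grid, dgrid in zip(data.years, data.lulc.grids,
                                          data.storage_stack().grids):
            res = storage.total_storage(lulc_grid, data.density_table,
                                        data.pixel_area_hm2)
            _write(dgrid, f"cs_density_{year}.tif")
            per_year.append({"year": year, "total_Tg": res.total_Tg})
        _csv(pd.DataFrame(per_year).set_index("year"), "storage_by_year.csv")

    if "nep" in stages:
        for year, grid in zip(data.years, data.nep_stack().grids):
            _write(grid, f"nep_{year}.tif")
        rows = []
        for year, grid in zip(data.years, data.nep_stack().grids):
            vals = grid.filled(np.nan)
            mean = float(np.nanmean(vals))
            # regional sink strength: mean NEP (g C m^-2) over the valid area
            area_m2 = np.count_nonzero(~np.isnan(vals)) * data.pixel_area_hm2 * 1e4
            rows.append({"year": year, "mean_g_C_m2": mean,
                         "total_Tg_C": mean * area_m2 / 1e12})
        _csv(pd.DataFrame(rows).set_index("year"), "nep_by_year.csv")

    if "balance" in stages:
        cb = data.cb_stack()
        for year, grid in zip(cb.years, cb.grids):
            _write(grid, f"cb_{year}.tif")
        windows = [tuple(w) for w in data.cfg.get("windows", [])]
        summary = balance.interannual_summary(cb, data.lulc,
                                              data.pixel_area_hm2,
                                              windows=windows)
        _csv(summary.yearly.join(summary.per_class), "interannual.csv")
        if not summary.window_slopes.empty:
            _csv(summary.window_slopes, "window_slopes.csv")

    if "trend" in stages:
        res = trend.trend_stack(data.cb_stack())
        _write(res.slope, "cb_slope.tif")
        _write(res.p, "cb_pvalue.tif")
        _write(res.klass, "cb_trend_class.tif")
        legend = {c.value: c.name for c in trend.TrendClass}
        (outdir / "trend_class_legend.json").write_text(json.dumps(legend))
        _csv(trend.trend_summary(res.klass, data.pixel_area_km2).table,
             "trend_summary.csv")

    if "corr" in stages:
        pairs = {"temperature": (data.temperature, data.precipitation),
                 "precipitation": (data.precipitation, data.temperature)}
        for var, (climate, control) in pairs.items():
            maps = correlation.correlation_maps(data.cb_stack(), climate, control)
            _write(maps.r_partial, f"pcor_{var}.tif")
            _write(maps.klass, f"pcor_{var}_class.tif")
            _csv(correlation.correlation_summary(maps, data.pixel_area_km2),
                 f"pcor_{var}_summary.csv")
        legend = {c.value: c.name for c in correlation.CorrelationClass}
        (outdir / "corr_class_legend.json").write_text(json.dumps(legend))

    if "attribute" in stages:
        maps = attribution.attribute_stack(data.cb_stack(), data.temperature,
                                           data.precipitation)
        _write(maps.slope_cc, "cbcc_slope.tif")
        _write(maps.slope_ha, "cbha_slope.tif")
        _write(maps.scenario, "scenario.tif")
        _write(maps.contrib_cc, "contrib_cc.tif")
        _write(maps.contrib_ha, "contrib_ha.tif")
        _csv(attribution.attribution_summary(maps, data.pixel_area_km2),
             "attribution_summary.csv")

    if "geodetect" in stages:
        cb = data.cb_stack()
        det_years = data.cfg.get("geodetect_years", [cb.years[0], cb.years[-1]])
        y_by_year = {y: cb.grid_for(y) for y in det_years}
        factors: dict[str, dict] = {}
        for name, grid in data.covariates.items():
            factors[name] = {"grid": grid,
                             "categorical": name in {"vegetation_type", "soil_type"}}
        factors["land_use"] = {"grid": {y: data.lulc.grid_for(y) for y in det_years},
                               "categorical": True}
        factors["temperature"] = {"grid": {y: data.temperature.grid_for(y)
                                           for y in det_years}}
        factors["precipitation"] = {"grid": {y: data.precipitation.grid_for(y)
                                             for y in det_years}}
        q_table, inter = geodetector.factor_report(y_by_year, factors)
        _csv(q_table.set_index(["factor", "year"]), "q_table.csv")
        for year, mat in inter.items():
            _csv(mat, f"interaction_matrix_{year}.csv")

    if "transfer" in stages:
        tm = storage.transfer_matrix(data.lulc.grids[0], data.lulc.grids[-1],
                                     data.pixel_area_km2)
        p = outdir / f"transfer_{data.years[0]}_{data.years[-1]}.csv"
        tm.to_csv(p)
        outputs.append(str(p))

    run_log = {
        "seed": data.seed,
        "stages": stages,
        "years": data.years,
        "pixel_area_hm2": data.pixel_area_hm2,
        "versions": {"tercab": tercab.__version__, "numpy": np.__version__,
                     "pandas": pd.__version__, "python": platform.python_version()},
        "config": {k: v for k, v in cfg.items() if k != "inputs"},
        "outputs": sorted(outputs),
    }
    (outdir / "run_log.json").write_text(json.dumps(run_log, indent=2, default=str))
    return run_log
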