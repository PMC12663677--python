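"""Synthetic multi-year raster scenes with known ground truth.

Scenes emulate the statistical structure the analysis stages assume:
land cover evolving by per-pixel Markov transitions plus deterministic
"human disturbance" patch overrides, smooth climate fields (elevation
lapse on temperature) with configurable linear trends and Gaussian noise,
NPP responding linearly to climate, a static log-normal soil-carbon field,
and static covariate grids for the factor-detection stage. Everything is
reproducible from one root seed; each variable draws from its own child
stream so adding a variable never perturbs the others.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from tercab.gridio import AnnualStack, Grid, GridTransform, write_grid
from tercab.lulc import LULCClass

__all__ = [
    "HumanPatch",
    "SceneConfig",
    "SyntheticScene",
    "generate_scene",
    "inject_climate_signal",
    "persistence_matrix",
]

# fixed child-stream keys so streams are independent of generation order
_STREAMS = {"terrain": 0, "lulc": 1, "temperature": 2, "precipitation": 3,
            "npp": 4, "soc": 5, "covariates": 6}

N_CLASSES = 7
TEMP_LAPSE_PER_M = 0.0065  # deg C per metre of elevation


def persistence_matrix(p_stay: float = 0.995) -> np.ndarray:
    """Markov matrix with uniform leakage to the other six classes."""
    off = (1.0 - p_stay) / (N_CLASSES - 1)
    m = np.full((N_CLASSES, N_CLASSES), off)
    np.fill_diagonal(m, p_stay)
    return m


@dataclass(frozen=True)
class HumanPatch:
    """Deterministic land-cover override applied from ``year`` onward."""

    year: int
    row0: int
    col0: int
    height: int
    width: int
    target_class: int

    @property
    def footprint(self) -> tuple[slice, slice]:
        return (slice(self.row0, self.row0 + self.height),
                slice(self.col0, self.col0 + self.width))


@dataclass
class SceneConfig:
    shape: tuple[int, int] = (48, 64)
    years: list[int] = field(default_factory=lambda: list(range(2000, 2023)))
    pixel_area_hm2: float = 1.0
    class_proportions: tuple = (0.28, 0.55, 0.01, 0.02, 0.05, 0.01, 0.08)
    transition_matrix: np.ndarray = field(default_factory=persistence_matrix)
    climate_base: tuple[float, float] = (24.0, 1.8)   # deg C, m
    climate_trend: tuple[float, float] = (0.02, 0.002)  # per year
    climate_noise_sd: tuple[float, float] = (0.3, 0.08)
    npp_coefficients: tuple = (200.0, 20.0, 150.0, 30.0)  # c0, c1 (per degC), c2 (per m), noise sd
    soc_field: tuple[float, float] = (4.5, 1.5)  # mean, sd (kg C m^-2)
    human_patches: list[HumanPatch] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        self.transition_matrix = np.asarray(self.transition_matrix, dtype=float)
        if self.transition_matrix.shape != (N_CLASSES, N_CLASSES):
            raise ValueError("transition matrix must be 7x7")
        if (self.transition_matrix < 0).any() or not np.allclose(
                self.transition_matrix.sum(axis=1), 1.0, atol=1e-8):
            raise ValueError("transition matrix rows must be non-negative and sum to 1")
        props = np.asarray(self.class_proportions, dtype=float)
        if props.shape != (N_CLASSES,) or not np.isclose(props.sum(), 1.0, atol=1e-8):
            raise ValueError("class proportions must be 7 values summing to 1")
        if any(sd < 0 for sd in self.climate_noise_sd) or self.npp_coefficients[3] < 0:
            raise ValueError("noise standard deviations must be >= 0")
        self.human_patches = [
            p if isinstance(p, HumanPatch) else HumanPatch(**p)
            for p in self.human_patches
        ]
        rows, cols = self.shape
        for p in self.human_patches:
            if not (0 <= p.row0 and p.row0 + p.height <= rows
                    and 0 <= p.col0 and p.col0 + p.width <= cols):
                raise ValueError(f"patch {p} exceeds grid shape {self.shape}")

    @classmethod
    def from_dict(cls, d: dict) -> "SceneConfig":
        d = dict(d)
        if "shape" in d:
            d["shape"] = tuple(d["shape"])
        if "transition_matrix" in d:
            d["transition_matrix"] = np.asarray(d["transition_matrix"], dtype=float)
        return cls(**d)


@dataclass
class SyntheticScene:
    config: SceneConfig
    lulc: AnnualStack
    temperature: AnnualStack
    precipitation: AnnualStack
    npp: AnnualStack
    soc: Grid
    covariates: dict[str, Grid]
    truth: dict

    def write(self, outdir: str | Path) -> dict:
        """Write all stacks/grids as rasters plus ``truth.json``; returns paths."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths: dict[str, object] = {}
        for name in ("lulc", "temperature", "precipitation", "npp"):
            stack: AnnualStack = getattr(self, name)
            paths[name] = {}
            for year, grid in zip(stack.years, stack.grids):
                p = outdir / f"{name}_{year}.tif"
                write_grid(grid, p)
                paths[name][year] = str(p)
        paths["soc"] = str(write_grid(self.soc, outdir / "soc.tif"))
        for cname, grid in self.covariates.items():
            paths[f"cov_{cname}"] = str(write_grid(grid, outdir / f"cov_{cname}.tif"))
        truth_path = outdir / "truth.json"
        truth_path.write_text(json.dumps(self.truth, indent=2))
        paths["truth"] = str(truth_path)
        return paths


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((seed, _STREAMS[stream])))


def _smooth_field(rng: np.random.Generator, shape: tuple[int, int]) -> np.ndarray:
    """Zero-mean, unit-sd smooth field from a random 2-D quadratic."""
    rows, cols = shape
    yy, xx = np.meshgrid(np.linspace(-1, 1, rows), np.linspace(-1, 1, cols),
                         indexing="ij")
    terms = [xx, yy, xx * yy, xx ** 2, yy ** 2]
    coeffs = rng.normal(size=len(terms))
    f = sum(c * t for c, t in zip(coeffs, terms))
    f = f - f.mean()
    sd = f.std()
    return f / sd if sd > 0 else f


def generate_scene(config: SceneConfig) -> SyntheticScene:
    """Generate a full multi-year scene; bit-reproducible from the seed."""
    shape = config.shape
    years = list(config.years)
    n_years = len(years)
    transform = GridTransform.unit()
    template = Grid(np.zeros(shape), transform=transform, crs="synthetic")

    # terrain and static covariates
    t_rng = _rng(config.seed, "terrain")
    elev = 800.0 * np.abs(_smooth_field(t_rng, shape)) + 50.0
    grad_r, grad_c = np.gradient(elev)
    slope = np.degrees(np.arctan(np.hypot(grad_r, grad_c) / 100.0))
    aspect = np.degrees(np.arctan2(-grad_r, grad_c)) % 360.0

    # temperature: base - lapse * elevation + spatial field + trend + noise
    T_rng = _rng(config.seed, "temperature")
    t_base, p_base = config.climate_base
    t_trend, p_trend = config.climate_trend
    t_sd, p_sd = config.climate_noise_sd
    t_spatial = 0.5 * _smooth_field(T_rng, shape)
    temp = np.empty((n_years, *shape))
    for i in range(n_years):
        temp[i] = (t_base - TEMP_LAPSE_PER_M * elev + t_spatial + t_trend * i
                   + T_rng.normal(0.0, t_sd, size=shape) if t_sd > 0
                   else t_base - TEMP_LAPSE_PER_M * elev + t_spatial + t_trend * i)

    P_rng = _rng(config.seed, "precipitation")
    p_spatial = 0.25 * _smooth_field(P_rng, shape)
    precip = np.empty((n_years, *shape))
    for i in range(n_years):
        noise = P_rng.normal(0.0, p_sd, size=shape) if p_sd > 0 else 0.0
        precip[i] = np.maximum(p_base + p_spatial + p_trend * i + noise, 0.0)

    # NPP = c0 + c1*T + c2*P + noise, clipped at 0
    npp_rng = _rng(config.seed, "npp")
    c0, c1, c2, npp_sd = config.npp_coefficients
    npp = np.empty((n_years, *shape))
    for i in range(n_years):
        noise = npp_rng.normal(0.0, npp_sd, size=shape) if npp_sd > 0 else 0.0
        npp[i] = np.maximum(c0 + c1 * temp[i] + c2 * precip[i] + noise, 0.0)

    # static log-normal SOC field
    soc_rng = _rng(config.seed, "soc")
    mean, sd = config.soc_field
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    soc_std_field = 0.7 * _smooth_field(soc_rng, shape) + \
        0.7 * soc_rng.standard_normal(shape)
    soc = np.exp(mu + np.sqrt(sigma2) * soc_std_field)

    # land cover: initial draw, yearly Markov step, patch overrides
    l_rng = _rng(config.seed, "lulc")
    codes = np.array([c.value for c in LULCClass])
    lulc = np.empty((n_years, *shape), dtype=np.int16)
    lulc[0] = l_rng.choice(codes, p=np.asarray(config.class_proportions), size=shape)
    cum = np.cumsum(config.transition_matrix, axis=1)
    identity = np.allclose(config.transition_matrix, np.eye(N_CLASSES))
    for i in range(1, n_years):
        if identity:
            lulc[i] = lulc[i - 1]
        else:
            u = l_rng.random(size=shape)
            new = np.empty(shape, dtype=np.int16)
            for ci, code in enumerate(codes):
                sel = lulc[i - 1] == code
                if sel.any():
                    new[sel] = codes[np.searchsorted(cum[ci], u[sel], side="right")
                                     .clip(0, N_CLASSES - 1)]
            lulc[i] = new
    for patch in config.human_patches:
        for i, year in enumerate(years):
            if year >= patch.year:
                lulc[i][patch.footprint] = patch.target_class

    cov_rng = _rng(config.seed, "covariates")
    veg_type = np.digitize(elev + 100.0 * cov_rng.standard_normal(shape),
                           np.quantile(elev, [0.25, 0.5, 0.75])) + 1
    soil_type = np.digitize(_smooth_field(cov_rng, shape),
                            [-0.8, -0.3, 0.3, 0.8]) + 1
    erosion = np.abs(_smooth_field(cov_rng, shape)) * 2.0
    population = np.exp(1.5 * _smooth_field(cov_rng, shape) - elev / 500.0) * 100.0
    gdp = population * np.exp(0.5 * cov_rng.standard_normal(shape))
    covariates = {
        "elevation": template.like(elev),
        "slope": template.like(slope),
        "aspect": template.like(aspect),
        "vegetation_type": template.like(veg_type.astype(np.int16)),
        "soil_type": template.like(soil_type.astype(np.int16)),
        "soil_erosion": template.like(erosion),
        "population": template.like(population),
        "gdp": template.like(gdp),
    }

    truth = {
        "seed": config.seed,
        "temperature_trend_per_yr": t_trend,
        "precipitation_trend_per_yr": p_trend,
        "npp_coefficients": list(config.npp_coefficients[:3]),
        "patches": [
            {**dataclasses.asdict(p), "n_pixels": p.height * p.width}
            for p in config.human_patches
        ],
    }
    return SyntheticScene(
        config=config,
        lulc=AnnualStack.from_array(years, lulc, template, nodata=0),
        temperature=AnnualStack.from_array(years, temp, template),
        precipitation=AnnualStack.from_array(years, precip, template),
        npp=AnnualStack.from_array(years, npp, template),
        soc=template.like(soc),
        covariates=covariates,
        truth=truth,
    )


def inject_climate_signal(scene: SyntheticScene, a: float, b: float,
                          c: float) -> AnnualStack:
    """Carbon-balance-like stack built exactly as a*T + b*P + c per
    pixel-year (no residual), for attribution recovery tests."""
    grids = [
        t.like(a * t.filled(np.nan) + b * p.filled(np.nan) + c)
        for t, p in zip(scene.temperature.grids, scene.precipitation.grids)
    ]
    return AnnualStack(list(scene.temperature.years), grids)
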