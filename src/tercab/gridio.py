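"""Grid containers, raster I/O and nearest-neighbour alignment.

Rasters are stored as single-band TIFF files with a JSON sidecar
(``<file>.aux.json``) carrying the affine georeference, CRS identifier and
nodata sentinel, or as ESRI ASCII grids (``.asc``) which are self-describing.
All analysis operations require co-registered grids (identical shape,
transform and CRS); :func:`align_stack` resamples onto a common target by
nearest neighbour, which never invents class codes.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, NamedTuple, Sequence

import numpy as np
import tifffile

__all__ = [
    "GridTransform",
    "Grid",
    "AnnualStack",
    "read_grid",
    "write_grid",
    "align_stack",
    "ensure_coregistered",
]


class GridTransform(NamedTuple):
    """Affine georeference with top-left origin and axis-aligned pixels.

    Cell ``(row, col)`` has its centre at
    ``(x0 + (col + 0.5) * dx, y0 - (row + 0.5) * dy)``; ``dx, dy > 0``.
    """

    x0: float
    y0: float
    dx: float
    dy: float

    @classmethod
    def unit(cls) -> "GridTransform":
        return cls(0.0, 0.0, 1.0, 1.0)

    def cell_center(self, row, col):
        return (self.x0 + (np.asarray(col) + 0.5) * self.dx,
                self.y0 - (np.asarray(row) + 0.5) * self.dy)

    def index_of(self, x, y):
        """Row/col indices of the cells containing points ``(x, y)``."""
        col = np.floor((np.asarray(x) - self.x0) / self.dx).astype(int)
        row = np.floor((self.y0 - np.asarray(y)) / self.dy).astype(int)
        return row, col


@dataclass
class Grid:
    """A single-band 2-D raster with nodata sentinel and georeference."""

    values: np.ndarray
    nodata: float | int | None = None
    transform: GridTransform = field(default_factory=GridTransform.unit)
    crs: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError(f"Grid values must be 2-D, got shape {self.values.shape}")
        if not isinstance(self.transform, GridTransform):
            self.transform = GridTransform(*self.transform)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def mask(self) -> np.ndarray:
        """Boolean array, True where the cell is nodata."""
        if self.nodata is None:
            if np.issubdtype(self.values.dtype, np.floating):
                return np.isnan(self.values)
            return np.zeros(self.shape, dtype=bool)
        m = self.values == self.nodata
        if np.issubdtype(self.values.dtype, np.floating):
            m |= np.isnan(self.values)
        return m

    @property
    def valid(self) -> np.ndarray:
        return ~self.mask

    def filled(self, fill: float = np.nan) -> np.ndarray:
        """Float copy of the values with nodata cells replaced by ``fill``."""
        out = self.values.astype(float, copy=True)
        out[self.mask] = fill
        return out

    def like(self, values: np.ndarray, nodata: float | int | None = None) -> "Grid":
        """New grid sharing this grid's georeference."""
        values = np.asarray(values)
        if values.shape != self.shape:
            raise ValueError(f"shape {values.shape} != grid shape {self.shape}")
        return Grid(values, nodata=nodata, transform=self.transform, crs=self.crs)

    def coregistered_with(self, other: "Grid") -> bool:
        return (self.shape == other.shape
                and np.allclose(self.transform, other.transform)
                and self.crs == other.crs)


def ensure_coregistered(*grids: Grid) -> None:
    """Raise ``ValueError`` unless all grids share shape, transform and CRS."""
    first = grids[0]
    for g in grids[1:]:
        if not first.coregistered_with(g):
            raise ValueError(
                "grids are not co-registered: "
                f"{first.shape}/{first.transform} vs {g.shape}/{g.transform}"
            )


def _sidecar_path(path: Path) -> Path:
    return Path(str(path) + ".aux.json")


def read_grid(path: str | Path, band: int = 1) -> Grid:
    """Read a raster from TIFF (+ JSON sidecar) or ESRI ASCII grid.

    Values are returned unchanged (no rescaling). A missing georeference
    triggers a warning and a unit-square transform is assumed.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() == ".asc":
        return _read_ascii_grid(path)

    arr = tifffile.imread(path)
    if arr.ndim == 3:  # band-interleaved (band, row, col)
        arr = arr[band - 1]
    elif arr.ndim != 2:
        raise ValueError(f"unsupported raster dimensionality {arr.ndim} in {path}")

    sidecar = _sidecar_path(path)
    transform = GridTransform.unit()
    crs = None
    nodata = None
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        if meta.get("transform") is not None:
            transform = GridTransform(*meta["transform"])
        crs = meta.get("crs")
        nodata = meta.get("nodata")
    if crs is None:
        warnings.warn(f"{path}: no CRS recorded; assuming unit-square transform",
                      stacklevel=2)
    return Grid(arr, nodata=nodata, transform=transform, crs=crs)


def write_grid(grid: Grid, path: str | Path) -> Path:
    """Write a grid as TIFF + JSON sidecar (or ``.asc`` ASCII grid)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix.lower() == ".asc":
        _write_ascii_grid(grid, path)
        return path
    tifffile.imwrite(path, grid.values)
    meta = {
        "transform": list(grid.transform),
        "crs": grid.crs,
        "nodata": None if grid.nodata is None else float(grid.nodata)
        if np.issubdtype(type(grid.nodata), np.floating) else grid.nodata,
    }
    _sidecar_path(path).write_text(json.dumps(meta))
    return path


def _read_ascii_grid(path: Path) -> Grid:
    header: dict[str, float] = {}
    with open(path) as fh:
        lines = fh.readlines()
    n_header = 0
    for line in lines:
        parts = line.split()
        if len(parts) == 2 and parts[0].lower() in {
                "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value"}:
            header[parts[0].lower()] = float(parts[1])
            n_header += 1
        else:
            break
    values = np.loadtxt(lines[n_header:])
    values = np.atleast_2d(values)
    cell = header.get("cellsize", 1.0)
    nrows = int(header.get("nrows", values.shape[0]))
    transform = GridTransform(
        header.get("xllcorner", 0.0),
        header.get("yllcorner", 0.0) + nrows * cell,
        cell, cell,
    )
    return Grid(values, nodata=header.get("nodata_value"), transform=transform, crs=None)


def _write_ascii_grid(grid: Grid, path: Path) -> None:
    t = grid.transform
    if not np.isclose(t.dx, t.dy):
        raise ValueError("ASCII grids require square cells")
    nodata = grid.nodata if grid.nodata is not None else -9999
    nrows, ncols = grid.shape
    with open(path, "w") as fh:
        fh.write(f"ncols {ncols}\nnrows {nrows}\n")
        fh.write(f"xllcorner {t.x0}\nyllcorner {t.y0 - nrows * t.dy}\n")
        fh.write(f"cellsize {t.dx}\nNODATA_value {nodata}\n")
        np.savetxt(fh, grid.values, fmt="%.10g")


def _default_nodata(dtype: np.dtype) -> float | int:
    if np.issubdtype(dtype, np.floating):
        return np.nan
    return -9999


def align_stack(grids: Sequence[Grid], target: Grid,
                method: str = "nearest") -> list[Grid]:
    """Resample grids onto the target's shape/transform by nearest neighbour.

    Class-code grids are safe: output values are always drawn from the
    source, never interpolated. Cells outside a source's extent become
    nodata. Raises if a source does not overlap the target at all.
    """
    if method != "nearest":
        raise ValueError(f"unsupported resampling method {method!r}")
    rows, cols = np.indices(target.shape)
    x, y = target.transform.cell_center(rows, cols)
    out: list[Grid] = []
    for g in grids:
        if g.coregistered_with(target):
            out.append(Grid(g.values.copy(), nodata=g.nodata,
                            transform=target.transform, crs=target.crs))
            continue
        r, c = g.transform.index_of(x, y)
        inside = (r >= 0) & (r < g.shape[0]) & (c >= 0) & (c < g.shape[1])
        if not inside.any():
            raise ValueError("source grid extent does not overlap target extent")
        nodata = g.nodata if g.nodata is not None else _default_nodata(g.values.dtype)
        dtype = g.values.dtype
        if nodata is np.nan and not np.issubdtype(dtype, np.floating):
            dtype = np.dtype(float)
        values = np.full(target.shape, nodata, dtype=dtype)
        values[inside] = g.values[r[inside], c[inside]]
        out.append(Grid(values, nodata=None if nodata is np.nan else nodata,
                        transform=target.transform, crs=target.crs))
    return out


@dataclass
class AnnualStack:
    """An ordered multi-year series of co-registered grids of one variable."""

    years: list[int]
    grids: list[Grid]

    def __post_init__(self) -> None:
        self.years = [int(y) for y in self.years]
        if len(self.years) != len(self.grids):
            raise ValueError("years and grids must have equal length")
        if any(b <= a for a, b in zip(self.years, self.years[1:])):
            raise ValueError(f"years must be strictly increasing: {self.years}")
        if self.grids:
            ensure_coregistered(*self.grids)

    def __len__(self) -> int:
        return len(self.years)

    def __getitem__(self, i: int) -> Grid:
        return self.grids[i]

    def grid_for(self, year: int) -> Grid:
        return self.grids[self.years.index(year)]

    @property
    def template(self) -> Grid:
        return self.grids[0]

    def to_array(self) -> np.ndarray:
        """(n_years, rows, cols) float array with NaN at nodata cells."""
        return np.stack([g.filled(np.nan) for g in self.grids])

    def combined_mask(self) -> np.ndarray:
        """True where the pixel is nodata in *any* year (excluded everywhere)."""
        m = np.zeros(self.template.shape, dtype=bool)
        for g in self.grids:
            m |= g.mask
        return m

    @classmethod
    def from_array(cls, years: Sequence[int], arr: np.ndarray,
                   template: Grid, nodata: float | int | None = None) -> "AnnualStack":
        if arr.shape[0] != len(years):
            raise ValueError("leading axis of array must match years")
        grids = [template.like(arr[i], nodata=nodata) for i in range(len(years))]
        return cls(list(years), grids)

    def map(self, func: Callable[[np.ndarray], np.ndarray],
            nodata: float | int | None = None) -> "AnnualStack":
        grids = [g.like(func(g.filled(np.nan)), nodata=nodata) for g in self.grids]
        return AnnualStack(list(self.years), grids)
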