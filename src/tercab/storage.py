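"""Land-use carbon storage bookkeeping and transfer-matrix accounting.

Carbon storage is the sum over land-use classes of class area times the
class's total carbon density (aboveground + belowground + soil organic +
dead organic pools, Mg/hm^2). Densities are constant per class and year;
change in storage is driven purely by land-use transitions, which the
transfer matrix tabulates as class-by-class areas between two years.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from tercab import reference_tables
from tercab.gridio import Grid, ensure_coregistered
from tercab.lulc import CLASS_NAMES

__all__ = [
    "CarbonDensityTable",
    "StorageResult",
    "TransferMatrix",
    "density_map",
    "total_storage",
    "transfer_matrix",
]

MG_PER_TG = 1e6
POOLS = ("Ca", "Cb", "Cs", "Cd")


@dataclass(frozen=True)
class CarbonDensityTable:
    """Per-class four-pool carbon densities (Mg/hm^2)."""

    frame: pd.DataFrame  # index: class code; columns Ca, Cb, Cs, Cd (+ name)

    def __post_init__(self) -> None:
        missing = [p for p in POOLS if p not in self.frame.columns]
        if missing:
            raise ValueError(f"density table missing pool columns {missing}")
        if (self.frame[list(POOLS)] < 0).any().any():
            raise ValueError("carbon densities must be non-negative")

    @property
    def codes(self) -> list[int]:
        return [int(c) for c in self.frame.index]

    def name_of(self, code: int) -> str:
        if "name" in self.frame.columns:
            return str(self.frame.loc[code, "name"])
        return CLASS_NAMES.get(int(code), str(code))

    def total_density(self, code: int) -> float:
        """Sum of the four pools for one class (Mg/hm^2)."""
        if code not in self.frame.index:
            raise KeyError(f"no carbon density row for class code {code}")
        return float(self.frame.loc[code, list(POOLS)].sum())

    @classmethod
    def from_csv(cls, path: str | Path) -> "CarbonDensityTable":
        df = pd.read_csv(path)
        if "class" in df.columns:
            df = df.set_index("class")
        return cls(df)

    @classmethod
    def default(cls) -> "CarbonDensityTable":
        """Published default densities for the seven-class dictionary."""
        return cls(reference_tables.load_carbon_density_frame().set_index("class"))


def density_map(lulc: Grid, table: CarbonDensityTable) -> Grid:
    """Per-pixel total carbon density (Mg/hm^2) looked up by class code."""
    codes = lulc.values
    valid = lulc.valid
    present = np.unique(codes[valid])
    unknown = [int(c) for c in present if int(c) not in table.frame.index]
    if unknown:
        raise KeyError(f"no carbon density row for class code(s) {unknown}")
    out = np.full(lulc.shape, np.nan)
    for code in present:
        out[valid & (codes == code)] = table.total_density(int(code))
    return lulc.like(out)


@dataclass
class StorageResult:
    """Carbon storage decomposed by class plus the per-pixel density map."""

    density: Grid  # Mg/hm^2
    per_class: pd.DataFrame  # index: class code; area_hm2, density_Mg_per_hm2, storage_Tg
    total_Tg: float


def total_storage(lulc: Grid, table: CarbonDensityTable,
                  pixel_area_hm2: float) -> StorageResult:
    """Total and per-class carbon storage (Tg) of one land-use grid."""
    if pixel_area_hm2 <= 0:
        raise ValueError("pixel_area_hm2 must be positive")
    valid = lulc.valid
    if not valid.any():
        raise ValueError("land-use grid has no valid pixels")
    dmap = density_map(lulc, table)
    rows = []
    for code in np.unique(lulc.values[valid]):
        code = int(code)
        count = int(np.count_nonzero(valid & (lulc.values == code)))
        area = count * pixel_area_hm2
        dens = table.total_density(code)
        rows.append({
            "class": code,
            "name": table.name_of(code),
            "area_hm2": area,
            "density_Mg_per_hm2": dens,
            "storage_Tg": area * dens / MG_PER_TG,
        })
    per_class = pd.DataFrame(rows).set_index("class")
    return StorageResult(density=dmap, per_class=per_class,
                         total_Tg=float(per_class["storage_Tg"].sum()))


@dataclass
class TransferMatrix:
    """Class-by-class transition areas between a start and an end year.

    ``matrix`` is in km^2 with start-year classes on the rows and end-year
    classes on the columns; the diagonal is unchanged area.
    """

    matrix: pd.DataFrame
    excluded_area_km2: float = 0.0  # pixels nodata in either year

    @property
    def grand_total(self) -> float:
        return float(self.matrix.to_numpy().sum())

    @property
    def row_totals(self) -> pd.Series:
        return self.matrix.sum(axis=1)

    @property
    def col_totals(self) -> pd.Series:
        return self.matrix.sum(axis=0)

    def loss(self, klass) -> float:
        """Area of ``klass`` converted to any other class (row off-diagonal)."""
        return float(self.matrix.loc[klass].sum() - self.matrix.loc[klass, klass])

    def gain(self, klass) -> float:
        """Area converted to ``klass`` from any other class (column off-diagonal)."""
        return float(self.matrix[klass].sum() - self.matrix.loc[klass, klass])

    @property
    def total_change(self) -> float:
        """Total changed area: sum of every off-diagonal cell."""
        m = self.matrix.to_numpy(dtype=float)
        return float(m[~np.eye(m.shape[0], dtype=bool)].sum())

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "TransferMatrix":
        if list(df.index) != list(df.columns):
            raise ValueError("transfer matrix requires identical row/column classes")
        if (df.to_numpy() < 0).any():
            raise ValueError("transfer areas must be non-negative")
        return cls(df.astype(float))

    def to_csv(self, path: str | Path) -> None:
        out = self.matrix.copy()
        out["total"] = self.row_totals
        out.loc["total"] = list(self.col_totals) + [self.grand_total]
        out.to_csv(path)


def transfer_matrix(lulc_start: Grid, lulc_end: Grid,
                    pixel_area_km2: float) -> TransferMatrix:
    """Tabulate per-class transition areas between two co-registered grids.

    Pixels nodata in either year are excluded and reported separately so
    that the grand total matches the commonly mapped area of both years.
    """
    ensure_coregistered(lulc_start, lulc_end)
    both = lulc_start.valid & lulc_end.valid
    start = lulc_start.values[both].astype(int)
    end = lulc_end.values[both].astype(int)
    classes = sorted(set(np.unique(start)) | set(np.unique(end)))
    index = pd.Index([CLASS_NAMES.get(c, str(c)) for c in classes], name="class")
    counts = np.zeros((len(classes), len(classes)), dtype=np.int64)
    pos = {c: i for i, c in enumerate(classes)}
    np.add.at(counts, (np.vectorize(pos.get)(start), np.vectorize(pos.get)(end)), 1)
    matrix = pd.DataFrame(counts * pixel_area_km2, index=index, columns=index)
    excluded = float(np.count_nonzero(~both)) * pixel_area_km2
    return TransferMatrix(matrix, excluded_area_km2=excluded)
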