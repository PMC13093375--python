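"""Shared grid data model.

Every layer in an analysis lives on one :class:`Grid`: a regular raster whose
cell (0, 0) is the upper-left corner. Cell centers are at
``origin_x + (col + 0.5) * cell_size`` and ``origin_y - (row + 0.5) * cell_size``
(y decreases with row, the usual raster convention). Coordinates are either
kilometres on a projected plane (synthetic mode) or the units of a projected
CRS in real mode; operations that measure distance refuse geographic degrees.

Nodata is represented internally as NaN; the ``nodata`` sentinel only appears
in files.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np

__all__ = [
    "Grid",
    "RasterLayer",
    "MaskLayer",
    "TimeSliceStack",
    "OccurrenceSet",
    "GridMismatchError",
    "require_same_grid",
]

#: Roles a binary mask may play downstream.
MASK_ROLES = ("range", "refugium", "protected_area", "forest_cover", "study_area")

#: Minimum number of unique occurrence records for a species to be modelable.
MIN_MODELABLE_RECORDS = 10


class GridMismatchError(ValueError):
    """Raised when two layers do not share bitwise-identical grid geometry."""


@dataclass(frozen=True)
class Grid:
    """Geometry shared by all raster layers of one analysis."""

    n_rows: int
    n_cols: int
    origin_x: float = 0.0
    origin_y: float = 0.0
    cell_size: float = 4.5
    nodata: float = -9999.0
    crs_tag: str = "synthetic-cartesian"
    units: str = "km"

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and one column")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def is_metric(self) -> bool:
        return self.units in ("km", "m")

    @property
    def cell_size_km(self) -> float:
        if self.units == "km":
            return self.cell_size
        if self.units == "m":
            return self.cell_size / 1000.0
        raise ValueError(
            f"grid units {self.units!r} are not metric; distance operations "
            "require a projected metric CRS"
        )

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) center coordinates as two ``(n_rows, n_cols)`` arrays."""
        cols = np.arange(self.n_cols)
        rows = np.arange(self.n_rows)
        x = self.origin_x + (cols + 0.5) * self.cell_size
        y = self.origin_y - (rows + 0.5) * self.cell_size
        return np.meshgrid(x, y)

    def center_of(self, row: int, col: int) -> tuple[float, float]:
        return (
            self.origin_x + (col + 0.5) * self.cell_size,
            self.origin_y - (row + 0.5) * self.cell_size,
        )

    def cell_of(self, x: float, y: float) -> tuple[int, int]:
        """Row/col of the cell containing point (x, y). No bounds clipping."""
        col = int(np.floor((x - self.origin_x) / self.cell_size))
        row = int(np.floor((self.origin_y - y) / self.cell_size))
        return row, col

    def contains(self, x: float, y: float) -> bool:
        row, col = self.cell_of(x, y)
        return 0 <= row < self.n_rows and 0 <= col < self.n_cols


def require_same_grid(a: "Grid", b: "Grid", what: str = "layer") -> None:
    if a != b:
        raise GridMismatchError(f"{what} grid {b} does not match reference grid {a}")


@dataclass
class RasterLayer:
    """A single-variable raster on a :class:`Grid`. NaN marks nodata."""

    grid: Grid
    values: np.ndarray
    variable: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"values shape {self.values.shape} does not match grid {self.grid.shape}"
            )

    @property
    def valid(self) -> np.ndarray:
        return ~np.isnan(self.values)

    def mean(self) -> float:
        """Mean over non-nodata cells."""
        return float(np.nanmean(self.values))

    def copy(self, values: np.ndarray | None = None, variable: str | None = None) -> "RasterLayer":
        return RasterLayer(
            grid=self.grid,
            values=self.values.copy() if values is None else np.asarray(values, dtype=float),
            variable=self.variable if variable is None else variable,
        )


@dataclass
class MaskLayer:
    """Binary (0/1, NaN-nodata) raster with a declared role."""

    grid: Grid
    values: np.ndarray
    role: str = "study_area"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError("mask shape does not match grid")
        if self.role not in MASK_ROLES:
            raise ValueError(f"unknown mask role {self.role!r}; expected one of {MASK_ROLES}")
        finite = self.values[~np.isnan(self.values)]
        if finite.size and not np.isin(finite, (0.0, 1.0)).all():
            raise ValueError("mask values must be 0, 1 or nodata")

    @property
    def bool_array(self) -> np.ndarray:
        """Mask as booleans; nodata counts as False."""
        return np.nan_to_num(self.values, nan=0.0) == 1.0

    def count(self) -> int:
        return int(self.bool_array.sum())

    def as_raster(self, variable: str = "") -> RasterLayer:
        return RasterLayer(self.grid, self.values.copy(), variable or self.role)


@dataclass
class TimeSliceStack:
    """Time-ordered paleoclimate layers, one raster per variable per slice.

    ``ages`` are kyr before present, strictly decreasing (oldest first). The
    contemporary (age 0) climate is deliberately not part of the stack: the
    stability statistics are computed from past slices only.
    """

    grid: Grid
    ages: list[float]
    layers: dict[str, list[RasterLayer]]

    def __post_init__(self) -> None:
        ages = list(self.ages)
        if any(a2 >= a1 for a1, a2 in zip(ages, ages[1:])):
            raise ValueError("ages must be strictly decreasing (oldest first)")
        if any(a <= 0 for a in ages):
            raise ValueError("stack ages must be positive (no present-day slice)")
        for var, lays in self.layers.items():
            if len(lays) != len(ages):
                raise ValueError(f"variable {var!r} has {len(lays)} layers for {len(ages)} ages")
            for lay in lays:
                require_same_grid(self.grid, lay.grid, f"slice of {var!r}")
        self.ages = ages

    @property
    def n_slices(self) -> int:
        return len(self.ages)

    @property
    def variables(self) -> list[str]:
        return list(self.layers)

    def slice_climate(self, i: int) -> dict[str, RasterLayer]:
        """All variables of slice ``i`` as a {variable: layer} mapping."""
        return {var: lays[i] for var, lays in self.layers.items()}


@dataclass
class OccurrenceSet:
    """Unique occurrence points of one species, in the grid's CRS."""

    species: str
    points: np.ndarray  # (n, 2) array of x, y

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float).reshape(-1, 2)
        self.points = np.unique(pts, axis=0)

    @property
    def n_unique(self) -> int:
        return int(self.points.shape[0])

    @property
    def modelable(self) -> bool:
        """True when the species has enough unique records (> 10) for an ENM."""
        return self.n_unique > MIN_MODELABLE_RECORDS
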