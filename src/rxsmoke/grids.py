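"""Planar study grid and gridded concentration containers.

The study domain is a regular planar grid (a surrogate for a 4 km
chemical-transport-model projection): cell (i=0, j=0) is the south-west
corner and cell centers sit at ``origin + (index + 0.5) * cell_size``.
Daily fields are stored dense as ``(day, y, x)`` arrays; dates are a
contiguous calendar range shared by every field on the grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import cached_property

import numpy as np
import pandas as pd

__all__ = [
    "GridSpec",
    "ConcentrationField",
    "ScenarioPair",
    "MonitorSeries",
    "PM25",
    "O3",
    "SPECIES_UNITS",
    "DEFAULT_FLOORS",
]

PM25 = "PM2.5"
O3 = "MDA8-O3"

SPECIES_UNITS = {PM25: "ug/m3", O3: "ppb"}

#: model values below these are treated as numerically unreliable denominators
DEFAULT_FLOORS = {PM25: 0.1, O3: 1.0}


@dataclass(frozen=True)
class GridSpec:
    """Regular planar grid plus a daily calendar.

    Coordinates are in km in a planar study projection. ``nx`` counts cells
    along x (west-east), ``ny`` along y (south-north).
    """

    origin_x: float
    origin_y: float
    nx: int
    ny: int
    cell_size: float
    date_start: str
    date_end: str

    def __post_init__(self) -> None:
        if self.nx < 1:
            raise ValueError(f"nx must be >= 1, got {self.nx}")
        if self.ny < 1:
            raise ValueError(f"ny must be >= 1, got {self.ny}")
        if not self.cell_size > 0:
            raise ValueError(f"cell_size must be > 0, got {self.cell_size}")
        start = pd.Timestamp(self.date_start)
        end = pd.Timestamp(self.date_end)
        if end < start:
            raise ValueError(
                f"date range is empty: date_end {self.date_end} precedes "
                f"date_start {self.date_start}"
            )

    @cached_property
    def dates(self) -> pd.DatetimeIndex:
        return pd.date_range(self.date_start, self.date_end, freq="D")

    @property
    def n_days(self) -> int:
        return len(self.dates)

    @property
    def n_cells(self) -> int:
        return self.nx * self.ny

    @cached_property
    def x_centers(self) -> np.ndarray:
        return self.origin_x + (np.arange(self.nx) + 0.5) * self.cell_size

    @cached_property
    def y_centers(self) -> np.ndarray:
        return self.origin_y + (np.arange(self.ny) + 0.5) * self.cell_size

    @cached_property
    def years(self) -> np.ndarray:
        """Calendar year of each day in the range."""
        return self.dates.year.to_numpy()

    @cached_property
    def day_of_year(self) -> np.ndarray:
        return self.dates.dayofyear.to_numpy().astype(float)

    def contains(self, x_km: float, y_km: float) -> bool:
        return (
            self.origin_x <= x_km < self.origin_x + self.nx * self.cell_size
            and self.origin_y <= y_km < self.origin_y + self.ny * self.cell_size
        )

    def cell_of(self, x_km: float, y_km: float) -> tuple[int, int]:
        """Return (iy, ix) of the cell containing a point."""
        if not self.contains(x_km, y_km):
            raise ValueError(f"point ({x_km}, {y_km}) lies outside the grid")
        ix = int((x_km - self.origin_x) // self.cell_size)
        iy = int((y_km - self.origin_y) // self.cell_size)
        return min(iy, self.ny - 1), min(ix, self.nx - 1)

    def cell_center(self, iy: int, ix: int) -> tuple[float, float]:
        return float(self.x_centers[ix]), float(self.y_centers[iy])

    def day_index(self, date) -> int:
        ts = pd.Timestamp(date)
        loc = self.dates.get_loc(ts)
        return int(loc)

    def with_dates(self, date_start: str, date_end: str) -> "GridSpec":
        return replace(self, date_start=date_start, date_end=date_end)


@dataclass
class ConcentrationField:
    """Daily values of one species on a regular grid.

    ``values`` is ``(n_days, ny, nx)``. Total-concentration fields are
    non-negative; burn-impact fields may carry sign (ozone titration can
    reduce MDA8-O3 locally).
    """

    grid: GridSpec
    species: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        expected = (self.grid.n_days, self.grid.ny, self.grid.nx)
        if self.values.shape != expected:
            raise ValueError(
                f"values shape {self.values.shape} does not match grid "
                f"(days, ny, nx) = {expected}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("concentration values must be finite")

    @property
    def units(self) -> str:
        return SPECIES_UNITS.get(self.species, "")

    def like(self, values: np.ndarray) -> "ConcentrationField":
        return ConcentrationField(self.grid, self.species, values)

    def same_frame(self, other: "ConcentrationField") -> bool:
        return self.grid == other.grid and self.species == other.species

    def annual_mean(self, year: int) -> np.ndarray:
        """(ny, nx) mean over the days of one calendar year."""
        mask = self.grid.years == year
        if not mask.any():
            raise ValueError(f"year {year} not in field date range")
        return self.values[mask].mean(axis=0)


@dataclass
class ScenarioPair:
    """Paired all-emissions and no-prescribed-burn simulations."""

    c_all: ConcentrationField
    c_no_pb: ConcentrationField

    def __post_init__(self) -> None:
        if not self.c_all.same_frame(self.c_no_pb):
            raise ValueError("scenario fields must share grid, dates and species")

    @property
    def grid(self) -> GridSpec:
        return self.c_all.grid

    @property
    def species(self) -> str:
        return self.c_all.species


@dataclass
class MonitorSeries:
    """One monitoring site's daily observations, aligned to a grid calendar.

    ``values`` has one entry per day of the owning grid's date range;
    missing observations are NaN.
    """

    site_id: str
    x_km: float
    y_km: float
    species: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("monitor values must be a 1-d daily series")
        if not np.any(np.isfinite(self.values)):
            raise ValueError(f"monitor {self.site_id} has no non-missing values")

    @property
    def n_obs(self) -> int:
        return int(np.isfinite(self.values).sum())


def monitor_cells(monitors: list[MonitorSeries], grid: GridSpec) -> np.ndarray:
    """(n_monitors, 2) array of (iy, ix) containing cells."""
    return np.array([grid.cell_of(m.x_km, m.y_km) for m in monitors], dtype=int)


def collocate(model: ConcentrationField, monitors: list[MonitorSeries]) -> np.ndarray:
    """Model values at monitor cells: (n_monitors, n_days)."""
    cells = monitor_cells(monitors, model.grid)
    return model.values[:, cells[:, 0], cells[:, 1]].T.copy()


def observation_matrix(
    monitors: list[MonitorSeries], grid: GridSpec
) -> np.ndarray:
    """(n_monitors, n_days) observations, NaN where missing."""
    out = np.full((len(monitors), grid.n_days), np.nan)
    for i, m in enumerate(monitors):
        if len(m.values) != grid.n_days:
            raise ValueError(
                f"monitor {m.site_id} series length {len(m.values)} does not "
                f"match grid calendar ({grid.n_days} days)"
            )
        out[i] = m.values
    return out
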