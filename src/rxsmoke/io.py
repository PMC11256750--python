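"""Readers and writers for the pipeline's file dialects.

Tabular artifacts (detections, permits, monitors, county tables, cluster
and estimate tables) are delimited text with headers. Gridded daily fields
are self-describing NetCDF (written through xarray's scipy backend) with a
plain-text fallback of one row-major matrix per day.
"""

from __future__ import annotations

import pathlib

import numpy as np
import pandas as pd
import xarray as xr

from .fires import FireDetection
from .grids import SPECIES_UNITS, ConcentrationField, GridSpec, MonitorSeries
from .fusion import FusionParams
from .synthetic import PermitRecord

__all__ = [
    "write_detections",
    "read_detections",
    "write_permits",
    "read_permits",
    "write_monitors",
    "read_monitors",
    "write_field_netcdf",
    "read_field_netcdf",
    "write_field_text",
    "read_field_text",
    "write_params",
    "read_params",
    "write_county_map",
    "read_county_map",
]

_DET_COLS = ["id", "lon_km", "lat_km", "date", "area_acres", "landcover"]


def write_detections(detections: list[FireDetection], path) -> None:
    df = pd.DataFrame(
        {
            "id": [d.id for d in detections],
            "lon_km": [d.x_km for d in detections],
            "lat_km": [d.y_km for d in detections],
            "date": [d.date.date().isoformat() for d in detections],
            "area_acres": [d.detected_area for d in detections],
            "landcover": [d.landcover for d in detections],
        }
    )
    df.to_csv(path, index=False)


def read_detections(path) -> list[FireDetection]:
    df = pd.read_csv(path, dtype={"id": str})
    missing = set(_DET_COLS) - set(df.columns)
    if missing:
        raise ValueError(f"detection file {path} missing columns: {sorted(missing)}")
    return [
        FireDetection(
            id=row.id,
            x_km=float(row.lon_km),
            y_km=float(row.lat_km),
            date=pd.Timestamp(row.date),
            detected_area=float(row.area_acres),
            landcover=str(row.landcover),
        )
        for row in df.itertuples()
    ]


def write_permits(permits: list[PermitRecord], path) -> None:
    df = pd.DataFrame(
        {
            "id": [p.id for p in permits],
            "lon_km": [p.x_km for p in permits],
            "lat_km": [p.y_km for p in permits],
            "date": [pd.Timestamp(p.date).date().isoformat() for p in permits],
            "area_acres": [p.area_acres for p in permits],
            "landcover": ["" for _ in permits],
        }
    )
    df.to_csv(path, index=False)


def read_permits(path) -> list[PermitRecord]:
    df = pd.read_csv(path, dtype={"id": str})
    return [
        PermitRecord(
            id=row.id,
            x_km=float(row.lon_km),
            y_km=float(row.lat_km),
            date=pd.Timestamp(row.date),
            area_acres=float(row.area_acres),
        )
        for row in df.itertuples()
    ]


def write_monitors(monitors: list[MonitorSeries], grid: GridSpec, path) -> None:
    """Long-format site_id, x_km, y_km, species, date, value (missing skipped)."""
    frames = []
    dates = grid.dates
    for m in monitors:
        ok = np.isfinite(m.values)
        frames.append(
            pd.DataFrame(
                {
                    "site_id": m.site_id,
                    "x_km": m.x_km,
                    "y_km": m.y_km,
                    "species": m.species,
                    "date": dates[ok].strftime("%Y-%m-%d"),
                    "value": m.values[ok],
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_monitors(path, grid: GridSpec) -> list[MonitorSeries]:
    df = pd.read_csv(path, dtype={"site_id": str})
    df["date"] = pd.to_datetime(df["date"])
    out = []
    for (site, x, y, sp), g in df.groupby(
        ["site_id", "x_km", "y_km", "species"], sort=True
    ):
        values = np.full(grid.n_days, np.nan)
        idx = grid.dates.get_indexer(g["date"])
        if (idx < 0).any():
            raise ValueError(f"monitor {site} has dates outside the grid calendar")
        values[idx] = g["value"].to_numpy()
        out.append(
            MonitorSeries(
                site_id=site, x_km=float(x), y_km=float(y), species=sp, values=values
            )
        )
    return out


def _grid_attrs(grid: GridSpec) -> dict:
    return {
        "origin_x": grid.origin_x,
        "origin_y": grid.origin_y,
        "cell_size": grid.cell_size,
        "date_start": grid.date_start,
        "date_end": grid.date_end,
    }


def write_field_netcdf(field: ConcentrationField, path) -> None:
    grid = field.grid
    da = xr.DataArray(
        field.values,
        dims=("time", "y", "x"),
        coords={
            "time": grid.dates,
            "y": grid.y_centers,
            "x": grid.x_centers,
        },
        attrs={"units": SPECIES_UNITS.get(field.species, ""), "species": field.species},
    )
    ds = xr.Dataset({"concentration": da}, attrs=_grid_attrs(grid))
    ds.to_netcdf(path, engine="scipy")


def read_field_netcdf(path) -> ConcentrationField:
    with xr.open_dataset(path, engine="scipy") as ds:
        da = ds["concentration"]
        grid = GridSpec(
            origin_x=float(ds.attrs["origin_x"]),
            origin_y=float(ds.attrs["origin_y"]),
            nx=da.sizes["x"],
            ny=da.sizes["y"],
            cell_size=float(ds.attrs["cell_size"]),
            date_start=str(ds.attrs["date_start"]),
            date_end=str(ds.attrs["date_end"]),
        )
        return ConcentrationField(grid, str(da.attrs["species"]), da.values.copy())


def write_field_text(field: ConcentrationField, directory) -> None:
    """Plain-text fallback: one row-major matrix file per day."""
    directory = pathlib.Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    grid = field.grid
    header = (
        f"species={field.species} origin_x={grid.origin_x} origin_y={grid.origin_y} "
        f"cell_size={grid.cell_size}"
    )
    for t, date in enumerate(grid.dates):
        np.savetxt(
            directory / f"{date.date().isoformat()}.txt",
            field.values[t],
            header=header,
        )


def read_field_text(directory, grid: GridSpec, species: str) -> ConcentrationField:
    directory = pathlib.Path(directory)
    values = np.empty((grid.n_days, grid.ny, grid.nx))
    for t, date in enumerate(grid.dates):
        f = directory / f"{date.date().isoformat()}.txt"
        if not f.exists():
            raise FileNotFoundError(f"missing daily field file {f}")
        values[t] = np.loadtxt(f)
    return ConcentrationField(grid, species, values)


def write_params(params: FusionParams, path) -> None:
    lines = [
        f"beta = {params.beta!r}",
        f"A = {params.A!r}",
        f"t_max = {params.t_max!r}",
        f"correlogram_range_km = {params.correlogram_range_km!r}",
        f"mean_obs_model_correlation = {params.mean_obs_model_correlation!r}",
        f"floor = {params.floor!r}",
    ]
    for y in sorted(params.alpha_year):
        lines.append(f"alpha_{y} = {params.alpha_year[y]!r}")
    pathlib.Path(path).write_text("\n".join(lines) + "\n")


def read_params(path) -> FusionParams:
    kv = {}
    for line in pathlib.Path(path).read_text().splitlines():
        if not line.strip():
            continue
        key, _, val = line.partition("=")
        kv[key.strip()] = float(val)
    alpha = {
        int(k.removeprefix("alpha_")): v for k, v in kv.items() if k.startswith("alpha_")
    }
    return FusionParams(
        alpha_year=alpha,
        beta=kv["beta"],
        A=kv["A"],
        t_max=kv["t_max"],
        correlogram_range_km=kv["correlogram_range_km"],
        mean_obs_model_correlation=kv["mean_obs_model_correlation"],
        floor=kv["floor"],
    )


def write_county_map(county_map: np.ndarray, path) -> None:
    np.savetxt(path, county_map, fmt="%d")


def read_county_map(path) -> np.ndarray:
    return np.loadtxt(path, dtype=int)
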