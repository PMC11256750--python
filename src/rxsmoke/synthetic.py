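"""Synthetic study inputs with known ground truth.

Real inputs to this pipeline — satellite fire detections, burn permits,
paired chemical-transport-model scenario runs, regulatory monitor
observations, county mortality tables and a population raster — are bulky
and not redistributable. This module fabricates all six on a small planar
grid with the generating parameters recorded in a :class:`TruthBundle`, so
every downstream stage can be validated by parameter and label recovery:

* fire events are constructed to satisfy the duration classification rule
  exactly (prescribed events are single-day, wildfires span >= 2 days) and
  are spatio-temporally separated so the default clustering recovers them;
* the all-emissions field is the no-burn background plus a burn-only field
  built from truncated-Gaussian plume kernels, so scenario differencing is
  exact by construction;
* monitor observations differ from the model field by exactly the bias
  family the fusion stage fits (a per-year scale times a seasonal cosine),
  plus optional truncated Gaussian noise — noise-free runs permit exact
  recovery tests;
* permit areas follow a stored linear relation to detected areas.

The kernels are a stand-in for plume dispersion, not a dispersion model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fires import AGRICULTURAL, PRESCRIBED, WILDFIRE, FireDetection
from .grids import O3, PM25, ConcentrationField, GridSpec, MonitorSeries, ScenarioPair
from .seasonal import seasonal_factor

__all__ = [
    "PermitRecord",
    "TruthBundle",
    "BackgroundParams",
    "default_grid",
    "generate_fire_records",
    "generate_scenario_fields",
    "generate_monitor_obs",
    "generate_county_tables",
]

# spacing (in cells) of the lattice of candidate event sites; together with
# the +/-1 km detection jitter it keeps distinct events farther apart than
# the default 4 km clustering radius
_SITE_SPACING_CELLS = 3
_JITTER_KM = 1.0
# same-site events are separated by > 2 days so the 1-day temporal link
# never chains two events together
_MIN_SITE_GAP_DAYS = 3


@dataclass(frozen=True)
class PermitRecord:
    """A burn-permit entry: reporting grid cell, date and reported area."""

    id: str
    x_km: float  # cell-center coordinates of the reporting cell
    y_km: float
    date: pd.Timestamp
    area_acres: float


@dataclass
class TruthBundle:
    """Generating parameters recorded for recovery tests."""

    true_burn_field: dict[str, np.ndarray] = field(default_factory=dict)
    true_alpha_year: dict[int, float] = field(default_factory=dict)
    true_A: float = 0.0
    true_tmax: float = 1.0
    true_fire_labels: dict[str, str] = field(default_factory=dict)
    true_area_slope: float = 1.0
    true_area_intercept: float = 0.0
    event_labels: list[str] = field(default_factory=list)

    def validate(self) -> None:
        for sp, f in self.true_burn_field.items():
            if not np.all(f >= 0):
                raise ValueError(f"true burn field for {sp} has negative values")
        if not 0.0 <= self.true_A < 1.0:
            raise ValueError(f"true_A must lie in [0, 1), got {self.true_A}")
        if not 1.0 <= self.true_tmax <= 365.25:
            raise ValueError(f"true_tmax must lie in [1, 365.25], got {self.true_tmax}")


@dataclass(frozen=True)
class BackgroundParams:
    """Controls the no-burn background and the burn plume kernel.

    ``kernel_coef`` converts detected area (acres) to the peak concentration
    added at the detection cell; the kernel is an isotropic Gaussian of
    scale ``kernel_scale_cells`` cells, truncated at ``kernel_cut_cells``,
    active on the detection day and the following day at ``carryover``
    amplitude. ``amplitude_scale`` is a global multiplier used in
    sensitivity runs.
    """

    base_level: float
    spatial_amp: float = 0.2
    ar_rho: float = 0.7
    ar_sigma: float = 0.25
    kernel_coef: float = 0.02
    kernel_scale_cells: float = 1.5
    kernel_cut_cells: float = 4.0
    carryover: float = 0.3
    amplitude_scale: float = 1.0


DEFAULT_BACKGROUND = {
    PM25: BackgroundParams(base_level=8.0, kernel_coef=0.1),
    O3: BackgroundParams(base_level=40.0, ar_sigma=0.12, kernel_coef=0.04),
}

#: per-year multiplicative model bias of the synthetic "observed truth"
DEFAULT_TRUE_ALPHA = 1.2
DEFAULT_TRUE_A = 0.2
DEFAULT_TRUE_TMAX = 45.0

DEFAULT_TRUE_AREA_SLOPE = 1.3
DEFAULT_TRUE_AREA_INTERCEPT = 10.0


def default_grid() -> GridSpec:
    """20 x 20 cells of 4 km, three simulated years."""
    return GridSpec(
        origin_x=0.0,
        origin_y=0.0,
        nx=20,
        ny=20,
        cell_size=4.0,
        date_start="2015-01-01",
        date_end="2017-12-31",
    )


def _event_sites(grid: GridSpec) -> np.ndarray:
    ix = np.arange(1, grid.nx - 1, _SITE_SPACING_CELLS)
    iy = np.arange(1, grid.ny - 1, _SITE_SPACING_CELLS)
    gx, gy = np.meshgrid(ix, iy)
    return np.column_stack([gy.ravel(), gx.ravel()])  # (iy, ix)


def _reserve_interval(
    calendar: dict[int, list[tuple[int, int]]], site: int, start: int, end: int
) -> bool:
    for s, e in calendar.get(site, []):
        if not (start > e + _MIN_SITE_GAP_DAYS - 1 or end < s - _MIN_SITE_GAP_DAYS + 1):
            return False
    calendar.setdefault(site, []).append((start, end))
    return True


def generate_fire_records(
    grid: GridSpec,
    n_prescribed: int,
    n_wildfire: int,
    n_agricultural: int,
    seed: int,
    area_slope: float = DEFAULT_TRUE_AREA_SLOPE,
    area_intercept: float = DEFAULT_TRUE_AREA_INTERCEPT,
    permit_noise_sd: float = 5.0,
) -> tuple[list[FireDetection], list[PermitRecord], TruthBundle]:
    """Fabricate fire detections, burn permits and their ground truth.

    Prescribed events are single-day groups of 1-5 detections inside one
    clustering radius; wildfire events span 2-4 consecutive days;
    agricultural detections are single and carry the agricultural landcover
    class. Each prescribed event gets a permit whose area follows
    ``area_slope * detected + area_intercept`` plus truncated Gaussian noise.
    """
    for name, v in (
        ("n_prescribed", n_prescribed),
        ("n_wildfire", n_wildfire),
        ("n_agricultural", n_agricultural),
    ):
        if v < 0:
            raise ValueError(f"{name} must be >= 0, got {v}")

    rng = np.random.default_rng(seed)
    sites = _event_sites(grid)
    n_days = grid.n_days
    calendar: dict[int, list[tuple[int, int]]] = {}
    detections: list[FireDetection] = []
    permits: list[PermitRecord] = []
    truth = TruthBundle(
        true_area_slope=area_slope, true_area_intercept=area_intercept
    )

    def place(site_idx: int, day_idx: int, label: str, area: float, det_id: str):
        iy, ix = sites[site_idx]
        cx, cy = grid.cell_center(iy, ix)
        x = cx + rng.uniform(-_JITTER_KM, _JITTER_KM)
        y = cy + rng.uniform(-_JITTER_KM, _JITTER_KM)
        det = FireDetection(
            id=det_id,
            x_km=x,
            y_km=y,
            date=grid.dates[day_idx],
            detected_area=area,
            landcover=AGRICULTURAL if label == AGRICULTURAL else "forest",
        )
        detections.append(det)
        truth.true_fire_labels[det_id] = label
        return det

    def schedule(duration: int) -> tuple[int, int]:
        for _ in range(2000):
            site = int(rng.integers(len(sites)))
            start = int(rng.integers(0, n_days - duration + 1))
            if _reserve_interval(calendar, site, start, start + duration - 1):
                return site, start
        raise RuntimeError(
            "could not place all fire events; grid or date range too small "
            "for the requested event counts"
        )

    k = 0
    for _ in range(n_prescribed):
        site, day = schedule(1)
        n_det = int(rng.integers(1, 6))
        event_area = 0.0
        for _ in range(n_det):
            area = float(rng.uniform(10.0, 300.0))
            event_area += area
            place(site, day, PRESCRIBED, area, f"F{k:05d}")
            k += 1
        truth.event_labels.append(PRESCRIBED)
        iy, ix = sites[site]
        cx, cy = grid.cell_center(iy, ix)
        permit_area = (
            area_slope * event_area
            + area_intercept
            + rng.normal(0.0, permit_noise_sd)
        )
        permits.append(
            PermitRecord(
                id=f"P{len(permits):05d}",
                x_km=cx,
                y_km=cy,
                date=grid.dates[day],
                area_acres=max(0.0, float(permit_area)),
            )
        )

    for _ in range(n_wildfire):
        duration = int(rng.integers(2, 5))
        site, start = schedule(duration)
        for d in range(duration):
            for _ in range(int(rng.integers(1, 4))):
                area = float(rng.uniform(50.0, 1000.0))
                place(site, start + d, WILDFIRE, area, f"F{k:05d}")
                k += 1
        truth.event_labels.append(WILDFIRE)

    for _ in range(n_agricultural):
        site, day = schedule(1)
        area = float(rng.uniform(5.0, 100.0))
        place(site, day, AGRICULTURAL, area, f"F{k:05d}")
        k += 1
        truth.event_labels.append(AGRICULTURAL)

    return detections, permits, truth


def _smooth_pattern(grid: GridSpec, rng: np.random.Generator) -> np.ndarray:
    """A fixed smooth spatial pattern with values in [-1, 1]."""
    x = grid.x_centers
    y = grid.y_centers
    lx = grid.nx * grid.cell_size
    ly = grid.ny * grid.cell_size
    p1, p2 = rng.uniform(0, 2 * np.pi, 2)
    pat = np.sin(2 * np.pi * x[None, :] / lx + p1) * np.cos(
        2 * np.pi * y[:, None] / ly + p2
    )
    return pat / max(np.abs(pat).max(), 1e-12)


def _ar1(n: int, rho: float, rng: np.random.Generator) -> np.ndarray:
    """Stationary AR(1) series with unit marginal variance."""
    eps = rng.standard_normal(n)
    out = np.empty(n)
    out[0] = eps[0]
    c = np.sqrt(1.0 - rho**2)
    for t in range(1, n):
        out[t] = rho * out[t - 1] + c * eps[t]
    return out


def _burn_kernel_field(
    grid: GridSpec,
    fires: list[FireDetection],
    labels: dict[str, str],
    which: str,
    params: BackgroundParams,
) -> np.ndarray:
    """Sum of truncated-Gaussian plume kernels for fires labelled ``which``."""
    out = np.zeros((grid.n_days, grid.ny, grid.nx))
    scale_km = params.kernel_scale_cells * grid.cell_size
    cut_km = params.kernel_cut_cells * grid.cell_size
    xg = grid.x_centers[None, :]
    yg = grid.y_centers[:, None]
    for det in fires:
        if labels.get(det.id) != which:
            continue
        if not grid.contains(det.x_km, det.y_km):
            raise ValueError(f"fire {det.id} lies outside the grid")
        try:
            t0 = grid.day_index(det.date)
        except KeyError:
            raise ValueError(
                f"fire {det.id} date {det.date.date()} outside the grid's range"
            ) from None
        r2 = (xg - det.x_km) ** 2 + (yg - det.y_km) ** 2
        kern = np.exp(-r2 / (2.0 * scale_km**2))
        kern[r2 > cut_km**2] = 0.0
        amp = params.amplitude_scale * params.kernel_coef * det.detected_area
        out[t0] += amp * kern
        if t0 + 1 < grid.n_days:
            out[t0 + 1] += params.carryover * amp * kern
    return out


def generate_scenario_fields(
    grid: GridSpec,
    fires: list[FireDetection],
    labels: dict[str, str],
    background_params: dict[str, BackgroundParams] | None = None,
    seed: int = 0,
    truth: TruthBundle | None = None,
) -> tuple[dict[str, ScenarioPair], TruthBundle]:
    """Paired all-emissions / no-prescribed-burn daily fields, both species.

    The no-burn background is smooth and positive with spatially correlated
    day-to-day variation; wildfire plumes are present in both scenarios (so
    they cancel in the difference), while prescribed-burn plumes enter the
    all-emissions field only. ``c_all = c_no_pb + burn`` holds exactly and
    the burn-only field is stored in the returned truth.
    """
    params = dict(DEFAULT_BACKGROUND)
    if background_params:
        params.update(background_params)
    truth = truth if truth is not None else TruthBundle()
    rng = np.random.default_rng(seed)
    pairs: dict[str, ScenarioPair] = {}
    for species in (PM25, O3):
        p = params[species]
        sub = np.random.default_rng(rng.integers(2**31))
        pattern = _smooth_pattern(grid, sub)
        p1 = _smooth_pattern(grid, sub)
        p2 = _smooth_pattern(grid, sub)
        logf = p.ar_sigma * _ar1(grid.n_days, p.ar_rho, sub)
        u = _ar1(grid.n_days, p.ar_rho, sub)
        v = _ar1(grid.n_days, p.ar_rho, sub)
        bg = (
            p.base_level
            * (1.0 + p.spatial_amp * pattern)[None, :, :]
            * np.exp(logf)[:, None, None]
            * (
                1.0
                + 0.1 * u[:, None, None] * p1[None, :, :]
                + 0.1 * v[:, None, None] * p2[None, :, :]
            )
        )
        bg = np.maximum(bg, 0.05 * p.base_level)
        bg += _burn_kernel_field(grid, fires, labels, WILDFIRE, p)
        burn = _burn_kernel_field(grid, fires, labels, PRESCRIBED, p)
        truth.true_burn_field[species] = burn
        pairs[species] = ScenarioPair(
            c_all=ConcentrationField(grid, species, bg + burn),
            c_no_pb=ConcentrationField(grid, species, bg),
        )
    truth.validate()
    return pairs, truth


def generate_monitor_obs(
    pair: ScenarioPair,
    truth: TruthBundle,
    n_monitors: int,
    noise_sd: float,
    seed: int,
    alpha_year: dict[int, float] | float = DEFAULT_TRUE_ALPHA,
    seasonal_amplitude: float = DEFAULT_TRUE_A,
    seasonal_tmax: float = DEFAULT_TRUE_TMAX,
) -> list[MonitorSeries]:
    """Monitor observations biased relative to the model by a known family.

    obs(m, t) = alpha_year(y(t)) * (1 + A cos(2 pi (t - t_max)/365.25))
                * c_all(cell of m, t) + N(0, noise_sd), truncated at 0.

    With ``noise_sd = 0`` the bias is exactly inside the family the fusion
    stage fits, enabling exact recovery tests. The bias parameters are
    recorded in ``truth``.
    """
    grid = pair.grid
    if n_monitors < 1:
        raise ValueError("n_monitors must be >= 1")
    if n_monitors > grid.n_cells:
        raise ValueError(
            f"n_monitors={n_monitors} exceeds the number of grid cells "
            f"({grid.n_cells})"
        )
    rng = np.random.default_rng(seed)
    flat = rng.choice(grid.n_cells, size=n_monitors, replace=False)
    iy, ix = np.unravel_index(flat, (grid.ny, grid.nx))

    if not isinstance(alpha_year, dict):
        alpha_year = {int(y): float(alpha_year) for y in np.unique(grid.years)}
    truth.true_alpha_year = dict(alpha_year)
    truth.true_A = float(seasonal_amplitude)
    truth.true_tmax = float(seasonal_tmax)
    truth.validate()

    alpha_t = np.array([alpha_year[int(y)] for y in grid.years])
    season = seasonal_factor(grid.day_of_year, seasonal_amplitude, seasonal_tmax)
    bias = alpha_t * season

    monitors = []
    for i in range(n_monitors):
        cx, cy = grid.cell_center(int(iy[i]), int(ix[i]))
        clean = bias * pair.c_all.values[:, iy[i], ix[i]]
        noise = noise_sd * rng.standard_normal(grid.n_days)
        monitors.append(
            MonitorSeries(
                site_id=f"M{i:03d}",
                x_km=cx,
                y_km=cy,
                species=pair.species,
                values=np.maximum(clean + noise, 0.0),
            )
        )
    return monitors


def generate_county_tables(
    grid: GridSpec, n_counties: int, seed: int
) -> tuple[np.ndarray, pd.DataFrame, np.ndarray]:
    """County map, county population/mortality table and population raster.

    Counties are the nearest-seed (Voronoi) regions of ``n_counties`` random
    seed cells, hence contiguous on the grid. Registered deaths are built as
    cardiovascular + respiratory + other, so the all-cause count dominates
    the cause-specific ones by construction. Returns ``(county_map,
    counties, pop_raster)`` where ``counties`` has one row per county-year.
    """
    if not 1 <= n_counties <= grid.n_cells:
        raise ValueError(
            f"n_counties must be in [1, {grid.n_cells}], got {n_counties}"
        )
    rng = np.random.default_rng(seed)
    flat = rng.choice(grid.n_cells, size=n_counties, replace=False)
    sy, sx = np.unravel_index(flat, (grid.ny, grid.nx))
    seeds_xy = np.column_stack([grid.x_centers[sx], grid.y_centers[sy]])

    gx, gy = np.meshgrid(grid.x_centers, grid.y_centers)
    d2 = (gx.ravel()[:, None] - seeds_xy[None, :, 0]) ** 2 + (
        gy.ravel()[:, None] - seeds_xy[None, :, 1]
    ) ** 2
    county_map = np.argmin(d2, axis=1).reshape(grid.ny, grid.nx)

    pop_raster = np.maximum(
        np.round(rng.lognormal(mean=6.5, sigma=1.0, size=(grid.ny, grid.nx))), 1.0
    )

    years = np.unique(grid.years)
    rows = []
    for c in range(n_counties):
        pop = float(pop_raster[county_map == c].sum())
        jitter = rng.uniform(0.85, 1.15)
        for y in years:
            cvd = int(round(0.0028 * jitter * pop))
            resp = int(round(0.0010 * jitter * pop))
            other = int(round(0.0057 * jitter * pop))
            rows.append(
                {
                    "county_id": c,
                    "year": int(y),
                    "population": pop,
                    "deaths_allcause": cvd + resp + other,
                    "deaths_cvd": cvd,
                    "deaths_resp": resp,
                }
            )
    return county_map, pd.DataFrame(rows), pop_raster
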