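"""Observation-model data fusion and observation-adjusted burn impacts.

A chemical-transport model carries systematic bias from emissions,
meteorology and process error. This module calibrates the modelled total
field against regulatory monitor observations and propagates the
calibration to the prescribed-burn contribution:

* :func:`scenario_difference` — the burn impact as the cellwise difference
  of the all-emissions and no-burn scenario fields.
* :func:`fit_fusion_params` — a per-year multiplicative scale
  ``alpha_year``, a global scale ``beta`` (diagnostic), a seasonal cosine
  correction with amplitude ``A`` and peak day ``t_max``, the e-folding
  range of the inter-monitor correlogram, and the mean observation-model
  correlation. The per-year scale and the seasonal pair are estimated
  jointly by alternating least squares on
  ``obs = alpha_year * (1 + A cos(2 pi (doy - t_max)/365.25)) * model``,
  which reduces to the ratio of annual means when ``A = 0``.
* :func:`build_weight_field` / :func:`interpolate_observation_ratio` /
  :func:`fuse` — a weighted blend: near monitors the fused field follows
  the interpolated observation/model ratio (local temporal variation from
  observations, spatial texture from the model); far from monitors it
  relaxes to the bias-adjusted model.
* :func:`adjust_burn_impact` — scales the fused total by the model's
  cellwise burn fraction, preserving that fraction exactly.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .grids import (
    DEFAULT_FLOORS,
    ConcentrationField,
    GridSpec,
    MonitorSeries,
    ScenarioPair,
    collocate,
    monitor_cells,
    observation_matrix,
)
from .seasonal import PERIOD_DAYS, phase_to_tmax, seasonal_factor

__all__ = [
    "FusionParams",
    "WeightField",
    "scenario_difference",
    "fit_fusion_params",
    "build_weight_field",
    "interpolate_observation_ratio",
    "fuse",
    "adjust_burn_impact",
]

logger = logging.getLogger(__name__)

_MAX_AMPLITUDE = 0.999


@dataclass
class FusionParams:
    """Fitted bias and weighting parameters for one species."""

    alpha_year: dict[int, float]
    beta: float
    A: float
    t_max: float
    correlogram_range_km: float
    mean_obs_model_correlation: float
    floor: float

    def __post_init__(self) -> None:
        if any(a <= 0 for a in self.alpha_year.values()):
            raise ValueError("alpha_year values must be positive")
        if not 0.0 <= self.A < 1.0:
            raise ValueError(f"seasonal amplitude A must lie in [0, 1), got {self.A}")
        if not 1.0 <= self.t_max <= PERIOD_DAYS:
            raise ValueError(f"t_max must lie in [1, {PERIOD_DAYS}], got {self.t_max}")
        if not self.correlogram_range_km > 0:
            raise ValueError("correlogram_range_km must be > 0")
        if not -1.0 <= self.mean_obs_model_correlation <= 1.0:
            raise ValueError("mean_obs_model_correlation must lie in [-1, 1]")

    def adjusted_model(self, model: ConcentrationField) -> np.ndarray:
        """alpha_year(y(t)) * seasonal(t) * model, the no-monitor limit."""
        grid = model.grid
        alpha_t = np.array([self.alpha_year[int(y)] for y in grid.years])
        season = seasonal_factor(grid.day_of_year, self.A, self.t_max)
        return (alpha_t * season)[:, None, None] * model.values


@dataclass
class WeightField:
    """Static per-cell observation weight in [0, 1]."""

    grid: GridSpec
    w: np.ndarray

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=float)
        if self.w.shape != (self.grid.ny, self.grid.nx):
            raise ValueError("weight shape does not match grid")
        if self.w.min() < 0 or self.w.max() > 1:
            raise ValueError("weights must lie in [0, 1]")


def scenario_difference(pair: ScenarioPair) -> ConcentrationField:
    """Burn impact: all-emissions minus no-burn, cellwise, sign preserved."""
    return pair.c_all.like(pair.c_all.values - pair.c_no_pb.values)


def _species_floor(species: str, floor: float | None) -> float:
    if floor is not None:
        return floor
    return DEFAULT_FLOORS.get(species, 0.1)


def fit_fusion_params(
    obs: list[MonitorSeries],
    model: ConcentrationField,
    floor: float | None = None,
    max_iter: int = 200,
    tol: float = 1e-13,
) -> FusionParams:
    """Fit the multiplicative bias family and the spatial weighting inputs.

    Requires at least 3 monitors and at least one full year of days.
    Monitor-days with missing observations or with model values at or below
    the floor are excluded from the bias fit.
    """
    if len(obs) < 3:
        raise ValueError(f"fusion fit needs >= 3 monitors, got {len(obs)}")
    grid = model.grid
    if grid.n_days < 365:
        raise ValueError("fusion fit needs at least one full year of days")
    floor = _species_floor(model.species, floor)

    m = collocate(model, obs)  # (n_mon, n_days)
    o = observation_matrix(obs, grid)
    valid = np.isfinite(o) & (m > floor)
    if not valid.any():
        raise ValueError("all model values lie at or below the floor")

    doy = grid.day_of_year
    omega = 2.0 * np.pi / PERIOD_DAYS
    cosw = np.cos(omega * doy)
    sinw = np.sin(omega * doy)
    years = grid.years
    uyears = np.unique(years)

    # alternating least squares on the bilinear scale x seasonal model
    a = b = 0.0
    alpha = {int(y): 1.0 for y in uyears}
    for _ in range(max_iter):
        season = 1.0 + a * cosw + b * sinw
        new_alpha = {}
        for y in uyears:
            sel = valid & (years == y)[None, :]
            denom = (m * season)[sel].sum()
            if denom <= 0:
                raise ValueError(f"no usable monitor-days in year {y}")
            new_alpha[int(y)] = float(o[sel].sum() / denom)
        alpha_t = np.array([new_alpha[int(y)] for y in years])
        r = np.where(valid, o / np.where(valid, alpha_t * m, 1.0), np.nan)
        resid = (r - 1.0)[valid]
        design = np.column_stack(
            [np.broadcast_to(cosw, o.shape)[valid], np.broadcast_to(sinw, o.shape)[valid]]
        )
        coef, *_ = np.linalg.lstsq(design, resid, rcond=None)
        delta = max(
            abs(coef[0] - a),
            abs(coef[1] - b),
            max(abs(new_alpha[y] - alpha[y]) for y in new_alpha),
        )
        a, b = float(coef[0]), float(coef[1])
        alpha = new_alpha
        if delta < tol:
            break

    amp, t_max = phase_to_tmax(a, b)
    if amp >= _MAX_AMPLITUDE:
        amp = _MAX_AMPLITUDE
    season = seasonal_factor(doy, amp, t_max)
    beta = float(o[valid].sum() / (m * season)[valid].sum())

    corr_range = _fit_correlogram_range(obs, o, grid)
    mean_corr = _mean_obs_model_correlation(o, m)

    return FusionParams(
        alpha_year=alpha,
        beta=beta,
        A=amp,
        t_max=t_max,
        correlogram_range_km=corr_range,
        mean_obs_model_correlation=mean_corr,
        floor=floor,
    )


def _fit_correlogram_range(
    obs: list[MonitorSeries], o: np.ndarray, grid: GridSpec
) -> float:
    """E-folding distance of inter-monitor daily-value correlation."""
    n = len(obs)
    xy = np.array([[s.x_km, s.y_km] for s in obs])
    dists, corrs = [], []
    for i in range(n):
        for j in range(i + 1, n):
            both = np.isfinite(o[i]) & np.isfinite(o[j])
            if both.sum() < 30:
                continue
            oi, oj = o[i, both], o[j, both]
            if oi.std() == 0 or oj.std() == 0:
                continue
            dists.append(float(np.hypot(*(xy[i] - xy[j]))))
            corrs.append(float(np.corrcoef(oi, oj)[0, 1]))
    dists = np.asarray(dists)
    corrs = np.asarray(corrs)
    if len(dists) < 2:
        # single usable pair (or none): fall back to the grid's length scale
        return float(max(grid.nx, grid.ny) * grid.cell_size / 2.0)
    span = max(dists.max(), grid.cell_size)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(
                lambda d, L: np.exp(-d / L),
                dists,
                np.clip(corrs, 0.0, 1.0),
                p0=[span / 3.0],
                bounds=(1e-3, 100.0 * span),
                maxfev=2000,
            )
        return float(popt[0])
    except RuntimeError:  # pragma: no cover - ill-posed correlogram
        logger.warning("correlogram fit failed; falling back to grid half-span")
        return float(span / 2.0)


def _mean_obs_model_correlation(o: np.ndarray, m: np.ndarray) -> float:
    cors = []
    for i in range(o.shape[0]):
        ok = np.isfinite(o[i])
        if ok.sum() < 3 or o[i, ok].std() == 0 or m[i, ok].std() == 0:
            continue
        cors.append(np.corrcoef(o[i, ok], m[i, ok])[0, 1])
    if not cors:
        return 0.0
    return float(np.clip(np.mean(cors), 0.0, 1.0))


def _snapped_monitor_centers(
    monitors: list[MonitorSeries], grid: GridSpec
) -> np.ndarray:
    """Monitor positions snapped to their cell centers, (n_mon, 2).

    Snapping makes the distance-to-nearest-monitor exactly zero at monitor
    cells, so the weight is exactly 1 there.
    """
    cells = monitor_cells(monitors, grid)
    return np.column_stack(
        [grid.x_centers[cells[:, 1]], grid.y_centers[cells[:, 0]]]
    )


def _cell_monitor_distances(
    monitors: list[MonitorSeries], grid: GridSpec
) -> np.ndarray:
    """(n_cells, n_mon) distances from cell centers to monitor cell centers."""
    mon_xy = _snapped_monitor_centers(monitors, grid)
    gx, gy = np.meshgrid(grid.x_centers, grid.y_centers)
    cells_xy = np.column_stack([gx.ravel(), gy.ravel()])
    return np.hypot(
        cells_xy[:, None, 0] - mon_xy[None, :, 0],
        cells_xy[:, None, 1] - mon_xy[None, :, 1],
    )


def build_weight_field(
    monitors: list[MonitorSeries], params: FusionParams, grid: GridSpec
) -> WeightField:
    """w(x) = exp(-d(x)/range) with d the distance to the nearest monitor."""
    if not monitors:
        raise ValueError("weight field needs at least one monitor")
    d = _cell_monitor_distances(monitors, grid).min(axis=1)
    w = np.exp(-d / params.correlogram_range_km).reshape(grid.ny, grid.nx)
    return WeightField(grid=grid, w=w)


def interpolate_observation_ratio(
    obs: list[MonitorSeries],
    model: ConcentrationField,
    params: FusionParams,
    day: int,
) -> np.ndarray:
    """Correlogram-weighted obs/model ratio surface for one day, (ny, nx).

    ``day`` is an index into the grid calendar. Where no monitor reports
    that day the surface is 1 (pure adjusted model downstream).
    """
    grid = model.grid
    o = observation_matrix(obs, grid)[:, day]
    m = collocate(model, obs)[:, day]
    reporting = np.isfinite(o)
    if not reporting.any():
        logger.warning("no monitor reports on day index %d; ratio surface = 1", day)
        return np.ones((grid.ny, grid.nx))
    r = o[reporting] / np.maximum(m[reporting], params.floor)
    d = _cell_monitor_distances(obs, grid)[:, reporting]
    wk = np.exp(-d / params.correlogram_range_km)
    surface = (wk @ r) / wk.sum(axis=1)
    return surface.reshape(grid.ny, grid.nx)


def fuse(
    model: ConcentrationField,
    obs: list[MonitorSeries],
    params: FusionParams,
    weights: WeightField,
) -> ConcentrationField:
    """Blend the model with interpolated observation ratios.

    fused(x, t) = w(x) * model(x, t) * ratio_surface(x, t)
                  + (1 - w(x)) * adjusted_model(x, t),   clipped at 0.
    """
    grid = model.grid
    if weights.grid != grid:
        raise ValueError("weight field grid does not match the model grid")
    for s in obs:
        if s.species != model.species:
            raise ValueError(
                f"monitor {s.site_id} species {s.species} does not match "
                f"model species {model.species}"
            )
    o = observation_matrix(obs, grid)
    m = collocate(model, obs)
    d = _cell_monitor_distances(obs, grid)
    wk_all = np.exp(-d / params.correlogram_range_km)  # (n_cells, n_mon)

    adj = params.adjusted_model(model)
    fused = np.empty_like(model.values)
    w = weights.w
    for t in range(grid.n_days):
        reporting = np.isfinite(o[:, t])
        if reporting.any():
            r = o[reporting, t] / np.maximum(m[reporting, t], params.floor)
            wk = wk_all[:, reporting]
            surf = ((wk @ r) / wk.sum(axis=1)).reshape(grid.ny, grid.nx)
        else:
            surf = 1.0
        fused[t] = w * model.values[t] * surf + (1.0 - w) * adj[t]
    return model.like(np.maximum(fused, 0.0))


def adjust_burn_impact(
    fused_total: ConcentrationField,
    pair: ScenarioPair,
    floor: float | None = None,
) -> ConcentrationField:
    """Observation-adjusted burn impact.

    The fused total is multiplied by the model's cellwise burn fraction
    ``delta_model / c_all_model``; where the model total is at or below the
    floor the impact is 0. The burn fraction of the fused field therefore
    equals the model's burn fraction wherever defined; negative impacts
    (ozone titration) are preserved.
    """
    if not fused_total.same_frame(pair.c_all):
        raise ValueError("fused field and scenario pair must share grid/species")
    floor = _species_floor(pair.species, floor)
    delta = pair.c_all.values - pair.c_no_pb.values
    denom = pair.c_all.values
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(denom > floor, fused_total.values * delta / denom, 0.0)
    return fused_total.like(out)
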