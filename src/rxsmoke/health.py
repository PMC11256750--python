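"""Mortality attributable to prescribed-burn smoke exposure.

Excess deaths follow the standard log-linear concentration-response form
for short-term exposure:

    delta_D = D_registered * (1 - exp(-beta * delta_C))

with ``delta_C`` the annual-mean burn-attributable concentration increment
(county mean of the observation-adjusted burn impact, floored at 0),
``D_registered`` the cause-specific registered deaths in the county and
year, and ``beta`` the per-unit log-relative-risk from epidemiological
meta-analysis. Confidence bounds come from evaluating at the coefficient's
interval endpoints; no other uncertainty source is propagated.

Two variants are provided: the county formulation (registered county
deaths) and a gridded formulation (per-cell population raster times a
baseline rate), plus a daily-accumulation option since the coefficients
describe short-term exposure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grids import ConcentrationField, GridSpec

__all__ = [
    "CRCoefficient",
    "CountyExposure",
    "MortalityEstimate",
    "regrid_to_county",
    "population_weighted_exposure",
    "crf_excess_deaths",
    "aggregate_mortality",
    "gridded_variant_deaths",
    "daily_variant_deaths",
    "resample_nearest",
]

#: a per-unit beta above this is almost certainly a per-10-unit value that
#: was not divided by 10
MAX_PLAUSIBLE_BETA = 0.1


@dataclass(frozen=True)
class CRCoefficient:
    """Log-linear concentration-response coefficient with its interval.

    Betas are per concentration unit (per ug/m3 for PM2.5, per ppb for
    MDA8-O3). Published per-10-unit coefficients must be divided by 10
    before entering a config.
    """

    pollutant: str
    cause: str
    beta_central: float
    beta_low: float
    beta_high: float

    def __post_init__(self) -> None:
        if not self.beta_low <= self.beta_central <= self.beta_high:
            raise ValueError(
                f"CR coefficient interval out of order for {self.pollutant}/"
                f"{self.cause}: {self.beta_low}, {self.beta_central}, {self.beta_high}"
            )
        if abs(self.beta_central) > MAX_PLAUSIBLE_BETA:
            raise ValueError(
                f"beta_central={self.beta_central} per unit for {self.pollutant}/"
                f"{self.cause} looks like a per-10-unit value; divide by 10"
            )


@dataclass(frozen=True)
class CountyExposure:
    county_id: int
    year: int
    pollutant: str
    annual_mean_delta: float

    def __post_init__(self) -> None:
        if self.annual_mean_delta < 0:
            raise ValueError("county exposure must be >= 0 after flooring")


@dataclass(frozen=True)
class MortalityEstimate:
    scope: str  # county id as str, or "state"/"domain"
    year: int | None
    pollutant: str
    cause: str
    deaths_central: float
    deaths_low: float
    deaths_high: float

    def __post_init__(self) -> None:
        if not self.deaths_low <= self.deaths_central <= self.deaths_high:
            raise ValueError("mortality interval out of order")


def regrid_to_county(
    field: ConcentrationField, county_map: np.ndarray, year: int
) -> list[CountyExposure]:
    """County annual-mean burn impact, floored at 0.

    The mean is unweighted over (cells in county) x (days in year).
    Negative impacts (ozone titration) are floored at zero before
    averaging enters the health function, at the county level.
    """
    grid = field.grid
    if county_map.shape != (grid.ny, grid.nx):
        raise ValueError("county map shape does not match the field grid")
    annual = field.annual_mean(year)
    out = []
    for c in np.unique(county_map):
        cells = county_map == c
        mean = float(max(annual[cells].mean(), 0.0))
        out.append(
            CountyExposure(
                county_id=int(c),
                year=year,
                pollutant=field.species,
                annual_mean_delta=mean,
            )
        )
    return out


def population_weighted_exposure(
    field: ConcentrationField,
    pop_raster: np.ndarray,
    period: slice | None = None,
) -> float:
    """Population-weighted mean exposure over a period (default: all days)."""
    grid = field.grid
    if pop_raster.shape != (grid.ny, grid.nx):
        raise ValueError("population raster shape does not match the field grid")
    total = pop_raster.sum()
    if not total > 0:
        raise ValueError("total population must be > 0")
    values = field.values if period is None else field.values[period]
    cell_mean = values.mean(axis=0)
    return float((pop_raster * cell_mean).sum() / total)


def crf_excess_deaths(
    exposure: CountyExposure,
    registered_deaths: float,
    crc: CRCoefficient,
) -> MortalityEstimate:
    """delta_D = registered * (1 - exp(-beta * delta_C)) at the three betas."""
    if registered_deaths < 0:
        raise ValueError("registered_deaths must be >= 0")
    if crc.pollutant != exposure.pollutant:
        raise ValueError(
            f"CR coefficient pollutant {crc.pollutant} does not match "
            f"exposure pollutant {exposure.pollutant}"
        )
    dc = exposure.annual_mean_delta

    def deaths(beta: float) -> float:
        return float(registered_deaths * (1.0 - np.exp(-beta * dc)))

    return MortalityEstimate(
        scope=str(exposure.county_id),
        year=exposure.year,
        pollutant=exposure.pollutant,
        cause=crc.cause,
        deaths_central=deaths(crc.beta_central),
        deaths_low=deaths(crc.beta_low),
        deaths_high=deaths(crc.beta_high),
    )


def aggregate_mortality(
    estimates: list[MortalityEstimate], scope: str
) -> MortalityEstimate:
    """Sum county estimates (central/low/high each) into one scope total."""
    if not estimates:
        raise ValueError("nothing to aggregate")
    causes = {e.cause for e in estimates}
    pollutants = {e.pollutant for e in estimates}
    if len(causes) > 1 or len(pollutants) > 1:
        raise ValueError(
            f"cannot aggregate mixed causes/pollutants: {causes}, {pollutants}"
        )
    years = {e.year for e in estimates}
    return MortalityEstimate(
        scope=scope,
        year=years.pop() if len(years) == 1 else None,
        pollutant=pollutants.pop(),
        cause=causes.pop(),
        deaths_central=sum(e.deaths_central for e in estimates),
        deaths_low=sum(e.deaths_low for e in estimates),
        deaths_high=sum(e.deaths_high for e in estimates),
    )


def resample_nearest(
    values: np.ndarray, source: GridSpec, target: GridSpec
) -> np.ndarray:
    """Nearest-neighbour resampling of a raster between planar grids."""
    if values.shape != (source.ny, source.nx):
        raise ValueError("raster shape does not match its grid")
    ix = np.clip(
        ((target.x_centers - source.origin_x) // source.cell_size).astype(int),
        0,
        source.nx - 1,
    )
    iy = np.clip(
        ((target.y_centers - source.origin_y) // source.cell_size).astype(int),
        0,
        source.ny - 1,
    )
    return values[np.ix_(iy, ix)]


def gridded_variant_deaths(
    field: ConcentrationField,
    pop_raster: np.ndarray,
    baseline_rate: dict[str, float],
    crc: CRCoefficient,
    year: int,
    pop_grid: GridSpec | None = None,
) -> MortalityEstimate:
    """Gridded comparative estimate with a per-cell population raster.

    Per cell: ``rate * pop(x) * (1 - exp(-beta * annual_mean(x)))`` summed
    over cells. A population raster on a different grid is resampled to the
    concentration grid by nearest neighbour. ``baseline_rate`` maps cause
    to deaths per person per year.
    """
    grid = field.grid
    if pop_grid is not None and pop_grid != grid:
        pop_raster = resample_nearest(pop_raster, pop_grid, grid)
    if pop_raster.shape != (grid.ny, grid.nx):
        raise ValueError("population raster shape does not match the field grid")
    rate = baseline_rate[crc.cause]
    annual = np.maximum(field.annual_mean(year), 0.0)

    def deaths(beta: float) -> float:
        return float((rate * pop_raster * (1.0 - np.exp(-beta * annual))).sum())

    return MortalityEstimate(
        scope="domain",
        year=year,
        pollutant=field.species,
        cause=crc.cause,
        deaths_central=deaths(crc.beta_central),
        deaths_low=deaths(crc.beta_low),
        deaths_high=deaths(crc.beta_high),
    )


def daily_variant_deaths(
    field: ConcentrationField,
    county_map: np.ndarray,
    registered: pd.DataFrame,
    crc: CRCoefficient,
    year: int,
    deaths_column: str,
) -> MortalityEstimate:
    """Daily-accumulation sensitivity variant of the county estimate.

    Sums ``registered/365.25 * (1 - exp(-beta * delta_C(t)))`` over the days
    of the year using the county-mean daily impact (floored at 0). With a
    constant daily impact this approaches the annual formulation for small
    beta * delta_C.
    """
    grid = field.grid
    day_sel = grid.years == year
    if not day_sel.any():
        raise ValueError(f"year {year} not in field range")
    n_days_year = int(day_sel.sum())
    rows = registered[registered["year"] == year].set_index("county_id")

    def one(beta: float) -> float:
        total = 0.0
        for c in np.unique(county_map):
            daily = field.values[day_sel][:, county_map == c].mean(axis=1)
            daily = np.maximum(daily, 0.0)
            d_reg = float(rows.loc[int(c), deaths_column])
            total += (d_reg / n_days_year * (1.0 - np.exp(-beta * daily))).sum()
        return float(total)

    return MortalityEstimate(
        scope="domain",
        year=year,
        pollutant=field.species,
        cause=crc.cause,
        deaths_central=one(crc.beta_central),
        deaths_low=one(crc.beta_low),
        deaths_high=one(crc.beta_high),
    )
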