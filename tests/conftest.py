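"""Shared synthetic-study fixtures.

Expensive objects (the 20x20, three-year study with its scenario fields)
are session-scoped; every test works on generated data, never on stored
fixtures.
"""

from __future__ import annotations

from dataclasses import dataclass

import pytest

from rxsmoke.grids import PM25, GridSpec, ScenarioPair
from rxsmoke.synthetic import (
    TruthBundle,
    default_grid,
    generate_fire_records,
    generate_monitor_obs,
    generate_scenario_fields,
)


@dataclass
class Study:
    grid: GridSpec
    detections: list
    permits: list
    truth: TruthBundle
    pairs: dict[str, ScenarioPair]
    monitors: list  # noise-free PM2.5 monitors


@pytest.fixture(scope="session")
def grid() -> GridSpec:
    return default_grid()


@pytest.fixture(scope="session")
def study(grid) -> Study:
    """Noise-free study: bias exactly inside the fitted family."""
    detections, permits, truth = generate_fire_records(grid, 120, 8, 15, seed=101)
    pairs, truth = generate_scenario_fields(
        grid, detections, truth.true_fire_labels, seed=102, truth=truth
    )
    monitors = generate_monitor_obs(
        pairs[PM25], truth, n_monitors=30, noise_sd=0.0, seed=103,
        alpha_year=1.2, seasonal_amplitude=0.2, seasonal_tmax=45.0,
    )
    return Study(grid, detections, permits, truth, pairs, monitors)


@pytest.fixture(scope="session")
def small_grid() -> GridSpec:
    """One-year grid for cheaper pipeline-level tests."""
    return GridSpec(
        origin_x=0.0, origin_y=0.0, nx=12, ny=12, cell_size=4.0,
        date_start="2016-01-01", date_end="2016-12-31",
    )
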