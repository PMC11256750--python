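"""Fusion: scenario differencing, bias fitting, weighting, adjustment."""

import numpy as np
import pytest

from rxsmoke.fusion import (
    FusionParams,
    WeightField,
    adjust_burn_impact,
    build_weight_field,
    fit_fusion_params,
    fuse,
    interpolate_observation_ratio,
    scenario_difference,
)
from rxsmoke.grids import PM25, ConcentrationField, MonitorSeries, ScenarioPair, collocate
from rxsmoke.synthetic import generate_monitor_obs


def _params(alpha_years, **kw):
    defaults = dict(
        beta=1.0, A=0.0, t_max=45.0, correlogram_range_km=50.0,
        mean_obs_model_correlation=1.0, floor=0.1,
    )
    defaults.update(kw)
    return FusionParams(alpha_year=alpha_years, **defaults)


class TestScenarioDifference:
    def test_identical_fields_zero_impact(self, study):
        pair = ScenarioPair(study.pairs[PM25].c_all, study.pairs[PM25].c_all)
        assert np.all(scenario_difference(pair).values == 0)

    def test_equals_stored_burn_field(self, study):
        delta = scenario_difference(study.pairs[PM25])
        np.testing.assert_allclose(
            delta.values, study.truth.true_burn_field[PM25], rtol=1e-12, atol=1e-12
        )

    def test_mismatched_fields_rejected(self, study, small_grid):
        other = ConcentrationField(
            small_grid, PM25, np.ones((small_grid.n_days, small_grid.ny, small_grid.nx))
        )
        with pytest.raises(ValueError):
            ScenarioPair(study.pairs[PM25].c_all, other)


class TestFitFusionParams:
    def test_identity_observations(self, study):
        model = study.pairs[PM25].c_all
        m = collocate(model, study.monitors[:5])
        mons = [
            MonitorSeries(s.site_id, s.x_km, s.y_km, s.species, m[i].copy())
            for i, s in enumerate(study.monitors[:5])
        ]
        params = fit_fusion_params(mons, model)
        for a in params.alpha_year.values():
            assert a == pytest.approx(1.0, abs=1e-9)
        assert params.A == pytest.approx(0.0, abs=1e-9)
        assert params.mean_obs_model_correlation == pytest.approx(1.0)

    def test_pure_scale_recovered_exactly(self, study):
        mons = generate_monitor_obs(
            study.pairs[PM25], study.truth, 10, 0.0, seed=51,
            alpha_year=1.2, seasonal_amplitude=0.0, seasonal_tmax=45.0,
        )
        params = fit_fusion_params(mons, study.pairs[PM25].c_all)
        for a in params.alpha_year.values():
            assert a == pytest.approx(1.2, abs=1e-9)
        assert params.A == pytest.approx(0.0, abs=1e-6)
        assert params.beta == pytest.approx(1.2, abs=1e-9)

    def test_seasonal_parameters_recovered(self, study):
        params = fit_fusion_params(study.monitors, study.pairs[PM25].c_all)
        assert params.A == pytest.approx(0.2, abs=0.02)
        assert abs(params.t_max - 45.0) < 3.0

    def test_too_few_monitors_rejected(self, study):
        with pytest.raises(ValueError, match="3 monitors"):
            fit_fusion_params(study.monitors[:2], study.pairs[PM25].c_all)

    def test_all_below_floor_rejected(self, study):
        model = study.pairs[PM25].c_all
        tiny = model.like(np.full_like(model.values, 0.01))
        with pytest.raises(ValueError, match="floor"):
            fit_fusion_params(study.monitors, tiny)


class TestWeightField:
    def test_weight_one_at_monitor_cell(self, study):
        params = _params({2015: 1.0, 2016: 1.0, 2017: 1.0})
        wf = build_weight_field(study.monitors, params, study.grid)
        for m in study.monitors:
            iy, ix = study.grid.cell_of(m.x_km, m.y_km)
            assert wf.w[iy, ix] == pytest.approx(1.0)

    def test_efolding_at_range(self, study):
        grid = study.grid
        mon = study.monitors[0]
        iy, ix = grid.cell_of(mon.x_km, mon.y_km)
        params = _params(
            {2015: 1.0, 2016: 1.0, 2017: 1.0}, correlogram_range_km=grid.cell_size
        )
        wf = build_weight_field([mon], params, grid)
        if ix + 1 < grid.nx:
            assert wf.w[iy, ix + 1] == pytest.approx(np.exp(-1.0))

    def test_monotone_decay_from_isolated_monitor(self, study):
        grid = study.grid
        mon = study.monitors[0]
        params = _params({2015: 1.0, 2016: 1.0, 2017: 1.0})
        wf = build_weight_field([mon], params, grid)
        iy, ix = grid.cell_of(mon.x_km, mon.y_km)
        row = wf.w[iy, ix:]
        assert np.all(np.diff(row) < 0) or len(row) == 1
        assert wf.w.min() >= 0 and wf.w.max() <= 1

    def test_no_monitors_rejected(self, study):
        params = _params({2015: 1.0, 2016: 1.0, 2017: 1.0})
        with pytest.raises(ValueError):
            build_weight_field([], params, study.grid)


class TestRatioSurface:
    def test_single_monitor_sets_surface_value(self, study):
        grid = study.grid
        model = study.pairs[PM25].c_all
        mon = study.monitors[0]
        iy, ix = grid.cell_of(mon.x_km, mon.y_km)
        scaled = MonitorSeries(
            mon.site_id, mon.x_km, mon.y_km, mon.species,
            1.5 * model.values[:, iy, ix],
        )
        params = _params({2015: 1.0, 2016: 1.0, 2017: 1.0})
        surf = interpolate_observation_ratio([scaled], model, params, day=10)
        assert surf[iy, ix] == pytest.approx(1.5)
        np.testing.assert_allclose(surf, 1.5)  # single ratio -> constant surface

    def test_surface_is_convex_combination(self, study):
        grid = study.grid
        model = study.pairs[PM25].c_all
        mons = []
        for ratio, src in zip((1.0, 2.0), study.monitors[:2]):
            iy, ix = grid.cell_of(src.x_km, src.y_km)
            mons.append(
                MonitorSeries(
                    src.site_id, src.x_km, src.y_km, src.species,
                    ratio * model.values[:, iy, ix],
                )
            )
        params = _params({2015: 1.0, 2016: 1.0, 2017: 1.0})
        surf = interpolate_observation_ratio(mons, model, params, day=100)
        assert surf.min() >= 1.0 - 1e-12 and surf.max() <= 2.0 + 1e-12

    def test_all_missing_day_gives_unit_surface(self, study):
        grid = study.grid
        model = study.pairs[PM25].c_all
        mon = study.monitors[0]
        values = mon.values.copy()
        values[5] = np.nan
        m = MonitorSeries(mon.site_id, mon.x_km, mon.y_km, mon.species, values)
        params = _params({2015: 1.0, 2016: 1.0, 2017: 1.0})
        surf = interpolate_observation_ratio([m], model, params, day=5)
        np.testing.assert_array_equal(surf, 1.0)


class TestFuse:
    def test_zero_weight_gives_adjusted_model(self, study):
        grid = study.grid
        model = study.pairs[PM25].c_all
        params = fit_fusion_params(study.monitors, model)
        zero_w = WeightField(grid, np.zeros((grid.ny, grid.nx)))
        fused = fuse(model, study.monitors, params, zero_w)
        np.testing.assert_allclose(
            fused.values, np.maximum(params.adjusted_model(model), 0.0), rtol=1e-12
        )

    def test_identity_observations_reproduce_model(self, study):
        model = study.pairs[PM25].c_all
        m = collocate(model, study.monitors[:5])
        mons = [
            MonitorSeries(s.site_id, s.x_km, s.y_km, s.species, m[i].copy())
            for i, s in enumerate(study.monitors[:5])
        ]
        params = fit_fusion_params(mons, model)
        weights = build_weight_field(mons, params, study.grid)
        fused = fuse(model, mons, params, weights)
        np.testing.assert_allclose(fused.values, model.values, rtol=1e-6)

    def test_monitor_fidelity_noise_free(self, study):
        """Fused values reproduce the biased observation truth at monitor cells."""
        model = study.pairs[PM25].c_all
        params = fit_fusion_params(study.monitors, model)
        weights = build_weight_field(study.monitors, params, study.grid)
        fused = fuse(model, study.monitors, params, weights)
        for m in study.monitors:
            iy, ix = study.grid.cell_of(m.x_km, m.y_km)
            np.testing.assert_allclose(fused.values[:, iy, ix], m.values, rtol=1e-9)


class TestAdjustBurnImpact:
    def test_ratio_arithmetic(self, small_grid):
        shape = (small_grid.n_days, small_grid.ny, small_grid.nx)
        pair = ScenarioPair(
            ConcentrationField(small_grid, PM25, np.full(shape, 5.0)),
            ConcentrationField(small_grid, PM25, np.full(shape, 3.0)),
        )
        fused = ConcentrationField(small_grid, PM25, np.full(shape, 10.0))
        out = adjust_burn_impact(fused, pair)
        np.testing.assert_allclose(out.values, 4.0)

    def test_zero_model_impact_gives_zero(self, small_grid):
        shape = (small_grid.n_days, small_grid.ny, small_grid.nx)
        pair = ScenarioPair(
            ConcentrationField(small_grid, PM25, np.full(shape, 5.0)),
            ConcentrationField(small_grid, PM25, np.full(shape, 5.0)),
        )
        fused = ConcentrationField(small_grid, PM25, np.full(shape, 99.0))
        assert np.all(adjust_burn_impact(fused, pair).values == 0)

    def test_below_floor_returns_zero(self, small_grid):
        shape = (small_grid.n_days, small_grid.ny, small_grid.nx)
        pair = ScenarioPair(
            ConcentrationField(small_grid, PM25, np.full(shape, 0.05)),
            ConcentrationField(small_grid, PM25, np.full(shape, 0.01)),
        )
        fused = ConcentrationField(small_grid, PM25, np.full(shape, 1.0))
        assert np.all(adjust_burn_impact(fused, pair).values == 0)

    def test_negative_impact_preserved(self, small_grid):
        shape = (small_grid.n_days, small_grid.ny, small_grid.nx)
        pair = ScenarioPair(
            ConcentrationField(small_grid, "MDA8-O3", np.full(shape, 40.0)),
            ConcentrationField(small_grid, "MDA8-O3", np.full(shape, 42.0)),
        )
        fused = ConcentrationField(small_grid, "MDA8-O3", np.full(shape, 40.0))
        assert np.all(adjust_burn_impact(fused, pair).values < 0)
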