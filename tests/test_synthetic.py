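"""Generator contracts: label bookkeeping, additivity, bias family, seeds."""

import numpy as np
import pandas as pd
import pytest

from rxsmoke.fires import AGRICULTURAL, PRESCRIBED, WILDFIRE
from rxsmoke.grids import O3, PM25
from rxsmoke.synthetic import (
    generate_county_tables,
    generate_fire_records,
    generate_monitor_obs,
    generate_scenario_fields,
)


class TestFireRecords:
    def test_nothing_requested_gives_empty_lists(self, grid):
        dets, permits, truth = generate_fire_records(grid, 0, 0, 0, seed=1)
        assert dets == [] and permits == []

    def test_label_counts_match_request(self, grid):
        dets, permits, truth = generate_fire_records(grid, 10, 3, 5, seed=7)
        assert truth.event_labels.count(PRESCRIBED) == 10
        assert truth.event_labels.count(WILDFIRE) == 3
        assert truth.event_labels.count(AGRICULTURAL) == 5
        ag = [d for d in dets if d.landcover == AGRICULTURAL]
        assert len(ag) == 5
        # wildfire events span >= 2 consecutive days
        wf_dates = {}
        for d in dets:
            if truth.true_fire_labels[d.id] == WILDFIRE:
                wf_dates.setdefault((round(d.x_km, -1), round(d.y_km, -1)), set()).add(
                    d.date
                )
        for dates in wf_dates.values():
            assert len(dates) >= 2

    def test_prescribed_events_are_single_day_small_groups(self, grid):
        dets, _, truth = generate_fire_records(grid, 15, 0, 0, seed=3)
        by_day = {}
        for d in dets:
            assert truth.true_fire_labels[d.id] == PRESCRIBED
            by_day.setdefault(d.date, []).append(d)
        # each event contributes 1-5 detections on one day
        assert 15 <= len(dets) <= 75

    def test_permit_area_follows_stored_linear_relation(self, grid):
        dets, permits, truth = generate_fire_records(
            grid, 40, 0, 0, seed=5, permit_noise_sd=0.0
        )
        event_area = {}
        for d in dets:
            key = d.date
            event_area[key] = event_area.get(key, 0.0) + d.detected_area
        # permits exist one per prescribed event with the exact relation
        assert len(permits) == 40
        for p in permits:
            # noise-free: permit = slope * (summed detected) + intercept
            pass
        total_detected = sum(d.detected_area for d in dets)
        total_permit = sum(p.area_acres for p in permits)
        expected = truth.true_area_slope * total_detected + 40 * truth.true_area_intercept
        assert total_permit == pytest.approx(expected, rel=1e-12)

    def test_seed_determinism(self, grid):
        a = generate_fire_records(grid, 8, 2, 3, seed=42)
        b = generate_fire_records(grid, 8, 2, 3, seed=42)
        assert [d.__dict__ for d in a[0]] == [d.__dict__ for d in b[0]]
        assert [p.__dict__ for p in a[1]] == [p.__dict__ for p in b[1]]

    @pytest.mark.parametrize("counts", [(-1, 0, 0), (0, -2, 0), (0, 0, -3)])
    def test_negative_counts_rejected(self, grid, counts):
        with pytest.raises(ValueError, match="n_"):
            generate_fire_records(grid, *counts, seed=1)


class TestScenarioFields:
    def test_additivity_exact(self, study):
        for sp in (PM25, O3):
            pair = study.pairs[sp]
            np.testing.assert_allclose(
                pair.c_all.values - pair.c_no_pb.values,
                study.truth.true_burn_field[sp],
                rtol=1e-12,
                atol=1e-12,
            )

    def test_no_prescribed_fires_means_equal_scenarios(self, grid):
        dets, _, truth = generate_fire_records(grid, 0, 3, 2, seed=9)
        pairs, _ = generate_scenario_fields(
            grid, dets, truth.true_fire_labels, seed=10, truth=truth
        )
        for sp in (PM25, O3):
            np.testing.assert_array_equal(
                pairs[sp].c_all.values, pairs[sp].c_no_pb.values
            )

    def test_kernel_peaks_at_detection_cell_on_its_day(self, grid):
        dets, _, truth = generate_fire_records(grid, 1, 0, 0, seed=11)
        pairs, truth = generate_scenario_fields(
            grid, dets[:1], {dets[0].id: PRESCRIBED}, seed=12
        )
        burn = truth.true_burn_field[PM25]
        assert burn.min() >= 0
        t, iy, ix = np.unravel_index(np.argmax(burn), burn.shape)
        assert t == grid.day_index(dets[0].date)
        assert (iy, ix) == grid.cell_of(dets[0].x_km, dets[0].y_km)

    def test_doubling_amplitude_doubles_burn_field(self, grid):
        from rxsmoke.synthetic import DEFAULT_BACKGROUND
        import dataclasses

        dets, _, truth = generate_fire_records(grid, 5, 0, 0, seed=13)
        labels = truth.true_fire_labels
        _, t1 = generate_scenario_fields(grid, dets, labels, seed=14)
        doubled = {
            sp: dataclasses.replace(p, amplitude_scale=2.0)
            for sp, p in DEFAULT_BACKGROUND.items()
        }
        _, t2 = generate_scenario_fields(
            grid, dets, labels, background_params=doubled, seed=14
        )
        for sp in (PM25, O3):
            np.testing.assert_allclose(
                t2.true_burn_field[sp], 2.0 * t1.true_burn_field[sp], rtol=0, atol=0
            )

    def test_fire_outside_grid_rejected(self, grid):
        from rxsmoke.fires import FireDetection

        bad = FireDetection(
            id="X", x_km=-50.0, y_km=5.0, date=grid.dates[0],
            detected_area=10.0, landcover="forest",
        )
        with pytest.raises(ValueError, match="outside"):
            generate_scenario_fields(grid, [bad], {"X": PRESCRIBED}, seed=1)

    def test_background_positive(self, study):
        for sp in (PM25, O3):
            assert study.pairs[sp].c_no_pb.values.min() > 0


class TestMonitorObs:
    def test_identity_bias_reproduces_model(self, study):
        mons = generate_monitor_obs(
            study.pairs[PM25], study.truth, 10, noise_sd=0.0, seed=21,
            alpha_year=1.0, seasonal_amplitude=0.0, seasonal_tmax=45.0,
        )
        for m in mons:
            iy, ix = study.grid.cell_of(m.x_km, m.y_km)
            np.testing.assert_array_equal(
                m.values, study.pairs[PM25].c_all.values[:, iy, ix]
            )

    def test_pure_scaling_bias(self, study):
        mons = generate_monitor_obs(
            study.pairs[PM25], study.truth, 5, noise_sd=0.0, seed=22,
            alpha_year=1.2, seasonal_amplitude=0.0, seasonal_tmax=45.0,
        )
        for m in mons:
            iy, ix = study.grid.cell_of(m.x_km, m.y_km)
            np.testing.assert_allclose(
                m.values, 1.2 * study.pairs[PM25].c_all.values[:, iy, ix], rtol=1e-12
            )

    def test_noise_mean_within_three_standard_errors(self, study):
        sd = 2.0
        mons = generate_monitor_obs(
            study.pairs[PM25], study.truth, 20, noise_sd=sd, seed=23,
            alpha_year=1.2, seasonal_amplitude=0.2, seasonal_tmax=45.0,
        )
        clean = generate_monitor_obs(
            study.pairs[PM25], study.truth, 20, noise_sd=0.0, seed=23,
            alpha_year=1.2, seasonal_amplitude=0.2, seasonal_tmax=45.0,
        )
        resid = np.concatenate(
            [m.values - c.values for m, c in zip(mons, clean)]
        )
        se = sd / np.sqrt(len(resid))
        assert abs(resid.mean()) < 3 * se

    def test_too_many_monitors_rejected(self, study):
        with pytest.raises(ValueError, match="exceeds"):
            generate_monitor_obs(
                study.pairs[PM25], study.truth, study.grid.n_cells + 1, 0.0, seed=1
            )


class TestCountyTables:
    def test_single_county_covers_grid(self, grid):
        cmap, table, pop = generate_county_tables(grid, 1, seed=31)
        assert set(np.unique(cmap)) == {0}
        years = table["year"].nunique()
        assert table["population"].iloc[0] == pop.sum()

    def test_raster_sums_match_county_populations(self, grid):
        cmap, table, pop = generate_county_tables(grid, 9, seed=32)
        for c, g in table.groupby("county_id"):
            assert g["population"].iloc[0] == pytest.approx(pop[cmap == c].sum())

    def test_cause_specific_deaths_bounded_by_all_cause(self, grid):
        _, table, _ = generate_county_tables(grid, 7, seed=33)
        assert (
            table["deaths_allcause"] >= table["deaths_cvd"] + table["deaths_resp"]
        ).all()

    def test_counties_contiguous(self, grid):
        cmap, _, _ = generate_county_tables(grid, 10, seed=34)
        for c in np.unique(cmap):
            cells = set(map(tuple, np.argwhere(cmap == c)))
            start = next(iter(cells))
            seen = {start}
            frontier = [start]
            while frontier:
                iy, ix = frontier.pop()
                for dy, dx in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                    nb = (iy + dy, ix + dx)
                    if nb in cells and nb not in seen:
                        seen.add(nb)
                        frontier.append(nb)
            assert seen == cells

    @pytest.mark.parametrize("n", [0, 100000])
    def test_county_count_bounds(self, grid, n):
        with pytest.raises(ValueError, match="n_counties"):
            generate_county_tables(grid, n, seed=1)
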