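"""End-to-end orchestration: config validation, staged runs, manifests.

A run is a pure function of its config: synthesize inputs, classify fires,
difference the scenarios, fuse with observations, adjust the burn impact,
estimate mortality, cross-validate — writing every intermediate artifact
plus a manifest of seeds, config hash and per-stage counts. Rerunning the
same config reproduces the artifacts bit for bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import pathlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import fires as fr
from . import fusion as fu
from . import health as he
from . import io as rio
from . import synthetic as syn
from .evaluation import run_kfold_cv
from .grids import O3, PM25, GridSpec

__all__ = ["RunConfig", "validate_config", "run_pipeline", "default_config_dict"]

logger = logging.getLogger(__name__)

_TOP_KEYS = {
    "grid",
    "seeds",
    "fires",
    "monitors",
    "bias",
    "amplitude_scale",
    "counties",
    "fusion",
    "crc",
    "health",
    "evaluation",
    "output_dir",
}

_STAGE_SEEDS = ("fires", "fields", "monitors", "counties", "cv")

#: placeholder CR-coefficients (per unit: per ug/m3 / per ppb) at literature
#: magnitudes; replace with study-specific values for real analyses
DEFAULT_CRC = [
    {"pollutant": PM25, "cause": "all-cause", "beta": 0.0019, "beta_low": 0.0016, "beta_high": 0.0022},
    {"pollutant": PM25, "cause": "cardiovascular", "beta": 0.0017, "beta_low": 0.0010, "beta_high": 0.0024},
    {"pollutant": PM25, "cause": "respiratory", "beta": 0.0019, "beta_low": 0.0009, "beta_high": 0.0029},
    {"pollutant": O3, "cause": "all-cause", "beta": 0.00043, "beta_low": 0.00028, "beta_high": 0.00058},
    {"pollutant": O3, "cause": "cardiovascular", "beta": 0.00045, "beta_low": 0.00020, "beta_high": 0.00070},
    {"pollutant": O3, "cause": "respiratory", "beta": 0.00050, "beta_low": 0.00020, "beta_high": 0.00080},
]

_CAUSE_COLUMNS = {
    "all-cause": "deaths_allcause",
    "cardiovascular": "deaths_cvd",
    "respiratory": "deaths_resp",
}


def default_config_dict() -> dict:
    return {
        "grid": {
            "origin_x": 0.0,
            "origin_y": 0.0,
            "nx": 20,
            "ny": 20,
            "cell_size_km": 4.0,
            "date_start": "2015-01-01",
            "date_end": "2017-12-31",
        },
        "seeds": {"fires": 11, "fields": 12, "monitors": 13, "counties": 14, "cv": 15},
        "fires": {"n_prescribed": 400, "n_wildfire": 10, "n_agricultural": 40},
        "monitors": {
            "n_pm25": 30,
            "n_o3": 30,
            "noise_sd_pm25": 2.0,
            "noise_sd_o3": 3.0,
        },
        "bias": {"alpha": 1.2, "amplitude": 0.2, "t_max": 45.0},
        "amplitude_scale": 1.0,
        "counties": {"n": 12},
        "fusion": {"floor_pm25": 0.1, "floor_o3": 1.0},
        "crc": [dict(c) for c in DEFAULT_CRC],
        "health": {"variant": "county"},
        "evaluation": {"k": 10, "fraction": 0.1},
        "output_dir": "runs/demo",
    }


@dataclass
class RunConfig:
    grid: GridSpec
    seeds: dict[str, int]
    fire_counts: dict[str, int]
    monitors: dict[str, float]
    bias: dict[str, float]
    amplitude_scale: float
    n_counties: int
    floors: dict[str, float]
    crc: list[he.CRCoefficient]
    health_variant: str
    evaluation: dict[str, float]
    output_dir: pathlib.Path
    raw: dict = field(default_factory=dict, repr=False)


def _merge_defaults(user: dict, defaults: dict) -> dict:
    out = dict(defaults)
    for k, v in user.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = {**out[k], **v}
        else:
            out[k] = v
    return out


def validate_config(path) -> RunConfig:
    """Parse, default-fill and sanity-check a YAML run config."""
    path = pathlib.Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    user = yaml.safe_load(path.read_text()) or {}
    unknown = set(user) - _TOP_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    cfg = _merge_defaults(user, default_config_dict())

    g = cfg["grid"]
    grid = GridSpec(
        origin_x=float(g["origin_x"]),
        origin_y=float(g["origin_y"]),
        nx=int(g["nx"]),
        ny=int(g["ny"]),
        cell_size=float(g["cell_size_km"]),
        date_start=str(g["date_start"]),
        date_end=str(g["date_end"]),
    )
    seeds = {k: int(v) for k, v in cfg["seeds"].items()}
    missing = set(_STAGE_SEEDS) - set(seeds)
    if missing:
        raise ValueError(f"missing stage seeds: {sorted(missing)}")

    # CRCoefficient's constructor enforces the per-unit magnitude guard
    crc = [
        he.CRCoefficient(
            pollutant=c["pollutant"],
            cause=c["cause"],
            beta_central=float(c["beta"]),
            beta_low=float(c["beta_low"]),
            beta_high=float(c["beta_high"]),
        )
        for c in cfg["crc"]
    ]
    variant = cfg["health"]["variant"]
    if variant not in {"county", "gridded", "daily"}:
        raise ValueError(f"health variant must be county|gridded|daily, got {variant}")

    return RunConfig(
        grid=grid,
        seeds=seeds,
        fire_counts={k: int(v) for k, v in cfg["fires"].items()},
        monitors=cfg["monitors"],
        bias={k: float(v) for k, v in cfg["bias"].items()},
        amplitude_scale=float(cfg["amplitude_scale"]),
        n_counties=int(cfg["counties"]["n"]),
        floors={
            PM25: float(cfg["fusion"]["floor_pm25"]),
            O3: float(cfg["fusion"]["floor_o3"]),
        },
        crc=crc,
        health_variant=variant,
        evaluation=cfg["evaluation"],
        output_dir=pathlib.Path(cfg["output_dir"]),
        raw=cfg,
    )


def build_calibration_pairs(
    detections: list[fr.FireDetection],
    permits: list[syn.PermitRecord],
    clusters: list[fr.FireCluster],
    grid: GridSpec,
) -> list[tuple[float, float]]:
    """(detected, permit) area pairs matched at grid-cell/day level.

    Detected areas of prescribed clusters and permit areas are summed per
    (cell, date); only cells with nonzero permit area enter the fit.
    """
    det_by_key: dict[tuple[int, int, str], float] = {}
    for c in clusters:
        if c.label != fr.PRESCRIBED:
            continue
        key = (*grid.cell_of(c.centroid_x, c.centroid_y), c.start_date.date().isoformat())
        det_by_key[key] = det_by_key.get(key, 0.0) + c.total_detected_area
    per_by_key: dict[tuple[int, int, str], float] = {}
    for p in permits:
        key = (*grid.cell_of(p.x_km, p.y_km), pd.Timestamp(p.date).date().isoformat())
        per_by_key[key] = per_by_key.get(key, 0.0) + p.area_acres
    pairs = [
        (det_by_key[k], per_by_key[k])
        for k in sorted(det_by_key)
        if per_by_key.get(k, 0.0) > 0
    ]
    return pairs


def _sha256(path: pathlib.Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _species_tag(species: str) -> str:
    return "pm25" if species == PM25 else "o3"


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage, write artifacts, return the manifest dict."""
    out = config.output_dir
    out.mkdir(parents=True, exist_ok=True)
    grid = config.grid
    artifacts: dict[str, str] = {}
    counts: dict[str, int | float] = {}

    def save_table(df: pd.DataFrame, name: str) -> None:
        p = out / name
        df.to_csv(p, index=False)
        artifacts[name] = _sha256(p)

    # --- stage 1: synthetic fire records ------------------------------------
    stage = "synthetic_fires"
    try:
        detections, permits, truth = syn.generate_fire_records(
            grid,
            config.fire_counts["n_prescribed"],
            config.fire_counts["n_wildfire"],
            config.fire_counts["n_agricultural"],
            seed=config.seeds["fires"],
        )
        rio.write_detections(detections, out / "detections.csv")
        artifacts["detections.csv"] = _sha256(out / "detections.csv")
        rio.write_permits(permits, out / "permits.csv")
        artifacts["permits.csv"] = _sha256(out / "permits.csv")
        counts["n_detections"] = len(detections)
        counts["n_permits"] = len(permits)

        # --- stage 2: prescribed-burn identification ------------------------
        stage = "fire_classification"
        kept, removed = fr.filter_agricultural(detections)
        clusters = fr.classify_clusters(fr.cluster_detections(kept))
        if permits:
            pairs = build_calibration_pairs(kept, permits, clusters, grid)
            cal = fr.fit_area_calibration(pairs) if len(pairs) >= 2 else None
        else:
            cal = None
        if cal is not None:
            clusters = fr.apply_area_calibration(clusters, cal)
        save_table(fr.clusters_to_frame(clusters), "clusters.csv")
        counts["n_clusters"] = len(clusters)
        counts["n_agricultural_removed"] = len(removed)
        if cal is not None:
            counts["area_calibration_slope"] = cal.slope
            counts["area_calibration_r2"] = cal.r_squared

        # --- stage 3: scenario fields ---------------------------------------
        stage = "scenario_fields"
        bg = {
            sp: dataclasses.replace(p, amplitude_scale=config.amplitude_scale)
            for sp, p in syn.DEFAULT_BACKGROUND.items()
        }
        pairs_by_species, truth = syn.generate_scenario_fields(
            grid,
            detections,
            truth.true_fire_labels,
            background_params=bg,
            seed=config.seeds["fields"],
            truth=truth,
        )
        for sp, pr in pairs_by_species.items():
            tag = _species_tag(sp)
            rio.write_field_netcdf(pr.c_all, out / f"c_all_{tag}.nc")
            rio.write_field_netcdf(pr.c_no_pb, out / f"c_nopb_{tag}.nc")
            artifacts[f"c_all_{tag}.nc"] = _sha256(out / f"c_all_{tag}.nc")
            artifacts[f"c_nopb_{tag}.nc"] = _sha256(out / f"c_nopb_{tag}.nc")
        counts["n_days"] = grid.n_days
        counts["n_cells"] = grid.n_cells

        # --- stage 4: monitors ----------------------------------------------
        stage = "monitor_observations"
        mon_cfg = config.monitors
        monitors = {}
        for sp, n_key, sd_key, seed_off in (
            (PM25, "n_pm25", "noise_sd_pm25", 0),
            (O3, "n_o3", "noise_sd_o3", 1),
        ):
            monitors[sp] = syn.generate_monitor_obs(
                pairs_by_species[sp],
                truth,
                int(mon_cfg[n_key]),
                float(mon_cfg[sd_key]),
                seed=config.seeds["monitors"] + seed_off,
                alpha_year=config.bias["alpha"],
                seasonal_amplitude=config.bias["amplitude"],
                seasonal_tmax=config.bias["t_max"],
            )
            tag = _species_tag(sp)
            rio.write_monitors(monitors[sp], grid, out / f"monitors_{tag}.csv")
            artifacts[f"monitors_{tag}.csv"] = _sha256(out / f"monitors_{tag}.csv")
        counts["n_monitors_pm25"] = len(monitors[PM25])
        counts["n_monitors_o3"] = len(monitors[O3])

        # --- stage 5: fusion and observation-adjusted burn impact -----------
        stage = "fusion"
        impacts = {}
        for sp in (PM25, O3):
            tag = _species_tag(sp)
            pr = pairs_by_species[sp]
            params = fu.fit_fusion_params(
                monitors[sp], pr.c_all, floor=config.floors[sp]
            )
            weights = fu.build_weight_field(monitors[sp], params, grid)
            fused = fu.fuse(pr.c_all, monitors[sp], params, weights)
            impact = fu.adjust_burn_impact(fused, pr, floor=config.floors[sp])
            impacts[sp] = impact
            rio.write_params(params, out / f"fusion_params_{tag}.txt")
            rio.write_field_netcdf(fused, out / f"c_all_df_{tag}.nc")
            rio.write_field_netcdf(impact, out / f"impact_df_{tag}.nc")
            for name in (
                f"fusion_params_{tag}.txt",
                f"c_all_df_{tag}.nc",
                f"impact_df_{tag}.nc",
            ):
                artifacts[name] = _sha256(out / name)

        # --- stage 6: counties, exposure, mortality -------------------------
        stage = "health"
        county_map, county_table, pop_raster = syn.generate_county_tables(
            grid, config.n_counties, seed=config.seeds["counties"]
        )
        rio.write_county_map(county_map, out / "county_map.txt")
        artifacts["county_map.txt"] = _sha256(out / "county_map.txt")
        save_table(county_table, "county_table.csv")
        np.savetxt(out / "population.txt", pop_raster, fmt="%.1f")
        artifacts["population.txt"] = _sha256(out / "population.txt")

        years = sorted(np.unique(grid.years))
        exp_rows, mort_rows = [], []
        estimates_by_group: dict[tuple[str, str], list[he.MortalityEstimate]] = {}
        registered = county_table.set_index(["county_id", "year"])
        for sp in (PM25, O3):
            for year in years:
                exposures = he.regrid_to_county(impacts[sp], county_map, int(year))
                for e in exposures:
                    exp_rows.append(
                        {
                            "county_id": e.county_id,
                            "year": e.year,
                            "pollutant": e.pollutant,
                            "annual_mean_delta": e.annual_mean_delta,
                        }
                    )
                for crc in config.crc:
                    if crc.pollutant != sp:
                        continue
                    col = _CAUSE_COLUMNS[crc.cause]
                    ests = [
                        he.crf_excess_deaths(
                            e,
                            float(registered.loc[(e.county_id, e.year), col]),
                            crc,
                        )
                        for e in exposures
                    ]
                    estimates_by_group.setdefault((sp, crc.cause), []).extend(ests)
                    dom = he.aggregate_mortality(ests, scope="domain")
                    mort_rows.append(
                        {
                            "scope": "domain",
                            "year": int(year),
                            "pollutant": sp,
                            "cause": crc.cause,
                            "central": dom.deaths_central,
                            "low": dom.deaths_low,
                            "high": dom.deaths_high,
                        }
                    )
        for (sp, cause), ests in sorted(estimates_by_group.items()):
            tot = he.aggregate_mortality(ests, scope="domain")
            mort_rows.append(
                {
                    "scope": "domain",
                    "year": "all",
                    "pollutant": sp,
                    "cause": cause,
                    "central": tot.deaths_central,
                    "low": tot.deaths_low,
                    "high": tot.deaths_high,
                }
            )
        save_table(pd.DataFrame(exp_rows), "county_exposures.csv")
        save_table(pd.DataFrame(mort_rows), "mortality.csv")
        for sp in (PM25, O3):
            counts[f"pop_weighted_exposure_{_species_tag(sp)}"] = (
                he.population_weighted_exposure(impacts[sp], pop_raster)
            )
        total_all_cause = sum(
            r["central"]
            for r in mort_rows
            if r["year"] == "all" and r["cause"] == "all-cause"
        )
        counts["total_all_cause_deaths_central"] = total_all_cause

        # --- stage 7: cross-validation ---------------------------------------
        stage = "evaluation"
        ev = config.evaluation
        metric_rows = []
        for sp in (PM25, O3):
            cv = run_kfold_cv(
                monitors[sp],
                pairs_by_species[sp].c_all,
                k=int(ev["k"]),
                fraction=float(ev["fraction"]),
                seed=config.seeds["cv"],
                floor=config.floors[sp],
            )
            for label, m in (("fused", cv.pooled), ("raw_model", cv.pooled_model)):
                metric_rows.append(
                    {
                        "species": sp,
                        "scheme": cv.scheme,
                        "which": label,
                        "r_squared": m.r_squared,
                        "mean_bias": m.mean_bias,
                        "rmse": m.rmse,
                        "nmb_percent": m.nmb_percent,
                        "n_pairs": m.n_pairs,
                    }
                )
        save_table(pd.DataFrame(metric_rows), "cv_metrics.csv")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc

    config_hash = hashlib.sha256(
        json.dumps(config.raw, sort_keys=True, default=str).encode()
    ).hexdigest()
    manifest = {
        "config_hash": config_hash,
        "seeds": config.seeds,
        "artifacts": dict(sorted(artifacts.items())),
        "counts": counts,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    logger.info("pipeline complete: %d artifacts in %s", len(artifacts), out)
    return manifest
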