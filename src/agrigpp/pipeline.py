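"""End-to-end pipeline: simulate -> GPP -> aggregate -> filter ->
calibrate -> validate -> normalize.

The pipeline is a pure function of (config, seed): rerunning with the same
inputs produces byte-identical text artifacts. Validation follows the
calibrate-on-year-y / apply-to-year-y+1 protocol, so the driver simulates
two consecutive seasons that share the same ground-truth harvest indices.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import yaml

from . import vpm
from .calibration import (CropCoefficients, calibrate_all, compute_nrmse,
                          compute_r2, production_to_gpp, validate_next_year)
from .districts import (aggregate_district, build_filter_table,
                        district_gpp_frame, filter_districts)
from .io import CSV_FLOAT_FORMAT, write_scene, write_table
from .ngppcy import compute_ngppcy, district_yields_from_stats
from .raster import write_ascii_grid
from .synthetic import (DEFAULT_COEFFICIENTS, DEFAULT_MONSOON_CROPS,
                        DEFAULT_WINTER_CROPS, SceneConfig, SyntheticScene,
                        draw_true_hi, generate_crop_stats, generate_scene)

logger = logging.getLogger("agrigpp")

import pandas as pd


def coefficients_from_config(cfg: dict | None) -> dict[str, CropCoefficients]:
    """Coefficient table from a config mapping; defaults when absent."""
    if not cfg:
        return dict(DEFAULT_COEFFICIENTS)
    out = {}
    for crop, c in cfg.items():
        out[crop] = CropCoefficients(
            crop=crop, hi_lower=float(c["hi_lower"]), hi_upper=float(c["hi_upper"]),
            rc=float(c["rc"]), mc=float(c["mc"]),
            fixed_hi=(float(c["fixed_hi"]) if c.get("fixed_hi") is not None else None))
    return out


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError("pipeline config must be a YAML mapping")
    return cfg


def compute_seasonal_gpp(scene: SyntheticScene):
    """Seasonal GPP raster from a scene's emitted driver stacks."""
    lswi_max = vpm.compute_lswi_max(scene.lswi_stack)
    layers = np.empty_like(scene.ndvi_stack.layers)
    for k in range(len(scene.ndvi_stack)):
        layers[k] = vpm.compute_gpp_composite(
            scene.ndvi_stack.layers[k], scene.lswi_stack.layers[k],
            lswi_max.data, scene.par_stack.layers[k],
            scene.tday_stack.layers[k], scene.prop_c3.data,
            scene.prop_c4.data)
    from .raster import CompositeStack

    stack = CompositeStack(layers, list(scene.ndvi_stack.start_dates),
                           scene.grid, "gpp", "gC m-2")
    return vpm.integrate_season(stack, scene.cropland_mask)


def default_crops(season: str) -> list[str]:
    return list(DEFAULT_MONSOON_CROPS if season == "monsoon" else DEFAULT_WINTER_CROPS)


def run_pipeline(config: dict, seed: int, outdir) -> dict:
    """Execute the full pipeline and write all artifacts under ``outdir``.

    Returns the metrics dictionary (also written as ``metrics.json``).
    """
    t0 = time.time()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    scene_cfg = config.get("scene", {})
    season = scene_cfg.get("season", "monsoon")
    crops = config.get("crops") or default_crops(season)
    coeffs = coefficients_from_config(config.get("coefficients"))
    for crop in crops:
        if crop not in coeffs:
            raise ValueError(f"pre-flight: crop {crop!r} has no coefficients")
    filters = config.get("filters", {})
    backend = config.get("solver_backend", "shared_s")
    noise_prod = scene_cfg.get("noise_sd_production",
                               SceneConfig.noise_sd_production)

    def stage(name):
        logger.info("stage %-10s t=%.2fs", name, time.time() - t0)

    # --- simulate two consecutive seasons sharing the true harvest indices
    stage("simulate")
    base = SceneConfig(**{**scene_cfg, "rng_seed": seed})
    true_hi = draw_true_hi(coeffs, crops, seed)
    scenes, stats, gpp_frames, gpp_rasters = {}, {}, {}, {}
    for offset in (0, 1):
        cfg_y = dataclasses.replace(base, year=base.year + offset,
                                    rng_seed=seed + offset)
        scene = generate_scene(cfg_y)
        st = generate_crop_stats(scene, crops, coeffs,
                                 production_noise_sd=noise_prod,
                                 true_hi=true_hi, rng_seed=seed + 100 + offset)
        scenes[cfg_y.year], stats[cfg_y.year] = scene, st
        write_scene(scene, outdir / f"scene_{cfg_y.year}", stats=st)

    # --- VPM GPP, aggregation and filters per year
    for year, scene in scenes.items():
        stage(f"gpp {year}")
        gpp = compute_seasonal_gpp(scene)
        gpp_rasters[year] = gpp
        write_ascii_grid(gpp, outdir / f"seasonal_gpp_{season}_{year}.asc")
        stage(f"aggregate {year}")
        agg = aggregate_district(gpp, scene.district_labels,
                                 scene.cropland_mask, season, year)
        frame = district_gpp_frame(agg)
        table = filter_districts(
            build_filter_table(stats[year], agg),
            min_area_ha=filters.get("min_area_ha", 75_000.0),
            min_considered_share=filters.get("min_considered_share", 0.30))
        frame = frame.merge(table[["district_id", "considered_share",
                                   "retained", "exclusion_reason"]],
                            on="district_id")
        gpp_frames[year] = frame
        write_table(frame, outdir / f"district_gpp_{year}.csv")

    year0, year1 = sorted(scenes)
    retained = set(gpp_frames[year0].loc[gpp_frames[year0]["retained"],
                                         "district_id"].astype(int))

    # --- calibration on year0
    stage("calibrate")
    results = calibrate_all(gpp_frames[year0], stats[year0], coeffs,
                            retained_ids=retained, backend=backend)
    calib_rows = []
    for r in results:
        for crop, h in sorted(r.hi.items()):
            calib_rows.append({
                "district_id": r.district_id, "season": season, "year": r.year,
                "crop": crop, "hi": h, "residual_z_gc": r.residual_z,
                "at_bound": bool(r.at_bound.get(crop, False)),
                "objective_evals": r.objective_evals,
            })
    write_table(pd.DataFrame(calib_rows), outdir / f"calibration_{year0}.csv")
    calib_pairs = pd.DataFrame([
        {"district_id": r.district_id,
         "sat_gpp": float(gpp_frames[year0].set_index("district_id")
                          .loc[r.district_id, "sat_gpp_total_gc"]),
         "stat_gpp": production_to_gpp(
             stats[year0][stats[year0]["district_id"] == r.district_id],
             r.hi, coeffs)}
        for r in results])

    # --- validation on year1 with year0 coefficients
    stage("validate")
    val_pairs, skipped = validate_next_year(
        results, stats[year1][stats[year1]["district_id"].isin(retained)],
        gpp_frames[year1], coeffs)
    write_table(val_pairs, outdir / f"validation_pairs_{year1}.csv")

    # --- normalized yield raster for year0
    stage("normalize")
    yields = district_yields_from_stats(stats[year0], season, year0)
    ngppcy = compute_ngppcy(gpp_rasters[year0], scenes[year0].district_labels,
                            yields)
    tag = "M" if season == "monsoon" else "W"
    write_ascii_grid(ngppcy, outdir / f"NGPPCY-{tag}{year0}.asc")

    hi_err = max(abs(r.hi[c] - true_hi[c]) for r in results
                 for c in r.hi if coeffs[c].fixed_hi is None) if results else float("nan")
    metrics = {
        "season": season, "calibration_year": year0, "validation_year": year1,
        "n_districts_retained": len(retained),
        "n_districts_skipped_validation": len(skipped),
        "calibration_r2": compute_r2(calib_pairs),
        "calibration_nrmse_pct": compute_nrmse(calib_pairs),
        "validation_r2": compute_r2(val_pairs),
        "validation_nrmse_pct": compute_nrmse(val_pairs),
        "max_abs_hi_error": hi_err,
    }
    (outdir / "metrics.json").write_text(json.dumps(metrics, indent=2,
                                                    sort_keys=True))
    manifest = {
        "seed": seed,
        "config_sha256": hashlib.sha256(
            json.dumps(config, sort_keys=True, default=str).encode()).hexdigest(),
        "artifacts": sorted(p.name for p in outdir.iterdir()),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                     sort_keys=True))
    stage("done")
    return metrics
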