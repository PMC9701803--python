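"""Scene and table serialization.

A scene directory holds one ASCII grid per stack layer plus static
rasters, a ``scene.json`` manifest (config, composite dates, variables),
the crop-statistics CSV and a ``truth.json`` sidecar with the generator's
ground truth. Everything is plain text; CSV floats use 9 significant
digits.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .raster import CompositeStack, Raster, read_ascii_grid, write_ascii_grid
from .synthetic import SceneConfig, SceneTruth, SyntheticScene

CSV_FLOAT_FORMAT = "%.9g"

_STACKS = ("ndvi", "lswi", "par", "tday")
_STATICS = ("prop_c3", "prop_c4", "cropland_mask", "district_labels")


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, float_format=CSV_FLOAT_FORMAT)


def write_stack(stack: CompositeStack, outdir: Path, name: str) -> None:
    for i in range(len(stack)):
        write_ascii_grid(stack.layer(i), outdir / f"{name}_{i:02d}.asc")


def read_stack(outdir: Path, name: str, dates, variable="", units="") -> CompositeStack:
    layers = [read_ascii_grid(outdir / f"{name}_{i:02d}.asc").data
              for i in range(len(dates))]
    grid = read_ascii_grid(outdir / f"{name}_00.asc").grid
    return CompositeStack(np.array(layers), list(dates), grid, variable, units)


def write_scene(scene: SyntheticScene, outdir, stats: pd.DataFrame | None = None) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name in _STACKS:
        write_stack(getattr(scene, f"{name}_stack"), outdir, name)
    for name in _STATICS:
        write_ascii_grid(getattr(scene, name), outdir / f"{name}.asc")
    manifest = {
        "config": dataclasses.asdict(scene.config),
        "start_dates": [d.isoformat() for d in scene.ndvi_stack.start_dates],
    }
    (outdir / "scene.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    truth = scene.truth
    sidecar = {
        "true_hi": truth.true_hi,
        "true_rc": truth.true_rc,
        "true_mc": truth.true_mc,
        "district_gpp_totals_gc": {str(k): v for k, v in truth.district_gpp_totals.items()},
        "district_area_ha": {str(k): v for k, v in truth.district_area_ha.items()},
    }
    (outdir / "truth.json").write_text(json.dumps(sidecar, indent=2, sort_keys=True))
    if truth.true_seasonal_gpp is not None:
        write_ascii_grid(truth.true_seasonal_gpp, outdir / "true_seasonal_gpp.asc")
    if stats is not None:
        write_table(stats, outdir / "crop_stats.csv")


def read_scene(indir) -> SyntheticScene:
    indir = Path(indir)
    manifest = json.loads((indir / "scene.json").read_text())
    config = SceneConfig(**manifest["config"])
    dates = [_dt.date.fromisoformat(d) for d in manifest["start_dates"]]
    stacks = {name: read_stack(indir, name, dates, name) for name in _STACKS}
    statics = {name: read_ascii_grid(indir / f"{name}.asc") for name in _STATICS}
    truth = SceneTruth()
    tpath = indir / "truth.json"
    if tpath.exists():
        sidecar = json.loads(tpath.read_text())
        truth.true_hi = sidecar.get("true_hi", {})
        truth.true_rc = sidecar.get("true_rc", {})
        truth.true_mc = sidecar.get("true_mc", {})
        truth.district_gpp_totals = {
            int(k): v for k, v in sidecar.get("district_gpp_totals_gc", {}).items()}
        truth.district_area_ha = {
            int(k): v for k, v in sidecar.get("district_area_ha", {}).items()}
    gpath = indir / "true_seasonal_gpp.asc"
    if gpath.exists():
        truth.true_seasonal_gpp = read_ascii_grid(gpath)
    # mask may round-trip through float; keep exact 0/1
    return SyntheticScene(
        config=config, grid=statics["cropland_mask"].grid,
        ndvi_stack=stacks["ndvi"], lswi_stack=stacks["lswi"],
        par_stack=stacks["par"], tday_stack=stacks["tday"],
        prop_c3=statics["prop_c3"], prop_c4=statics["prop_c4"],
        cropland_mask=statics["cropland_mask"],
        district_labels=statics["district_labels"], truth=truth,
    )


def read_crop_stats(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"district_id", "year", "season", "crop", "area_ha", "production_t"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"crop statistics file missing columns: {sorted(missing)}")
    if (df["area_ha"] < 0).any() or (df["production_t"] < 0).any():
        raise ValueError("areas and production must be non-negative")
    return df
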