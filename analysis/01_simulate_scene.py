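#!/usr/bin/env python
"""Simulate two consecutive monsoon seasons (drivers, masks, districts,
crop statistics) with shared ground-truth harvest indices.

Writes results/scene_<year>/ for the calibration year and the following
validation year, each with driver stacks, masks, district labels, a crop
statistics CSV and a truth sidecar.
"""

import dataclasses
from pathlib import Path

from agrigpp.io import write_scene
from agrigpp.synthetic import (DEFAULT_COEFFICIENTS, DEFAULT_MONSOON_CROPS,
                               SceneConfig, draw_true_hi, generate_crop_stats,
                               generate_scene)

RESULTS = Path(__file__).resolve().parents[1] / "results"
SEED = 20050601

BASE = SceneConfig(grid_rows=40, grid_cols=40, n_districts=9, n_composites=9,
                   season="monsoon", year=2005, noise_sd_ndvi=0.02,
                   noise_sd_production=0.05, rng_seed=SEED)


def main() -> None:
    true_hi = draw_true_hi(DEFAULT_COEFFICIENTS, DEFAULT_MONSOON_CROPS, SEED)
    for offset in (0, 1):
        cfg = dataclasses.replace(BASE, year=BASE.year + offset,
                                  rng_seed=SEED + offset)
        scene = generate_scene(cfg)
        stats = generate_crop_stats(scene, DEFAULT_MONSOON_CROPS,
                                    DEFAULT_COEFFICIENTS, true_hi=true_hi,
                                    rng_seed=SEED + 100 + offset)
        outdir = RESULTS / f"scene_{cfg.year}"
        write_scene(scene, outdir, stats=stats)
        n_crop = int((scene.cropland_mask.data == 1).sum())
        print(f"{cfg.year}: {cfg.grid_rows}x{cfg.grid_cols} grid, "
              f"{n_crop} cropland pixels, {cfg.n_districts} districts, "
              f"{len(stats)} stat records -> {outdir}")
    print("true harvest indices:",
          {k: round(v, 4) for k, v in true_hi.items()})


if __name__ == "__main__":
    main()
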