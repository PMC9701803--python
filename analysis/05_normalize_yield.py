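#!/usr/bin/env python
"""Redistribute district crop-combined yield to pixels in proportion to
GPP (the NGPPCY product) for the calibration year.

Writes results/NGPPCY-M<year>.asc and checks the conservation property
that each district's unweighted cropland mean equals its yield.
"""

from pathlib import Path

import numpy as np

from agrigpp.io import read_crop_stats, read_scene
from agrigpp.ngppcy import compute_ngppcy, district_yields_from_stats
from agrigpp.raster import read_ascii_grid, write_ascii_grid

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    year = min(int(p.name.split("_")[1]) for p in RESULTS.glob("scene_*"))
    scene = read_scene(RESULTS / f"scene_{year}")
    gpp = read_ascii_grid(RESULTS / f"seasonal_gpp_{year}.asc")
    stats = read_crop_stats(RESULTS / f"scene_{year}" / "crop_stats.csv")
    yields = district_yields_from_stats(stats, scene.config.season, year)
    out = compute_ngppcy(gpp, scene.district_labels, yields)
    tag = "M" if scene.config.season == "monsoon" else "W"
    path = RESULTS / f"NGPPCY-{tag}{year}.asc"
    write_ascii_grid(out, path)

    worst = 0.0
    for y in yields:
        sel = (scene.district_labels.data == y.district_id) & ~np.isnan(gpp.data)
        worst = max(worst, abs(np.mean(out.data[sel]) - y.yield_t_per_ha)
                    / max(y.yield_t_per_ha, 1e-12))
    vals = out.data[~np.isnan(out.data)]
    print(f"NGPPCY {year}: {vals.min():.2f}-{vals.max():.2f} t/Ha "
          f"({vals.size} pixels) -> {path.name}")
    print(f"district-mean conservation, worst relative error: {worst:.2e}")


if __name__ == "__main__":
    main()
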