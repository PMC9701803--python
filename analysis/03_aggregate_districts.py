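#!/usr/bin/env python
"""Aggregate seasonal GPP to district totals and apply the exclusion rules
(cropped area >= 75,000 Ha and considered-crop share >= 30%).

Writes results/district_gpp_<year>.csv with totals, shares and retention.
"""

from pathlib import Path

import pandas as pd

from agrigpp.districts import (aggregate_district, build_filter_table,
                               district_gpp_frame, filter_districts)
from agrigpp.io import read_crop_stats, read_scene, write_table
from agrigpp.raster import read_ascii_grid

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    for scene_dir in sorted(RESULTS.glob("scene_*")):
        year = int(scene_dir.name.split("_")[1])
        scene = read_scene(scene_dir)
        gpp = read_ascii_grid(RESULTS / f"seasonal_gpp_{year}.asc")
        stats = read_crop_stats(scene_dir / "crop_stats.csv")
        agg = aggregate_district(gpp, scene.district_labels,
                                 scene.cropland_mask, scene.config.season, year)
        table = filter_districts(build_filter_table(stats, agg))
        frame = district_gpp_frame(agg).merge(
            table[["district_id", "considered_share", "retained",
                   "exclusion_reason"]], on="district_id")
        out = RESULTS / f"district_gpp_{year}.csv"
        write_table(frame, out)
        kept = int(frame["retained"].sum())
        print(f"{year}: {len(frame)} districts, {kept} retained, "
              f"totals {frame['sat_gpp_total_gc'].min():.3g}"
              f"-{frame['sat_gpp_total_gc'].max():.3g} gC -> {out.name}")


if __name__ == "__main__":
    main()
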