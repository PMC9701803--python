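"""Pixel-level normalized crop yield (NGPPCY).

District-level crop-combined yield statistics are redistributed to pixels
in proportion to each pixel's seasonal GPP relative to the district mean:

    ngppcy(p) = gpp(p) / mean_{q in district cropland} gpp(q) * yield_d

so the unweighted mean of NGPPCY over a district's cropland equals the
district yield exactly (the defining conservation property), and the field
is invariant to rescaling a district's GPP by any positive constant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .raster import Raster, _require_same_grid


@dataclass
class DistrictYield:
    district_id: int
    season: str
    year: int
    yield_t_per_ha: float

    def __post_init__(self) -> None:
        if self.yield_t_per_ha < 0:
            raise ValueError("yield must be non-negative")


def district_yields_from_stats(stats: pd.DataFrame, season: str = "",
                               year: int = 0) -> list[DistrictYield]:
    """Crop-combined yield per district: sum(production)/sum(area) (t/Ha)."""
    out = []
    for did, recs in stats.groupby("district_id"):
        area = recs["area_ha"].sum()
        y = recs["production_t"].sum() / area if area > 0 else 0.0
        out.append(DistrictYield(int(did), season, year, float(y)))
    return out


def compute_ngppcy(seasonal_gpp: Raster, district_labels: Raster,
                   yields: list[DistrictYield], mean: str = "unweighted",
                   multi_year_mean: Raster | None = None) -> Raster:
    """Normalized yield raster (t/Ha) from seasonal GPP and district yields.

    ``mean`` selects the district normaliser: "unweighted" (default) or
    "area_weighted" (cos-latitude pixel areas). When ``multi_year_mean``
    is given, the pixel fraction is taken against that raster's district
    mean instead of the single-year field (the multi-year variant).

    Cropland membership is taken from non-nodata pixels of ``seasonal_gpp``;
    a labeled cropland district with no yield entry is an error, a district
    whose mean GPP is zero comes back nodata with a warning.
    """
    _require_same_grid(seasonal_gpp, district_labels)
    ref = multi_year_mean.data if multi_year_mean is not None else seasonal_gpp.data
    if multi_year_mean is not None:
        _require_same_grid(seasonal_gpp, multi_year_mean)
    yield_by_id = {y.district_id: y.yield_t_per_ha for y in yields}
    labels = district_labels.data
    gpp = seasonal_gpp.data
    out = np.full(gpp.shape, np.nan)
    if mean == "area_weighted":
        w = seasonal_gpp.grid.pixel_area_m2()
    elif mean == "unweighted":
        w = np.ones(gpp.shape)
    else:
        raise ValueError(f"unknown mean mode {mean!r}")
    for did in np.unique(labels[~np.isnan(labels)]).astype(int):
        sel = (labels == did) & ~np.isnan(gpp) & ~np.isnan(ref)
        if not sel.any():
            continue
        if did not in yield_by_id:
            raise KeyError(f"no yield for labeled district {did}")
        denom = np.average(ref[sel], weights=w[sel])
        if denom == 0:
            warnings.warn(f"district {did} has zero mean GPP; NGPPCY set to nodata")
            continue
        out[sel] = gpp[sel] / denom * yield_by_id[did]
    return Raster(out, seasonal_gpp.grid)
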