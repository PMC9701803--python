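"""District-level aggregation of seasonal GPP and the exclusion filters.

Districts are encoded as an integer label raster; totals are compared
with crop-production statistics, so they are expressed in grams of
carbon over the district's cropland.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .raster import Raster, _require_same_grid

M2_PER_HA = 1e4

#: districts smaller than this gross cropped area are excluded
MIN_AREA_HA = 75_000.0
#: districts where modelled ("considered") crops cover less than this share
#: of the total cropped area are excluded
MIN_CONSIDERED_SHARE = 0.30


@dataclass
class DistrictGPP:
    district_id: int
    season: str
    year: int
    sat_gpp_total: float  # gC over cropland
    cropland_area_ha: float
    n_pixels: int


def aggregate_district(seasonal_gpp: Raster, district_labels: Raster,
                       mask: Raster, season: str = "", year: int = 0
                       ) -> list[DistrictGPP]:
    """Sum masked seasonal GPP to district totals (gC).

    total_d = sum over cropland pixels of gpp(p) [gC m-2] * pixel_area(p) [m2],
    pixel area from the spherical cos-latitude formula. One record is
    returned for every district id present in the label raster, including
    districts whose cropland is entirely masked out (total 0, n_pixels 0).
    """
    _require_same_grid(seasonal_gpp, district_labels, mask)
    labels = district_labels.data
    ids = np.unique(labels[~np.isnan(labels)]).astype(int)
    if ids.size == 0:
        raise ValueError("district label raster contains no labels")
    area = seasonal_gpp.grid.pixel_area_m2()
    gpp = seasonal_gpp.data
    ok = (mask.data == 1) & ~np.isnan(gpp)
    out = []
    for did in ids:
        sel = ok & (labels == did)
        total = float(np.sum(gpp[sel] * area[sel])) if sel.any() else 0.0
        a_ha = float(np.sum(area[sel])) / M2_PER_HA
        out.append(DistrictGPP(int(did), season, year, total, a_ha, int(sel.sum())))
    return out


def district_gpp_frame(records: list[DistrictGPP]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "district_id": r.district_id,
                "season": r.season,
                "year": r.year,
                "sat_gpp_total_gc": r.sat_gpp_total,
                "cropland_area_ha": r.cropland_area_ha,
                "n_pixels": r.n_pixels,
            }
            for r in records
        ]
    )


def filter_districts(district_table: pd.DataFrame,
                     min_area_ha: float = MIN_AREA_HA,
                     min_considered_share: float = MIN_CONSIDERED_SHARE
                     ) -> pd.DataFrame:
    """Apply the two district exclusion rules.

    ``district_table`` needs columns ``district_id``,
    ``total_cropped_area_ha`` and ``considered_area_ha``. A district is
    retained iff its total cropped area is at least ``min_area_ha`` AND the
    considered crops' share of that area is at least
    ``min_considered_share``. Returns the table with ``considered_share``,
    ``retained`` and ``exclusion_reason`` columns added; the filter is
    idempotent and order-independent.
    """
    t = district_table.copy()
    if (t["total_cropped_area_ha"] < 0).any() or (t["considered_area_ha"] < 0).any():
        raise ValueError("areas must be non-negative")
    with np.errstate(invalid="ignore", divide="ignore"):
        share = np.where(t["total_cropped_area_ha"] > 0,
                         t["considered_area_ha"] / t["total_cropped_area_ha"], 0.0)
    t["considered_share"] = share
    small = t["total_cropped_area_ha"] < min_area_ha
    minor = t["considered_share"] < min_considered_share
    t["retained"] = ~(small | minor)
    reason = np.full(len(t), "", dtype=object)
    reason[minor.to_numpy()] = "considered-crop share below threshold"
    reason[small.to_numpy()] = "cropped area below threshold"
    reason[(small & minor).to_numpy()] = "cropped area and considered share below threshold"
    t["exclusion_reason"] = reason
    return t


def build_filter_table(stats: pd.DataFrame, district_gpp: list[DistrictGPP],
                       total_area_ha: dict[int, float] | None = None
                       ) -> pd.DataFrame:
    """Assemble the per-district filter table from crop statistics.

    Considered area is the summed area of the modelled crops in ``stats``;
    the total cropped area defaults to the district's cropland-mask area
    when no independent total is supplied.
    """
    cons = stats.groupby("district_id")["area_ha"].sum()
    rows = []
    for r in district_gpp:
        total = (total_area_ha or {}).get(r.district_id, r.cropland_area_ha)
        rows.append({
            "district_id": r.district_id,
            "total_cropped_area_ha": total,
            "considered_area_ha": float(cons.get(r.district_id, 0.0)),
        })
    return pd.DataFrame(rows)
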