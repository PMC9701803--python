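"""Vegetation Photosynthesis Model (VPM) core.

Pixel-level light-use-efficiency GPP:

    GPP = eps* x T_scalar x W_scalar x P_scalar x fPAR x PAR

with eps* the C3/C4-fraction-weighted maximum light-use efficiency,
fPAR = a x NDVI - b (clamped to [0,1]), a parabolic temperature scalar,
a water scalar driven by LSWI relative to its seasonal maximum, and the
phenology scalar fixed at 1 for the crop seasons modelled here.

All functions are numpy-vectorised and accept scalars or arrays; NaN is
the nodata value and propagates.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .raster import CompositeStack, GridSpec, Raster

#: W m-2 sustained for one day, in MJ m-2
MJ_PER_W_DAY = 0.0864

SEASON_SPANS = {
    # season -> (start month/day, end month/day, end-year offset)
    "monsoon": ((6, 1), (10, 31), 0),
    "winter": ((11, 1), (3, 31), 1),
}


@dataclass(frozen=True)
class FparParams:
    """Linear NDVI-to-fPAR relation fPAR = a*NDVI - b."""

    a: float = 1.24
    b: float = 0.168

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise ValueError("fPAR slope a must be positive")


@dataclass(frozen=True)
class PathwayParams:
    """Temperature response and maximum LUE for one photosynthetic pathway."""

    t_min: float
    t_max: float
    t_opt: float
    lue_max: float

    def __post_init__(self) -> None:
        if not (self.t_min < self.t_opt < self.t_max):
            raise ValueError("need t_min < t_opt < t_max")
        if self.lue_max <= 0:
            raise ValueError("lue_max must be positive")


C3_DEFAULT = PathwayParams(t_min=5.0, t_max=40.0, t_opt=25.0, lue_max=1.388)
C4_DEFAULT = PathwayParams(t_min=8.0, t_max=42.0, t_opt=30.0, lue_max=1.542)


def compute_fpar(ndvi, params: FparParams = FparParams()):
    """Fraction of PAR absorbed by chlorophyll, clamp(a*NDVI - b, 0, 1)."""
    ndvi = np.asarray(ndvi, dtype=float)
    valid = ~np.isnan(ndvi)
    if np.any((ndvi[valid] < -1) | (ndvi[valid] > 1)):
        raise ValueError("NDVI outside [-1, 1]")
    out = np.clip(params.a * ndvi - params.b, 0.0, 1.0)
    return out if out.ndim else float(out)


def compute_lswi(nir, swir):
    """Land surface water index (NIR - SWIR)/(NIR + SWIR); NaN where both 0."""
    nir = np.asarray(nir, dtype=float)
    swir = np.asarray(swir, dtype=float)
    if np.any(nir[~np.isnan(nir)] < 0) or np.any(swir[~np.isnan(swir)] < 0):
        raise ValueError("reflectances must be non-negative")
    denom = nir + swir
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(denom == 0, np.nan, (nir - swir) / denom)
    return out if out.ndim else float(out)


def compute_wscalar(lswi, lswi_max):
    """Water scalar (1 + LSWI)/(1 + LSWI_max), clamped to [0, 1].

    A pixel whose seasonal LSWI maximum is -1 is degenerate and returns NaN.
    """
    lswi = np.asarray(lswi, dtype=float)
    lswi_max = np.asarray(lswi_max, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.clip((1.0 + lswi) / (1.0 + lswi_max), 0.0, 1.0)
        out = np.where(lswi_max == -1.0, np.nan, out)
    return out if out.ndim else float(out)


def compute_tscalar(t, params: PathwayParams):
    """Parabolic temperature scalar; 0 outside (t_min, t_max), 1 at t_opt."""
    t = np.asarray(t, dtype=float)
    num = (t - params.t_max) * (t - params.t_min)
    den = num - (t - params.t_opt) ** 2
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(den == 0, 0.0, num / den)
    out = np.where((t <= params.t_min) | (t >= params.t_max), 0.0, out)
    out = np.where(np.isnan(t), np.nan, np.clip(out, 0.0, 1.0))
    return out if out.ndim else float(out)


def compute_lue_max(prop_c3, prop_c4, lue_c3: float = C3_DEFAULT.lue_max,
                    lue_c4: float = C4_DEFAULT.lue_max):
    """Mixed-pixel maximum LUE, the C3/C4-fraction convex combination."""
    prop_c3 = np.asarray(prop_c3, dtype=float)
    prop_c4 = np.asarray(prop_c4, dtype=float)
    s = prop_c3 + prop_c4
    bad = ~np.isnan(s) & (np.abs(s - 1.0) > 1e-6)
    if np.any(bad) or np.any(prop_c3[~np.isnan(prop_c3)] < 0) or np.any(
            prop_c4[~np.isnan(prop_c4)] < 0):
        raise ValueError("C3/C4 fractions must be non-negative and sum to 1")
    out = lue_c3 * prop_c3 + lue_c4 * prop_c4
    return out if out.ndim else float(out)


def compute_gpp_composite(ndvi, lswi, lswi_max, par_16d, tday, prop_c3, prop_c4,
                          fpar_params: FparParams = FparParams(),
                          c3: PathwayParams = C3_DEFAULT,
                          c4: PathwayParams = C4_DEFAULT):
    """GPP (gC m-2) for one 16-day composite.

    T_scalar is evaluated under each pathway's parameters and mixed with the
    same C3/C4 weights as the maximum LUE; P_scalar is 1. NaN in any driver
    propagates to the output.
    """
    eps_star = compute_lue_max(prop_c3, prop_c4, c3.lue_max, c4.lue_max)
    tsc = np.asarray(prop_c3) * compute_tscalar(tday, c3) \
        + np.asarray(prop_c4) * compute_tscalar(tday, c4)
    wsc = compute_wscalar(lswi, lswi_max)
    fpar = compute_fpar(ndvi, fpar_params)
    gpp = eps_star * tsc * wsc * fpar * np.asarray(par_16d, dtype=float)
    return gpp if np.ndim(gpp) else float(gpp)


def compute_lswi_max(lswi_stack: CompositeStack) -> Raster:
    """Per-pixel seasonal maximum of LSWI, ignoring nodata layers."""
    if len(lswi_stack) == 0:
        raise ValueError("empty LSWI stack")
    with np.errstate(all="ignore"):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            mx = np.nanmax(lswi_stack.layers, axis=0)
    return Raster(mx, lswi_stack.grid)


def integrate_season(gpp_stack: CompositeStack, mask: Raster) -> Raster:
    """Per-pixel sum over composites; mask==0 pixels become nodata."""
    if len(gpp_stack) == 0:
        raise ValueError("empty GPP stack")
    if mask.grid != gpp_stack.grid:
        raise ValueError("mask is not co-registered with the GPP stack")
    total = np.sum(gpp_stack.layers, axis=0)
    total = np.where(mask.data == 0, np.nan, total)
    total = np.where(np.isnan(mask.data), np.nan, total)
    return Raster(total, gpp_stack.grid)


def composite_climate(daily_par, daily_tmax, daily_tmin, window_start_dates,
                      tday_weights: tuple[float, float] = (0.75, 0.25)):
    """Aggregate daily climate series to 16-day composites.

    Parameters
    ----------
    daily_par, daily_tmax, daily_tmin : mapping date -> value
        Daily mean PAR (W m-2) and 2-m air temperature extremes (degC);
        pandas Series indexed by date work directly.
    window_start_dates : iterable of datetime.date
    tday_weights : (w_max, w_min)
        Daytime-mean estimator tday = w_max*Tmax + w_min*Tmin; the default
        0.75/0.25 weights Tmax heavily, (0.5, 0.5) gives the plain mean.

    Returns
    -------
    (par_16d, tday) : two float arrays, one value per window; PAR is the
    window total in MJ m-2 (0.0864 MJ per W m-2 sustained for a day), tday
    the window mean of the daily estimator. Any missing or NaN day flags
    the whole window as NaN.
    """
    wmax, wmin = tday_weights

    def get(series, day):
        try:
            v = series[day]
        except (KeyError, IndexError):
            return np.nan
        return float(v) if v is not None else np.nan

    par_out, tday_out = [], []
    for start in window_start_dates:
        days = [start + _dt.timedelta(days=i) for i in range(16)]
        par_vals = np.array([get(daily_par, d) for d in days])
        tmax_vals = np.array([get(daily_tmax, d) for d in days])
        tmin_vals = np.array([get(daily_tmin, d) for d in days])
        if np.isnan(par_vals).any() or np.isnan(tmax_vals).any() or np.isnan(tmin_vals).any():
            par_out.append(np.nan)
            tday_out.append(np.nan)
            continue
        par_out.append(float(np.sum(par_vals) * MJ_PER_W_DAY))
        tday_out.append(float(np.mean(wmax * tmax_vals + wmin * tmin_vals)))
    return np.array(par_out), np.array(tday_out)


def resample_to_grid(coarse: Raster, target_grid: GridSpec, method: str = "bilinear") -> Raster:
    """Resample a coarse raster onto ``target_grid`` (bilinear or nearest).

    Sampling is at target cell centers in the coarse raster's fractional
    pixel space; every target center must fall inside the coarse extent.
    NaN cells in the source propagate to any target cell they touch.
    """
    cg = coarse.grid
    lon = target_grid.lon_centers()
    lat = target_grid.lat_centers()
    if (lon.min() < cg.origin_lon or lon.max() > cg.origin_lon + cg.cols * cg.cell_size
            or lat.max() > cg.origin_lat or lat.min() < cg.origin_lat - cg.rows * cg.cell_size):
        raise ValueError("target grid extends beyond the coarse raster extent")
    # fractional row/col of each target center in the coarse grid
    col = (lon - cg.origin_lon) / cg.cell_size - 0.5
    row = (cg.origin_lat - lat) / cg.cell_size - 0.5
    rr, cc = np.meshgrid(row, col, indexing="ij")
    order = {"bilinear": 1, "nearest": 0}.get(method)
    if order is None:
        raise ValueError(f"unknown resampling method {method!r}")
    out = ndimage.map_coordinates(coarse.data, [rr, cc], order=order,
                                  mode="nearest", cval=np.nan)
    return Raster(out, target_grid)


def season_start_dates(season: str, year: int, n_composites: int) -> list[_dt.date]:
    """16-day composite start dates for a season labelled by its start year."""
    if season not in SEASON_SPANS:
        raise ValueError(f"unknown season {season!r}")
    (m, d), _, _ = SEASON_SPANS[season]
    start = _dt.date(year, m, d)
    return [start + _dt.timedelta(days=16 * i) for i in range(n_composites)]


def in_season(start_date: _dt.date, season: str, year: int) -> bool:
    """A 16-day window belongs to a season iff its start date lies in the span."""
    (sm, sd), (em, ed), off = SEASON_SPANS[season]
    lo = _dt.date(year, sm, sd)
    hi = _dt.date(year + off, em, ed)
    return lo <= start_date <= hi
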