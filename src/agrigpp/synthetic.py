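"""Synthetic scene and crop-statistics generator with known ground truth.

Emulates the driver set of the seasonal crop-GPP pipeline: smooth unimodal
NDVI/LSWI phenology on cropland at 16-day steps, spatially varying PAR and
daytime temperature generated on a coarser climate grid and resampled to
the model grid, per-district C3/C4 crop fractions, a cropland mask, a
rectangular district partition, and district crop-production tables built
by inverting the statistics-to-GPP relation from known "true" harvest
indices. Everything is deterministic given the configured seed.

What it deliberately does not emulate: orbital/QA artifacts, cloud gaps,
real phenology calendars or real district geometry.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import vpm
from .calibration import (CropCoefficients, GRAMS_PER_TONNE, LITTER_FACTOR)
from .districts import aggregate_district
from .raster import CompositeStack, GridSpec, Raster


#: default coefficient table; HI bounds and the RC/MC constants are typical
#: agronomic values (sugarcane's harvest index is conventionally fixed)
DEFAULT_COEFFICIENTS: dict[str, CropCoefficients] = {
    c.crop: c for c in [
        CropCoefficients("rice", 0.15, 0.50, rc=0.25, mc=0.14),
        CropCoefficients("maize", 0.20, 0.55, rc=0.30, mc=0.155),
        CropCoefficients("soybean", 0.20, 0.50, rc=0.35, mc=0.10),
        CropCoefficients("cotton", 0.10, 0.40, rc=0.30, mc=0.08),
        CropCoefficients("wheat", 0.20, 0.55, rc=0.30, mc=0.12),
        CropCoefficients("chickpea", 0.15, 0.45, rc=0.35, mc=0.10),
        CropCoefficients("mustard", 0.15, 0.40, rc=0.30, mc=0.08),
        CropCoefficients("sugarcane", 0.60, 0.80, rc=0.25, mc=0.70,
                         fixed_hi=0.69),
    ]
}

DEFAULT_MONSOON_CROPS = ["rice", "maize", "soybean"]
DEFAULT_WINTER_CROPS = ["wheat", "chickpea", "mustard"]


@dataclass(frozen=True)
class SceneConfig:
    """Size, season and noise settings for one synthetic scene."""

    grid_rows: int = 40
    grid_cols: int = 40
    cell_size_deg: float = 0.05
    origin_lon: float = 75.0
    origin_lat: float = 25.0
    n_districts: int = 9
    season: str = "monsoon"
    year: int = 2005
    n_composites: int = 9
    climate_downscale_factor: int = 5
    noise_sd_ndvi: float = 0.02
    noise_sd_production: float = 0.05
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.grid_rows < 2 or self.grid_cols < 2:
            raise ValueError("grid must be at least 2x2")
        if self.n_districts < 1 or self.n_districts > self.grid_rows * self.grid_cols:
            raise ValueError("n_districts must be in [1, grid_rows*grid_cols]")
        if self.noise_sd_ndvi < 0 or self.noise_sd_production < 0:
            raise ValueError("noise SDs must be non-negative")
        if self.climate_downscale_factor < 1:
            raise ValueError("climate_downscale_factor must be >= 1")
        if self.season not in vpm.SEASON_SPANS:
            raise ValueError(f"unknown season {self.season!r}")
        if self.n_composites < 1:
            raise ValueError("need at least one composite")


@dataclass
class SceneTruth:
    """Ground truth carried alongside a scene for parameter-recovery tests."""

    true_hi: dict[str, float] = field(default_factory=dict)
    true_rc: dict[str, float] = field(default_factory=dict)
    true_mc: dict[str, float] = field(default_factory=dict)
    true_seasonal_gpp: Raster | None = None
    district_gpp_totals: dict[int, float] = field(default_factory=dict)
    district_area_ha: dict[int, float] = field(default_factory=dict)


@dataclass
class SyntheticScene:
    config: SceneConfig
    grid: GridSpec
    ndvi_stack: CompositeStack
    lswi_stack: CompositeStack
    par_stack: CompositeStack      # MJ m-2 per 16-day composite
    tday_stack: CompositeStack     # degC
    prop_c3: Raster
    prop_c4: Raster
    cropland_mask: Raster
    district_labels: Raster
    truth: SceneTruth


def _district_blocks(rows: int, cols: int, n: int) -> np.ndarray:
    """Rectangular block partition of the grid into n labelled districts."""
    nr = max(1, int(np.floor(np.sqrt(n))))
    nc = int(np.ceil(n / nr))
    row_band = np.minimum((np.arange(rows) * nr) // rows, nr - 1)
    col_band = np.minimum((np.arange(cols) * nc) // cols, nc - 1)
    block = row_band[:, None] * nc + col_band[None, :]
    return np.minimum(block, n - 1) + 1  # ids 1..n


def _beta_pulse(x: np.ndarray, peak: np.ndarray) -> np.ndarray:
    """Unimodal pulse on [0,1] with maximum 1 at ``peak`` (beta-like shape)."""
    p = 1.0 + 4.0 * peak
    q = 1.0 + 4.0 * (1.0 - peak)
    with np.errstate(divide="ignore", invalid="ignore"):
        log_mode = (p - 1) * np.log(peak) + (q - 1) * np.log1p(-peak)
        log_val = (p - 1) * np.log(np.clip(x, 1e-12, 1)) \
            + (q - 1) * np.log(np.clip(1 - x, 1e-12, 1))
    return np.exp(log_val - log_mode)


def generate_scene(config: SceneConfig) -> SyntheticScene:
    """Build a self-consistent synthetic scene.

    The true seasonal GPP is obtained by running the VPM core forward on
    the noise-free drivers; the emitted NDVI/LSWI stacks add Gaussian noise
    of SD ``noise_sd_ndvi`` (clipped to [-1, 1]), so at zero noise the
    emitted stacks reproduce the truth exactly.
    """
    rng = np.random.default_rng(config.rng_seed)
    rows, cols = config.grid_rows, config.grid_cols
    grid = GridSpec(rows, cols, config.cell_size_deg,
                    config.origin_lon, config.origin_lat)
    dates = vpm.season_start_dates(config.season, config.year,
                                   config.n_composites)

    labels = _district_blocks(rows, cols, config.n_districts).astype(float)

    # cropland mask: mostly cropland with scattered non-crop pixels; every
    # district keeps at least one cropland pixel
    mask = (rng.random((rows, cols)) < 0.9).astype(float)
    for did in range(1, config.n_districts + 1):
        sel = labels == did
        if not (mask[sel] == 1).any():
            idx = np.argwhere(sel)[0]
            mask[idx[0], idx[1]] = 1.0

    # per-district phenology jitter: peak timing and amplitude
    peak_d = rng.uniform(0.40, 0.60, config.n_districts)
    amp_d = rng.uniform(0.50, 0.70, config.n_districts)
    amp_px = amp_d[(labels - 1).astype(int)] * rng.uniform(0.9, 1.1, (rows, cols))
    peak_px = peak_d[(labels - 1).astype(int)]

    tnorm = (np.arange(config.n_composites) + 0.5) / config.n_composites
    ndvi_clean = np.empty((config.n_composites, rows, cols))
    base = 0.15
    for k, x in enumerate(tnorm):
        pulse = _beta_pulse(np.full((rows, cols), x), peak_px)
        layer = base + amp_px * pulse
        ndvi_clean[k] = np.where(mask == 1, layer, 0.12)
    ndvi_clean = np.clip(ndvi_clean, -1.0, 1.0)

    # LSWI tracks NDVI with an offset plus a small deterministic ripple
    ripple = 0.03 * np.sin(2 * np.pi * tnorm)[:, None, None]
    lswi_clean = np.clip(0.7 * ndvi_clean - 0.12 + ripple, -1.0, 1.0)

    # climate on the coarse grid, then resampled to the model grid
    f = config.climate_downscale_factor
    crows = int(np.ceil(rows / f)) + 1
    ccols = int(np.ceil(cols / f)) + 1
    coarse_grid = GridSpec(crows, ccols, config.cell_size_deg * f,
                           config.origin_lon - config.cell_size_deg * f / 2,
                           config.origin_lat + config.cell_size_deg * f / 2)
    par_field = rng.uniform(-10.0, 10.0, (crows, ccols))
    t_field = rng.uniform(-2.0, 2.0, (crows, ccols))
    season_par = 140.0 + 25.0 * np.sin(np.pi * tnorm)      # MJ m-2 / 16 d
    season_t = 24.0 + 5.0 * np.sin(np.pi * tnorm)          # degC

    par_layers = np.empty((config.n_composites, rows, cols))
    tday_layers = np.empty((config.n_composites, rows, cols))
    for k in range(config.n_composites):
        par_coarse = Raster(season_par[k] + par_field, coarse_grid)
        t_coarse = Raster(season_t[k] + t_field, coarse_grid)
        par_layers[k] = vpm.resample_to_grid(par_coarse, grid).data
        tday_layers[k] = vpm.resample_to_grid(t_coarse, grid).data

    # per-district C4 fraction; fractions defined on the whole grid
    c4_d = rng.uniform(0.1, 0.5, config.n_districts)
    prop_c4 = c4_d[(labels - 1).astype(int)]
    prop_c3 = 1.0 - prop_c4

    # forward model on the noise-free drivers
    lswi_max = np.max(lswi_clean, axis=0)
    gpp_layers = np.empty_like(ndvi_clean)
    for k in range(config.n_composites):
        gpp_layers[k] = vpm.compute_gpp_composite(
            ndvi_clean[k], lswi_clean[k], lswi_max, par_layers[k],
            tday_layers[k], prop_c3, prop_c4)
    gpp_stack = CompositeStack(gpp_layers, dates, grid, "gpp", "gC m-2")
    mask_raster = Raster(mask, grid)
    labels_raster = Raster(labels, grid)
    true_gpp = vpm.integrate_season(gpp_stack, mask_raster)

    agg = aggregate_district(true_gpp, labels_raster, mask_raster,
                             config.season, config.year)
    truth = SceneTruth(
        true_seasonal_gpp=true_gpp,
        district_gpp_totals={r.district_id: r.sat_gpp_total for r in agg},
        district_area_ha={r.district_id: r.cropland_area_ha for r in agg},
    )

    sd = config.noise_sd_ndvi
    ndvi_out = np.clip(ndvi_clean + rng.normal(0, sd, ndvi_clean.shape)
                       if sd > 0 else ndvi_clean, -1.0, 1.0)
    lswi_out = np.clip(lswi_clean + rng.normal(0, sd, lswi_clean.shape)
                       if sd > 0 else lswi_clean, -1.0, 1.0)

    def stack(arr, name, units):
        return CompositeStack(arr, list(dates), grid, name, units)

    return SyntheticScene(
        config=config, grid=grid,
        ndvi_stack=stack(ndvi_out, "ndvi", ""),
        lswi_stack=stack(lswi_out, "lswi", ""),
        par_stack=stack(par_layers, "par", "MJ m-2 per composite"),
        tday_stack=stack(tday_layers, "tday", "degC"),
        prop_c3=Raster(prop_c3, grid), prop_c4=Raster(prop_c4.copy(), grid),
        cropland_mask=mask_raster, district_labels=labels_raster,
        truth=truth,
    )


def draw_true_hi(coefficients: dict[str, CropCoefficients], crops: list[str],
                 seed: int) -> dict[str, float]:
    """Draw ground-truth harvest indices strictly inside their bounds.

    All free crops share one relative position u in their bound intervals
    (hi_i = lo_i + u*(up_i - lo_i)): the district-level matching equation is
    scalar, so only this one degree of freedom is identifiable, and truth is
    placed on the identifiable manifold. Fixed-HI crops keep their pin.
    """
    rng = np.random.default_rng(seed)
    u = rng.uniform(0.15, 0.85)
    out = {}
    for crop in crops:
        c = coefficients[crop]
        out[crop] = c.fixed_hi if c.fixed_hi is not None \
            else c.hi_lower + u * (c.hi_upper - c.hi_lower)
    return out


def generate_crop_stats(scene: SyntheticScene, crops: list[str],
                        coefficients: dict[str, CropCoefficients],
                        production_noise_sd: float | None = None,
                        true_hi: dict[str, float] | None = None,
                        rng_seed: int | None = None,
                        carbon_fraction: float = 1.0) -> pd.DataFrame:
    """District crop-production tables consistent with the scene's GPP.

    Each district's satellite GPP total is split across crops by seeded
    Dirichlet shares and the statistics-to-GPP relation is inverted:

        production_i [t] = share_i * SatGPP_d * HI_i
                           / (1.15 * (1+RC_i) * (1-MC_i)) / 1e6

    so at zero noise the statistics convert back to the satellite totals
    exactly. Multiplicative lognormal noise (mean-one, SD as a fraction)
    keeps noisy production positive. Updates ``scene.truth`` with the true
    coefficient maps and returns records (district_id, year, season, crop,
    area_ha, production_t).
    """
    if production_noise_sd is None:
        production_noise_sd = scene.config.noise_sd_production
    if production_noise_sd < 0:
        raise ValueError("production noise SD must be non-negative")
    for crop in crops:
        if crop not in coefficients:
            raise KeyError(f"no coefficients for crop {crop!r}")
        c = coefficients[crop]
        if c.mc >= 1:
            raise ValueError(f"{crop}: moisture content must be < 1")
    seed = scene.config.rng_seed + 7919 if rng_seed is None else rng_seed
    rng = np.random.default_rng(seed)
    if true_hi is None:
        true_hi = draw_true_hi(coefficients, crops,
                               int(rng.integers(0, 2**31 - 1)))
    for crop, h in true_hi.items():
        if h <= 0:
            raise ValueError(f"{crop}: true harvest index must be positive")

    scene.truth.true_hi = dict(true_hi)
    scene.truth.true_rc = {c: coefficients[c].rc for c in crops}
    scene.truth.true_mc = {c: coefficients[c].mc for c in crops}

    cfg = scene.config
    rows = []
    for did, total in sorted(scene.truth.district_gpp_totals.items()):
        shares = rng.dirichlet(np.full(len(crops), 4.0))
        area_total = scene.truth.district_area_ha[did]
        for crop, share in zip(crops, shares):
            c = coefficients[crop]
            prod_t = (share * total * true_hi[crop]
                      / (LITTER_FACTOR * (1 + c.rc) * (1 - c.mc))
                      / GRAMS_PER_TONNE / carbon_fraction)
            if production_noise_sd > 0:
                sigma = np.sqrt(np.log1p(production_noise_sd ** 2))
                prod_t *= rng.lognormal(-sigma ** 2 / 2, sigma)
            rows.append({"district_id": did, "year": cfg.year,
                         "season": cfg.season, "crop": crop,
                         "area_ha": share * area_total,
                         "production_t": prod_t})
    return pd.DataFrame(rows)
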