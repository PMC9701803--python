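# Methods

## Model

The pixel model is the VPM light-use-efficiency formulation: GPP for a
16-day composite is `ε*·T_scalar·W_scalar·P_scalar·fPAR·PAR`, summed over
the season and masked to cropland. Assumptions inherited from that
formulation: photosynthesis is proportional to absorbed PAR below
saturation; chlorophyll fPAR is adequately approximated by a linear NDVI
transform; water limitation is captured by LSWI relative to its seasonal
maximum; and phenology needs no extra down-regulation (`P_scalar = 1`)
because the dominant crops hold full leaf through the modelled seasons.

Numerical details that the bare equations leave open, resolved as follows:

- **fPAR clamping.** `a·NDVI − b` is negative for NDVI < b/a ≈ 0.135 and
  exceeds 1 for NDVI > 0.94; fPAR is clamped to [0, 1] so GPP cannot go
  negative over sparse cover.
- **T_scalar outside the cardinal range.** The parabolic form returns
  negative or >1 values outside (T_min, T_max); it is forced to 0 there
  and clipped to [0, 1] inside, consistent with published VPM practice.
  Within the range the ratio is |num|/(|num|+d) ≤ 1, so the clip is a
  numerical guard only.
- **Mixed-pixel temperature response.** For pixels with both C3 and C4
  area, T_scalar is evaluated under each pathway's cardinal temperatures
  and mixed with the same `prop_C3/prop_C4` weights used for ε*. The
  alternative (one scalar at blended cardinal temperatures) is not
  equivalent; the weighted mixture keeps pure-C3 and pure-C4 pixels exact.
- **LSWI_max** is the per-pixel maximum of LSWI over the season's
  composites, ignoring nodata layers; a pixel whose maximum is −1 is
  degenerate and returns nodata.
- **Daytime mean temperature.** Composites carry a single daytime
  temperature, estimated per day as `0.75·T_max + 0.25·T_min` (daytime
  temperature sits closer to the daily maximum); `(T_max+T_min)/2` is
  available via `tday_weights=(0.5, 0.5)`. PAR aggregates daily mean
  W m⁻² to a window total with the exact factor 0.0864 MJ per W-day. A
  window with any missing day is flagged nodata rather than partially
  filled.
- **Scalars per composite.** T_scalar and W_scalar are computed once per
  16-day composite from the composite drivers (not daily-then-averaged);
  the two differ only through the nonlinearity of the temperature
  response, which is mild over a 16-day spread.
- **Season calendar.** A 16-day window belongs to a season iff its start
  date lies in the span: monsoon Jun 1–Oct 31; winter Nov 1–Mar 31,
  labelled by its starting year.
- **Geometry.** Grids are north-up geographic (WGS84 lon/lat), pixel
  areas use the spherical cos-latitude formula with R = 6 371 007.181 m.
  Nodata is NaN in memory, −9999 in the plain-text ASCII-grid files.
  Resampling of coarse climate fields is bilinear at target cell centers
  (nearest-neighbour available), rejecting targets outside the source
  extent.

## Statistics conversion and calibration

Production statistics convert to GPP as
`1.15 · Σ_i PROD_i[g]/HI_i · (1+RC_i) · (1−MC_i)`, with tonnes→grams at
1e6. The 1.15 multiplier covers litterfall and energy-efficiency losses.
An optional `carbon_fraction` multiplier (default 1.0) is exposed because
closing the unit circle between grams of dry matter and grams of carbon
plausibly requires a biomass→carbon factor (≈0.45) that the conversion
as written folds into its constants; with the default the generator and
the calibrator invert each other exactly, which is what the tests need.

The calibration objective is `Z = |Sat.GPP_D − stat.GPP(HI)|` per
district, season and year, with per-crop HI bounds and fixed-HI crops
(sugarcane at 0.69) held constant. One district provides one scalar
equation, so a multi-crop HI vector is not identifiable from it. The
default solver therefore parameterises all free HIs by a single shared
relative position `s ∈ [0,1]` in their bound intervals and finds the root
by bisection — stat.GPP is strictly decreasing in every HI, hence in `s`.
Bisection runs to 1e-10 on `s` and is followed by a short secant polish
inside the final bracket, which closes the residual to machine precision
on noiseless data; when no interior root exists the solution clips to the
bound (`at_bound` flagged, residual > 0; ties at exact bounds resolve to
the bound). Every run asserts the solution is no worse than the
bound-midpoint start. A multivariate L-BFGS-B backend starting from the
bound midpoints is available (`backend="multivariate"`); the two agree on
single-crop districts to well under 1e-6.

Consequence of the shared-`s` design: true harvest indices are
recoverable exactly only when they lie on the one identifiable degree of
freedom. The synthetic generator therefore draws one relative position
`u` and places every free crop's true HI at `lo_i + u·(up_i − lo_i)`,
strictly inside the bounds. This is a property of the problem (one
equation, several unknowns), not of the solver; the multivariate backend
has the same null space and simply returns a different point on it.

Validation applies a calibration year's HIs to the following year's
statistics with no optimisation; districts lacking prior coefficients are
skipped and logged. Metrics are `R²` (squared Pearson correlation of
district (satellite, statistics) GPP pairs; undefined at zero variance)
and `nRMSE = 100·RMSE/mean(stat.GPP)` — the statistics-derived mean is
the normaliser.

District exclusion: total cropped area ≥ 75 000 Ha AND considered-crop
share ≥ 30% of the total cropped area, evaluated per district-season
(gross cropped area). In synthetic scenes the generator allocates all
cropland to modelled crops, so the share rule binds only on constructed
tables; both rules are exercised directly in the tests.

NGPPCY: `ngppcy(p) = gpp(p)/mean_d(gpp) × yield_d`, with the unweighted
mean over the district's cropland pixels (an area-weighted variant is
available) and the district crop-combined yield computed as
Σ production / Σ area over the considered crops. Its defining property —
the district cropland mean of NGPPCY equals the district yield — holds to
1e-9 relative and is invariant to rescaling a district's GPP. A
multi-year mean GPP raster can replace the single-year normaliser via
`multi_year_mean`; single-year is the default.

## Synthetic scenes

The generator emulates the structure of the real driver set, not its
artifacts. Per scene: NDVI on cropland follows a beta-shaped unimodal
pulse (base 0.15, amplitude ≈ 0.5–0.8) with peak timing and amplitude
jittered per district and pixel; off-cropland NDVI is low and flat. LSWI
is an NDVI-correlated transform (0.7·NDVI − 0.12 plus a small seasonal
ripple), clipped to [−1, 1]. PAR (≈ 130–175 MJ m⁻² per composite) and
daytime temperature (≈ 22–31 °C) are generated on a coarse grid
(downscale factor 5 by default) with smooth seasonal arcs and spatial
variation, then bilinearly resampled to the model grid — the same
operation the pipeline applies to real reanalysis fields. Districts are
rectangular blocks; C4 fractions are constant per district in
U(0.1, 0.5); the cropland mask keeps ~90% of pixels with at least one
cropland pixel per district. The default scene (40×40 cells of 0.05°,
9 composites, 9 districts) gives seasonal totals of roughly 550–1000
gC m⁻², in the range of intensive cropping seasons, and district areas
well above the 75 000 Ha filter.

Ground-truth seasonal GPP is the forward model run on the noise-free
drivers; emitted NDVI/LSWI add Gaussian noise (SD 0.02 by default) and
are clipped, so zero-noise scenes reproduce the truth bit-exactly.
Production tables invert the statistics conversion from the true HIs per
district with seeded Dirichlet(4) crop shares; noise is multiplicative
mean-one lognormal (SD 0.05 by default), keeping production positive.
Default per-crop HI bounds and RC/MC constants are typical agronomic
values shipped in `DEFAULT_COEFFICIENTS` and overridable via YAML.

What passing tests show and do not show: the pipeline's algebra,
conservation properties, determinism and parameter recovery are verified
end to end, including under statistics noise. Synthetic scenes contain no
cloud gaps, QA artifacts, mixed or shifting phenology calendars, fallow
dynamics or unreported minor crops, so test results bound implementation
correctness — not the accuracy attainable on real satellite and
government data.

## Problem sizes

Tests run on 14–20 pixel-square scenes with 5–8 composites and 4–6
districts; the analysis drivers use 40×40 scenes with 9 composites and 9
districts, and 20 Monte-Carlo seeds per noise level in the degradation
experiment. These sizes make every stage's behaviour visible (multiple
districts, meaningful spatial variation) while keeping the full suite in
seconds.

## Known limitations

- The shared-`s` calibration returns one point of the solution manifold;
  cross-district or cross-year pooling that could identify individual
  crop HIs is out of scope.
- RC/MC are fixed constants per crop; no re-estimation.
- No EVI driver, QA screening, gap-filling, or real-geometry zonal
  statistics (district labels are rasters).
- The winter season spills into the next calendar year; annual totals are
  deliberately not formed (April–May are outside both seasons).
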