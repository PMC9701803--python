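"""Unit and property tests for the VPM core equations."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from agrigpp import vpm
from agrigpp.raster import CompositeStack, GridSpec, Raster
from agrigpp.vpm import (C3_DEFAULT, C4_DEFAULT, FparParams, PathwayParams,
                         compute_fpar, compute_gpp_composite, compute_lswi,
                         compute_lswi_max, compute_lue_max, compute_tscalar,
                         compute_wscalar, composite_climate, integrate_season,
                         resample_to_grid)

GRID = GridSpec(4, 5, 0.05, 75.0, 25.0)


def stack_of(layers, variable="x"):
    dates = [dt.date(2005, 6, 1) + dt.timedelta(days=16 * i)
             for i in range(len(layers))]
    return CompositeStack(np.array(layers, dtype=float), dates, GRID, variable)


class TestFpar:
    @pytest.mark.parametrize("ndvi,expected", [
        (0.5, 0.452),           # 1.24*0.5 - 0.168
        (0.168 / 1.24, 0.0),    # root of the linear relation
        (0.05, 0.0),            # clamped below
        (1.0, 1.0),             # clamped above (1.24 - 0.168 = 1.072)
    ])
    def test_linear_relation_with_clamping(self, ndvi, expected):
        assert compute_fpar(ndvi) == pytest.approx(expected, abs=1e-12)

    def test_out_of_range_ndvi_rejected(self):
        with pytest.raises(ValueError):
            compute_fpar(1.5)

    def test_nan_propagates(self):
        assert np.isnan(compute_fpar(float("nan")))


class TestLswi:
    @pytest.mark.parametrize("nir,swir,expected", [
        (0.3, 0.1, 0.5),
        (0.2, 0.2, 0.0),
        (0.4, 0.0, 1.0),
    ])
    def test_normalized_difference(self, nir, swir, expected):
        assert compute_lswi(nir, swir) == pytest.approx(expected, abs=1e-12)

    def test_zero_sum_is_nodata(self):
        assert np.isnan(compute_lswi(0.0, 0.0))

    def test_negative_reflectance_rejected(self):
        with pytest.raises(ValueError):
            compute_lswi(-0.1, 0.2)


class TestWscalar:
    @pytest.mark.parametrize("lswi,lswi_max,expected", [
        (0.4, 0.4, 1.0),
        (-1.0, 0.3, 0.0),
        (0.0, 0.4, 1 / 1.4),
    ])
    def test_ratio(self, lswi, lswi_max, expected):
        assert compute_wscalar(lswi, lswi_max) == pytest.approx(expected, abs=1e-12)

    def test_degenerate_seasonal_max_is_nodata(self):
        assert np.isnan(compute_wscalar(0.0, -1.0))

    def test_clamped_above_one(self):
        assert compute_wscalar(0.5, 0.2) == 1.0


class TestTscalar:
    @pytest.mark.parametrize("t,expected", [
        (25.0, 1.0),                       # optimum
        (5.0, 0.0),                        # lower cardinal temperature
        (40.0, 0.0),                       # upper cardinal temperature
        (15.0, (-25.0 * 10.0) / (-250.0 - 100.0)),  # 0.714285...
        (-3.0, 0.0),                       # below range forced to zero
        (55.0, 0.0),                       # above range forced to zero
    ])
    def test_parabolic_response_c3(self, t, expected):
        assert compute_tscalar(t, C3_DEFAULT) == pytest.approx(expected, abs=1e-12)

    def test_c4_optimum(self):
        assert compute_tscalar(30.0, C4_DEFAULT) == 1.0

    @given(st.floats(-20, 60))
    @settings(derandomize=True, max_examples=200)
    def test_bounded_unit_interval(self, t):
        v = compute_tscalar(t, C3_DEFAULT)
        assert 0.0 <= v <= 1.0

    def test_maximum_located_at_topt_by_grid_search(self):
        grid = np.linspace(-10, 60, 70001)
        for params in (C3_DEFAULT, C4_DEFAULT):
            vals = compute_tscalar(grid, params)
            assert grid[np.argmax(vals)] == pytest.approx(params.t_opt, abs=1e-9)

    def test_invalid_ordering_rejected(self):
        with pytest.raises(ValueError):
            PathwayParams(t_min=30, t_max=20, t_opt=25, lue_max=1.0)


class TestLueMax:
    @pytest.mark.parametrize("p3,p4,expected", [
        (1.0, 0.0, 1.388),
        (0.0, 1.0, 1.542),
        (0.5, 0.5, 1.465),
    ])
    def test_convex_mixing(self, p3, p4, expected):
        assert compute_lue_max(p3, p4) == pytest.approx(expected, abs=1e-12)

    @given(st.floats(0, 1))
    @settings(derandomize=True, max_examples=100)
    def test_between_endmembers(self, p3):
        v = compute_lue_max(p3, 1 - p3)
        assert min(1.388, 1.542) - 1e-12 <= v <= max(1.388, 1.542) + 1e-12

    def test_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError):
            compute_lue_max(0.5, 0.6)


class TestGppComposite:
    def test_zero_fpar_gives_zero_gpp(self):
        # NDVI below b/a clamps fPAR to 0
        assert compute_gpp_composite(0.1, 0.2, 0.3, 200.0, 25.0, 1.0, 0.0) == 0.0

    def test_scalar_arithmetic_example(self):
        # eps*=1.388, T=25 -> Tsc=1, W=1, fPAR=0.5 needs NDVI=(0.5+0.168)/1.24
        ndvi = (0.5 + 0.168) / 1.24
        gpp = compute_gpp_composite(ndvi, 0.3, 0.3, 200.0, 25.0, 1.0, 0.0)
        assert gpp == pytest.approx(1.388 * 0.5 * 200.0, rel=1e-12)

    def test_nodata_driver_propagates(self):
        assert np.isnan(compute_gpp_composite(np.nan, 0.2, 0.3, 200.0, 25.0, 1.0, 0.0))
        assert np.isnan(compute_gpp_composite(0.5, 0.2, 0.3, np.nan, 25.0, 1.0, 0.0))

    def test_linear_in_par(self):
        g1 = compute_gpp_composite(0.6, 0.2, 0.3, 100.0, 22.0, 0.7, 0.3)
        g2 = compute_gpp_composite(0.6, 0.2, 0.3, 300.0, 22.0, 0.7, 0.3)
        assert g2 == pytest.approx(3 * g1, rel=1e-12)

    def test_pure_c3_matches_single_pathway_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            ndvi = rng.uniform(0.2, 0.9)
            lswi, lswi_max = rng.uniform(-0.2, 0.3), 0.4
            par, t = rng.uniform(50, 300), rng.uniform(10, 38)
            expect = (1.388
                      * compute_tscalar(t, C3_DEFAULT)
                      * (1 + lswi) / (1 + lswi_max)
                      * max(0.0, min(1.0, 1.24 * ndvi - 0.168))
                      * par)
            got = compute_gpp_composite(ndvi, lswi, lswi_max, par, t, 1.0, 0.0)
            assert got == pytest.approx(expect, rel=1e-12)


class TestSeasonalIntegration:
    def test_sum_over_composites(self):
        stack = stack_of([np.full(GRID.shape, 10.0)] * 3, "gpp")
        mask = Raster(np.ones(GRID.shape), GRID)
        out = integrate_season(stack, mask)
        assert np.allclose(out.data, 30.0)

    def test_mask_zero_becomes_nodata(self):
        stack = stack_of([np.full(GRID.shape, 10.0)], "gpp")
        mask = Raster(np.zeros(GRID.shape), GRID)
        assert np.isnan(integrate_season(stack, mask).data).all()

    def test_single_layer_identity_on_cropland(self):
        layer = np.arange(20, dtype=float).reshape(GRID.shape)
        stack = stack_of([layer], "gpp")
        mask = Raster(np.ones(GRID.shape), GRID)
        assert np.array_equal(integrate_season(stack, mask).data, layer)

    def test_equals_running_sum_of_composites(self):
        rng = np.random.default_rng(2)
        layers = rng.uniform(0, 20, (5,) + GRID.shape)
        stack = stack_of(list(layers), "gpp")
        mask = Raster(np.ones(GRID.shape), GRID)
        out = integrate_season(stack, mask)
        ref = sum(layers[i] for i in range(5))
        assert np.allclose(out.data, ref, rtol=1e-12, atol=0)

    def test_shape_mismatch_rejected(self):
        stack = stack_of([np.zeros(GRID.shape)], "gpp")
        other = Raster(np.ones((3, 3)), GridSpec(3, 3, 0.05, 75.0, 25.0))
        with pytest.raises(ValueError):
            integrate_season(stack, other)


class TestLswiMax:
    def test_per_pixel_maximum(self):
        layers = [np.full(GRID.shape, v) for v in (-0.1, 0.3, 0.2)]
        out = compute_lswi_max(stack_of(layers, "lswi"))
        assert np.allclose(out.data, 0.3)

    def test_nodata_layers_ignored(self):
        l0 = np.full(GRID.shape, 0.1)
        l1 = np.full(GRID.shape, 0.2)
        l1[0, 0] = np.nan
        out = compute_lswi_max(stack_of([l0, l1], "lswi"))
        assert out.data[0, 0] == pytest.approx(0.1)
        assert out.data[1, 1] == pytest.approx(0.2)

    def test_all_nodata_pixel_stays_nodata(self):
        l0 = np.full(GRID.shape, 0.1)
        l0[0, 0] = np.nan
        out = compute_lswi_max(stack_of([l0], "lswi"))
        assert np.isnan(out.data[0, 0])


class TestCompositeClimate:
    def make_series(self, days, value):
        idx = pd.to_datetime(days)
        return pd.Series(value, index=[d.date() for d in idx])

    def test_constant_par_window_total(self):
        start = dt.date(2005, 6, 1)
        days = [start + dt.timedelta(days=i) for i in range(16)]
        par = pd.Series(100.0, index=days)
        t = pd.Series(20.0, index=days)
        par16, _ = composite_climate(par, t, t, [start])
        assert par16[0] == pytest.approx(100 * 0.0864 * 16, rel=1e-12)

    def test_daytime_mean_estimator_weights(self):
        start = dt.date(2005, 6, 1)
        days = [start + dt.timedelta(days=i) for i in range(16)]
        par = pd.Series(100.0, index=days)
        tmax = pd.Series(30.0, index=days)
        tmin = pd.Series(10.0, index=days)
        _, tday = composite_climate(par, tmax, tmin, [start])
        assert tday[0] == pytest.approx(0.75 * 30 + 0.25 * 10, abs=1e-12)
        _, tmean = composite_climate(par, tmax, tmin, [start],
                                     tday_weights=(0.5, 0.5))
        assert tmean[0] == pytest.approx(20.0, abs=1e-12)

    def test_missing_day_flags_window_nodata(self):
        start = dt.date(2005, 6, 1)
        days = [start + dt.timedelta(days=i) for i in range(15)]  # one short
        par = pd.Series(100.0, index=days)
        t = pd.Series(20.0, index=days)
        par16, tday = composite_climate(par, t, t, [start])
        assert np.isnan(par16[0]) and np.isnan(tday[0])


class TestResample:
    def test_constant_field_preserved(self):
        coarse = Raster(np.full((4, 4), 7.0), GridSpec(4, 4, 0.25, 74.5, 25.5))
        fine = GridSpec(10, 10, 0.05, 75.0, 25.0)
        out = resample_to_grid(coarse, fine)
        assert np.allclose(out.data, 7.0, rtol=1e-12)

    def test_identity_at_equal_grids(self):
        data = np.arange(12, dtype=float).reshape(3, 4)
        g = GridSpec(3, 4, 0.05, 75.0, 25.0)
        out = resample_to_grid(Raster(data, g), g)
        assert np.allclose(out.data, data, atol=1e-12)

    def test_linear_ramp_interpolated_exactly(self):
        # bilinear interpolation reproduces an affine field at cell centers
        cg = GridSpec(6, 6, 0.2, 74.8, 25.2)
        lon = cg.lon_centers()[None, :] * np.ones((6, 1))
        coarse = Raster(3.0 * lon + 1.0, cg)
        fine = GridSpec(10, 10, 0.05, 75.0, 25.0)
        out = resample_to_grid(coarse, fine)
        expect = 3.0 * fine.lon_centers()[None, :] + 1.0
        assert np.allclose(out.data, np.broadcast_to(expect, (10, 10)), rtol=1e-9)

    def test_non_overlapping_extent_rejected(self):
        coarse = Raster(np.zeros((3, 3)), GridSpec(3, 3, 0.05, 0.0, 0.0))
        with pytest.raises(ValueError):
            resample_to_grid(coarse, GridSpec(3, 3, 0.05, 75.0, 25.0))

    def test_nearest_mode(self):
        coarse = Raster(np.array([[1.0, 2.0], [3.0, 4.0]]),
                        GridSpec(2, 2, 0.5, 75.0, 25.5))
        fine = GridSpec(4, 4, 0.25, 75.0, 25.5)
        out = resample_to_grid(coarse, fine, method="nearest")
        assert set(np.unique(out.data)) <= {1.0, 2.0, 3.0, 4.0}


class TestSeasonCalendar:
    def test_16_day_start_dates(self):
        dates = vpm.season_start_dates("monsoon", 2005, 4)
        assert dates[0] == dt.date(2005, 6, 1)
        assert all((b - a).days == 16 for a, b in zip(dates, dates[1:]))

    def test_window_membership_spans(self):
        assert vpm.in_season(dt.date(2005, 6, 1), "monsoon", 2005)
        assert vpm.in_season(dt.date(2005, 10, 31), "monsoon", 2005)
        assert not vpm.in_season(dt.date(2005, 11, 1), "monsoon", 2005)
        # winter is labeled by its starting year and crosses the new year
        assert vpm.in_season(dt.date(2006, 3, 31), "winter", 2005)
        assert not vpm.in_season(dt.date(2005, 5, 1), "winter", 2005)
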