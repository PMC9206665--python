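"""Metric suite: geodesy, area series, cycles, correlations, maps."""

import numpy as np
import pandas as pd
import pytest
import xarray as xr

from topwet.evaluation import (
    EARTH_RADIUS_KM,
    RegionSpec,
    annual_stat_series,
    area_series,
    cell_area,
    cell_area_map,
    iav_stats,
    month_of_max,
    reference_correlation_map,
    rmse_map,
    seasonal_cycle,
)


def monthly_field(values, lat=None, lon=None, start="2000-01"):
    values = np.asarray(values, dtype=float)
    nt, nlat, nlon = values.shape
    return xr.DataArray(
        values,
        dims=("time", "lat", "lon"),
        coords={
            "time": pd.date_range(start, periods=nt, freq="MS"),
            "lat": lat if lat is not None else np.arange(nlat) * 0.25 + 0.125,
            "lon": lon if lon is not None else np.arange(nlon) * 0.25 + 0.125,
        },
        name="fwet",
    )


class TestCellArea:
    def test_global_grid_closes_to_sphere(self):
        lat_edges = np.linspace(-90, 90, 721)
        total = sum(
            cell_area((lat_edges[i], lat_edges[i + 1]), 0.25) * 1440
            for i in range(720)
        )
        sphere = 4 * np.pi * EARTH_RADIUS_KM**2
        assert total == pytest.approx(sphere, rel=1e-4)

    def test_equatorial_quarter_degree_cell(self):
        assert cell_area((-0.125, 0.125), 0.25) == pytest.approx(772.6, abs=0.5)

    def test_zero_width_band(self):
        assert cell_area((10.0, 10.0), 0.25) == 0.0

    def test_inverted_bounds_rejected(self):
        with pytest.raises(ValueError):
            cell_area((10.0, 5.0), 0.25)


class TestAreaSeries:
    def test_zero_field_zero_series(self):
        f = monthly_field(np.zeros((12, 4, 4)))
        assert (area_series(f) == 0).all()

    def test_full_fraction_equals_band_area(self):
        f = monthly_field(np.ones((1, 4, 4)))
        expected = float(
            cell_area_map(f["lat"].values, f["lon"].values, 0.25).sum() / 1e6
        )
        assert area_series(f).iloc[0] == pytest.approx(expected)

    def test_additivity_over_disjoint_regions(self):
        rng = np.random.default_rng(1)
        f = monthly_field(rng.uniform(0, 1, (6, 8, 4)))
        south = RegionSpec("s", -90, f["lat"].values[4])
        north = RegionSpec("n", f["lat"].values[4], 90)
        total = area_series(f)
        np.testing.assert_allclose(
            (area_series(f, south) + area_series(f, north)).values,
            total.values,
        )

    def test_empty_region_rejected(self):
        f = monthly_field(np.zeros((1, 2, 2)))
        with pytest.raises(ValueError):
            area_series(f, RegionSpec("far", 80, 89))

    def test_fill_treated_as_zero_with_warning(self):
        vals = np.ones((1, 2, 2))
        vals[0, 0, 0] = np.nan
        f = monthly_field(vals)
        with pytest.warns(UserWarning, match="zero"):
            s = area_series(f)
        full = area_series(monthly_field(np.ones((1, 2, 2))))
        assert s.iloc[0] < full.iloc[0]


class TestCycles:
    def test_periodic_input_recovered(self):
        base = np.sin(2 * np.pi * np.arange(12) / 12.0) + 2.0
        s = pd.Series(
            np.tile(base, 4), index=pd.date_range("2000-01", periods=48, freq="MS")
        )
        np.testing.assert_allclose(seasonal_cycle(s).values, base)

    def test_constant_input(self):
        s = pd.Series(3.0, index=pd.date_range("2000-01", periods=24, freq="MS"))
        assert (seasonal_cycle(s) == 3.0).all()

    def test_noisy_sinusoid_recovered_within_3se(self):
        rng = np.random.default_rng(8)
        n_years, sigma = 40, 0.3
        base = np.sin(2 * np.pi * np.arange(12) / 12.0)
        vals = np.tile(base, n_years) + rng.normal(0, sigma, 12 * n_years)
        s = pd.Series(
            vals, index=pd.date_range("1980-01", periods=12 * n_years, freq="MS")
        )
        se = sigma / np.sqrt(n_years)
        assert np.all(np.abs(seasonal_cycle(s).values - base) <= 3 * se)

    def test_annual_max_and_mean(self):
        s = pd.Series(
            np.tile(np.arange(12.0), 2),
            index=pd.date_range("2000-01", periods=24, freq="MS"),
        )
        assert (annual_stat_series(s, "max") == 11.0).all()
        assert (annual_stat_series(s, "mean") == 5.5).all()

    def test_partial_year_dropped_with_warning(self):
        s = pd.Series(
            1.0, index=pd.date_range("2000-01", periods=30, freq="MS")
        )
        with pytest.warns(UserWarning, match="partial"):
            out = annual_stat_series(s, "max")
        assert list(out.index) == [2000, 2001]

    def test_single_spike_is_year_max(self):
        vals = np.zeros(12)
        vals[6] = 9.0
        s = pd.Series(vals, index=pd.date_range("2000-01", periods=12, freq="MS"))
        assert annual_stat_series(s, "max").iloc[0] == 9.0


class TestIavStats:
    def test_perfect_correlation(self):
        a = np.array([1.0, 2.0, 3.0])
        r, p, sd_a, sd_b = iav_stats(a, 2 * a)
        assert r == pytest.approx(1.0)
        assert sd_a == pytest.approx(1.0)

    def test_perfect_anticorrelation(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        r, _, _, _ = iav_stats(a, -a + 10)
        assert r == pytest.approx(-1.0)

    def test_zero_variance_gives_nan_not_crash(self):
        r, p, sd_a, _ = iav_stats([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        assert np.isnan(r) and np.isnan(p) and sd_a == 0.0

    def test_sample_sd_uses_n_minus_1(self):
        _, _, sd, _ = iav_stats([0.0, 1.0, 2.0], [3.0, 1.0, 2.0])
        assert sd == pytest.approx(1.0)


class TestRmseMap:
    def test_identical_fields_zero_map(self):
        rng = np.random.default_rng(2)
        f = monthly_field(rng.uniform(0, 1, (24, 3, 3)))
        out = rmse_map(f, f)
        np.testing.assert_allclose(out["rmse"].values, 0.0)

    def test_static_mode_is_abs_difference(self):
        sim = monthly_field(np.full((12, 1, 1), 0.6))
        obs = monthly_field(np.full((12, 1, 1), 0.2))
        out = rmse_map(sim, obs, mode="long_term_max")
        assert out["rmse"].values[0, 0] == pytest.approx(0.4)

    def test_below_threshold_flag(self):
        sim = monthly_field(np.zeros((12, 1, 2)))
        obs_vals = np.zeros((12, 1, 2))
        obs_vals[:, 0, 1] = 0.5
        out = rmse_map(sim, monthly_field(obs_vals))
        assert bool(out["below_threshold"].values[0, 0])
        assert not bool(out["below_threshold"].values[0, 1])

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError):
            rmse_map(
                monthly_field(np.zeros((12, 2, 2))),
                monthly_field(np.zeros((12, 3, 3))),
            )


class TestMonthOfMax:
    def test_july_peak(self):
        t = np.arange(24)
        vals = (0.5 - 0.4 * np.cos(2 * np.pi * (t - 0.5) / 12.0))[:, None, None]
        f = monthly_field(vals)  # peak at t=6 -> July
        assert month_of_max(f).values[0, 0] == 7

    def test_constant_nonzero_ties_to_january(self):
        f = monthly_field(np.full((12, 1, 1), 0.4))
        assert month_of_max(f).values[0, 0] == 1

    def test_two_equal_peaks_earliest_wins(self):
        vals = np.zeros((12, 1, 1))
        vals[2] = vals[8] = 0.9  # March and September
        assert month_of_max(monthly_field(vals)).values[0, 0] == 3

    def test_all_zero_cell_flagged(self):
        f = monthly_field(np.zeros((12, 1, 1)))
        assert month_of_max(f).values[0, 0] == 0


class TestReferenceCorrelation:
    def test_self_correlation_is_one(self):
        rng = np.random.default_rng(3)
        f = monthly_field(rng.uniform(0, 1, (36, 3, 3)))
        out = reference_correlation_map(f, f)
        np.testing.assert_allclose(out["r"].values, 1.0, atol=1e-12)
        assert bool(out["sig_05"].values.all())

    def test_negated_reference_gives_minus_one(self):
        rng = np.random.default_rng(4)
        f = monthly_field(rng.uniform(0, 1, (36, 2, 2)))
        out = reference_correlation_map(f, -f + 1.0)
        np.testing.assert_allclose(out["r"].values, -1.0, atol=1e-12)

    def test_zero_variance_cell_undefined(self):
        vals = np.random.default_rng(5).uniform(0, 1, (36, 1, 2))
        vals[:, 0, 0] = 0.5
        f = monthly_field(vals)
        ref = monthly_field(np.random.default_rng(6).uniform(0, 1, (36, 1, 2)))
        out = reference_correlation_map(f, ref)
        assert np.isnan(out["r"].values[0, 0])
        assert not bool(out["sig_05"].values[0, 0])

    def test_too_short_overlap_rejected(self):
        f = monthly_field(np.zeros((12, 1, 1)))
        with pytest.raises(ValueError, match="24"):
            reference_correlation_map(f, f)

    def test_null_rate_near_alpha(self):
        # white-noise reference: ~5% of cells significant at p < 0.05
        rng = np.random.default_rng(7)
        f = monthly_field(rng.normal(size=(168, 20, 50)))
        ref = monthly_field(rng.normal(size=(168, 20, 50)))
        out = reference_correlation_map(f, ref)
        rate = float(out["sig_05"].values.mean())
        # binomial 99% interval around 0.05 for n = 1000
        assert 0.03 <= rate <= 0.07
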