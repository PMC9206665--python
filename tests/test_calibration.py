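"""Observation preparation and per-cell/grid parameter calibration."""

import numpy as np
import pandas as pd
import pytest
import xarray as xr

from topwet.calibration import (
    CalMode,
    CalTarget,
    CellStatus,
    calibrate_cell,
    calibrate_grid,
    dataset_to_params,
    max_all,
    params_to_dataset,
    prepare_obs,
    reduce_series,
    rmse,
)
from topwet.core import empirical_curve, fit_sigmoid, psi
from topwet.synthetic import gen_truth_obs
from topwet.wtd import saturation_deficit_grid, wet_mask_grid

from conftest import random_subgrid


class TestRmse:
    def test_identity_is_zero(self):
        assert rmse([0.1, 0.5, 0.9], [0.1, 0.5, 0.9]) == 0.0

    def test_hand_value(self):
        assert rmse([0.2, 0.4], [0.4, 0.2]) == pytest.approx(0.2)

    def test_single_sample_is_abs_difference(self):
        assert rmse([0.7], [0.4]) == pytest.approx(0.3)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            rmse([0.1, 0.2], [0.1])


class TestReduceSeries:
    times = pd.date_range("2000-01", periods=36, freq="MS")

    def test_long_term_max(self):
        vals = np.arange(36) / 36.0
        assert reduce_series(vals, self.times, "long_term_max") == pytest.approx(
            [35 / 36]
        )

    def test_yearly_max(self):
        vals = np.tile(np.arange(12) / 12.0, 3) * np.repeat([1.0, 0.5, 0.25], 12)
        out = reduce_series(vals, self.times, "yearly_max")
        assert out == pytest.approx([11 / 12, 11 / 24, 11 / 48])

    def test_seasonal_cycle(self):
        vals = np.tile(np.arange(12) / 12.0, 3)
        out = reduce_series(vals, self.times, "seasonal_cycle")
        assert out == pytest.approx(np.arange(12) / 12.0)

    def test_all_months_identity(self):
        vals = np.linspace(0, 1, 36)
        np.testing.assert_array_equal(
            reduce_series(vals, self.times, "all_months"), vals
        )


def field(values, times=None):
    values = np.asarray(values, dtype=float)
    coords = {"lat": np.arange(values.shape[-2]) * 0.25,
              "lon": np.arange(values.shape[-1]) * 0.25}
    if times is not None:
        return xr.DataArray(values, dims=("time", "lat", "lon"),
                            coords={"time": times, **coords})
    return xr.DataArray(values, dims=("lat", "lon"), coords=coords)


class TestPrepareObs:
    def test_static_long_term_max_pass_through(self):
        f = field([[0.3, 0.0], [0.9, 0.5]])
        target, fmax = prepare_obs(f, mode="long_term_max")
        assert target.sizes["tstat"] == 1
        np.testing.assert_allclose(fmax.values, f.values)

    def test_rice_removal_clips_at_zero(self):
        f = field([[0.3]])
        rice = field([[0.5]])
        _, fmax = prepare_obs(f, rice_fraction=rice)
        assert fmax.values[0, 0] == 0.0

    def test_max_all_union(self):
        fields = [field([[0.2]]), field([[0.5]]), field([[0.1]])]
        assert max_all(fields).values[0, 0] == pytest.approx(0.5)

    def test_monthly_field_reduced_to_max(self):
        times = pd.date_range("2000-01", periods=24, freq="MS")
        vals = np.zeros((24, 1, 1))
        vals[7] = 0.8
        target, fmax = prepare_obs(field(vals, times), mode="long_term_max")
        assert fmax.values[0, 0] == pytest.approx(0.8)

    def test_yearly_max_mode_shape(self):
        times = pd.date_range("2000-01", periods=24, freq="MS")
        vals = np.random.default_rng(0).uniform(0, 1, (24, 2, 2))
        target, _ = prepare_obs(field(vals, times), mode="yearly_max")
        assert target.sizes["tstat"] == 2

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError):
            max_all([field([[0.2]]), field([[0.2, 0.3]])])


class TestCalTarget:
    def test_long_term_max_needs_scalar(self):
        with pytest.raises(ValueError):
            CalTarget(mode="long_term_max", values=[0.1, 0.2])

    def test_fraction_range_enforced(self):
        with pytest.raises(ValueError):
            CalTarget(mode="all_months", values=[1.5])


class TestCalibrateCell:
    def _world(self, true_m=8, n_months=48, seed=3):
        rng = np.random.default_rng(seed)
        sg = random_subgrid(rng, n_pixels=2000)
        times = pd.date_range("2000-01", periods=n_months, freq="MS")
        gamma = 0.45 + 0.35 * np.sin(2 * np.pi * np.arange(n_months) / 12.0)
        mask = np.zeros(n_months, dtype=bool)
        truth = fit_sigmoid(empirical_curve(sg, true_m))
        obs = psi(gamma, truth)
        return sg, gamma, mask, times, obs

    def test_recovers_true_m_long_term_max(self):
        sg, gamma, mask, times, obs = self._world(true_m=8)
        target = CalTarget(mode="long_term_max", values=[obs.max()])
        params = calibrate_cell(sg, gamma, mask, target, times=times)
        assert params.m == 8
        assert params.cal_rmse < 1e-9
        assert params.status is CellStatus.CALIBRATED

    def test_recovers_true_m_all_months(self):
        sg, gamma, mask, times, obs = self._world(true_m=11)
        target = CalTarget(mode="all_months", values=obs)
        params = calibrate_cell(sg, gamma, mask, target, times=times)
        assert params.m == 11

    def test_returned_m_is_optimal(self):
        # exhaustive recheck: no alternative M scores strictly better
        sg, gamma, mask, times, obs = self._world(true_m=5)
        target = CalTarget(mode="long_term_max", values=[obs.max()])
        params = calibrate_cell(sg, gamma, mask, target, times=times)
        for m in range(1, 16):
            sp = fit_sigmoid(empirical_curve(sg, m))
            sim = psi(gamma, sp)
            score = rmse(target.values, [sim.max()])
            assert params.cal_rmse <= score + 1e-12

    def test_zero_fmax_masks_cell(self):
        sg, gamma, mask, times, _ = self._world()
        target = CalTarget(mode="long_term_max", values=[0.0])
        params = calibrate_cell(sg, gamma, mask, target, times=times)
        assert params.status is CellStatus.MASKED
        assert params.f_max == 0.0

    def test_equal_rmse_ties_break_to_smaller_m(self):
        # all months masked: every M simulates identically zero
        sg, gamma, mask, times, obs = self._world()
        mask = np.ones_like(mask)
        target = CalTarget(mode="long_term_max", values=[0.4])
        params = calibrate_cell(sg, gamma, mask, target, times=times)
        assert params.m == 1
        assert params.cal_rmse == pytest.approx(0.4)


class TestCalibrateGrid:
    def test_self_consistent_recovery(self, small_world):
        w = small_world
        gamma = saturation_deficit_grid(w["forcing"])
        mask = wet_mask_grid(w["forcing"])
        target, fmax = prepare_obs(w["obs_max"], mode="long_term_max")
        params = calibrate_grid(w["cti"], gamma, mask, target, fmax)
        ok = params["status"].values == CellStatus.CALIBRATED.code
        assert ok.sum() >= 0.8 * len(w["cti"])
        recovered = params["m"].values[ok] == w["true_m"].values[ok]
        assert recovered.mean() >= 0.9
        assert np.nanmax(params["cal_rmse"].values[ok]) < 1e-3

    def test_desert_cells_masked(self, small_world):
        w = small_world
        gamma = saturation_deficit_grid(w["forcing"])
        mask = wet_mask_grid(w["forcing"])
        target, fmax = prepare_obs(w["obs_max"], mode="long_term_max")
        params = calibrate_grid(w["cti"], gamma, mask, target, fmax)
        desert = w["forcing"]["climate_class"].values == "BWh"
        assert np.all(
            params["status"].values[desert] == CellStatus.MASKED.code
        )

    def test_params_dataset_round_trip(self, small_world):
        w = small_world
        gamma = saturation_deficit_grid(w["forcing"])
        mask = wet_mask_grid(w["forcing"])
        target, fmax = prepare_obs(w["obs_max"], mode="long_term_max")
        params = calibrate_grid(w["cti"], gamma, mask, target, fmax)
        back = params_to_dataset(
            dataset_to_params(params), w["cti"].lat, w["cti"].lon
        )
        for var in ("m", "v", "k", "q", "fmax", "status"):
            np.testing.assert_array_equal(params[var].values, back[var].values)
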