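"""Scikit-learn-style estimator wrapping calibration and simulation.

The diagnostic model is naturally fit/predict shaped: ``fit`` selects the
per-cell transmissivity-decay parameter M and its sigmoid reduction
(v, k, q) against observed wetland extent, ``predict`` maps monthly
water-table-surrogate fields to monthly wetland-fraction fields.  The
estimator composes with sklearn tooling via ``get_params``/``set_params``
and ``clone``; the functional modules remain usable on their own.
"""

from __future__ import annotations

import numpy as np
import xarray as xr
from sklearn.base import BaseEstimator

from .calibration import (
    CalMode,
    calibrate_grid,
    prepare_obs,
)
from .core import CTIGrid, DEFAULT_GAMMA_GRID
from .simulate import simulate_grid
from .wtd import saturation_deficit_grid, wet_mask_grid

__all__ = ["TopmodelWetland"]


class TopmodelWetland(BaseEstimator):
    """Diagnostic TOPMODEL wetland-extent model on a regular grid.

    Parameters
    ----------
    mode
        Calibration target statistic: ``"long_term_max"`` (default),
        ``"yearly_max"``, ``"seasonal_cycle"`` or ``"all_months"``.
    gamma_grid
        Water-table scan grid used to build the per-cell empirical
        flooded-fraction curves (default: 301 points over [-1 m, 2 m]).
    n_jobs
        Cells are calibrated independently; > 1 parallelises over cells.
    st_method
        How the 70 cm mask temperature is sampled: ``"layer"`` (containing
        layer, default) or ``"interp"`` (midpoint interpolation).

    Attributes
    ----------
    params_ : xarray.Dataset
        Per-cell parameter map (m, v, k, q, fmax, cal_rmse, status).
    fmax_ : xarray.DataArray
        Observed long-term-maximum fraction used as the per-cell cap.
    n_cells_ : int
        Number of calibrated cells.
    """

    def __init__(
        self,
        mode: str = "long_term_max",
        gamma_grid=None,
        n_jobs: int | None = None,
        st_method: str = "layer",
    ):
        self.mode = mode
        self.gamma_grid = gamma_grid
        self.n_jobs = n_jobs
        self.st_method = st_method

    # -- helpers -----------------------------------------------------------
    def _gamma_grid(self):
        return DEFAULT_GAMMA_GRID if self.gamma_grid is None else np.asarray(
            self.gamma_grid, dtype=float
        )

    def _forcing_to_gamma_mask(self, X):
        """Accept either a forcing dataset or a prepared (gamma, mask) pair."""
        if isinstance(X, xr.Dataset):
            gamma = saturation_deficit_grid(X)
            mask = wet_mask_grid(X, st_method=self.st_method)
            return gamma, mask
        gamma, mask = X
        return gamma, mask

    # -- sklearn surface ---------------------------------------------------
    def fit(self, X, y, rice_fraction=None):
        """Calibrate every cell against observed wetland extent.

        Parameters
        ----------
        X
            ``(cti_grid, forcing)`` where ``cti_grid`` is a
            :class:`~topwet.core.CTIGrid` and ``forcing`` is either the
            forcing dataset or a prepared ``(gamma, mask)`` pair of
            (time, lat, lon) fields.
        y
            Observed wetland fraction: a monthly field, a static map, or a
            list of fields combined by per-cell union of their maxima.
        rice_fraction
            Optional rice-paddy fraction map removed from the observations
            by subtract-and-clip before calibration.
        """
        cti_grid, forcing = X
        if not isinstance(cti_grid, CTIGrid):
            raise TypeError("X[0] must be a CTIGrid")
        gamma, mask = self._forcing_to_gamma_mask(forcing)
        mode = CalMode(self.mode)
        target, fmax = prepare_obs(y, rice_fraction=rice_fraction, mode=mode)
        self.params_ = calibrate_grid(
            cti_grid, gamma, mask, target, fmax,
            mode=mode, gamma_grid=self._gamma_grid(), n_jobs=self.n_jobs,
        )
        self.fmax_ = fmax
        self.n_cells_ = int((self.params_["status"].values >= 0).sum())
        return self

    def predict(self, X, period=None) -> xr.DataArray:
        """Simulate monthly wetland fractions from forcing.

        ``X`` is a forcing dataset or a prepared ``(gamma, mask)`` pair;
        ``period`` optionally restricts the simulated time span.
        """
        if not hasattr(self, "params_"):
            raise RuntimeError("estimator is not fitted")
        gamma, mask = self._forcing_to_gamma_mask(X)
        return simulate_grid(self.params_, gamma, mask, period=period)

    def score(self, X, y) -> float:
        """Negative grid-mean calibration-mode RMSE against observations."""
        from .evaluation import rmse_map

        sim = self.predict(X)
        err = rmse_map(sim, y, mode=self.mode)["rmse"]
        return -float(np.nanmean(err.values))
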