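"""Monthly wetland-fraction simulation from calibrated parameters.

Per cell and month the product value is

    fwet = 0                       if the zero-wetland mask fires,
    fwet = min(psi(gamma), f_max)  otherwise,

with NaN propagated where the water-table surrogate is missing.
"""

from __future__ import annotations

import numpy as np
import xarray as xr

from .calibration import CellParams, CellStatus
from .core import psi

__all__ = ["simulate_cell", "simulate_grid"]


def simulate_cell(
    params: CellParams,
    gamma_series: np.ndarray,
    mask_series: np.ndarray,
    apply_fmax: bool = True,
) -> np.ndarray:
    """Monthly fraction series of one cell."""
    gamma_series = np.asarray(gamma_series, dtype=float)
    mask_series = np.asarray(mask_series, dtype=bool)
    if params.status is CellStatus.MASKED:
        out = np.zeros_like(gamma_series)
    elif params.status is CellStatus.DEGENERATE:
        out = np.full_like(gamma_series, params.f_const)
    else:
        out = psi(gamma_series, params.sigmoid)
    if apply_fmax and params.status is not CellStatus.MASKED:
        out = np.minimum(out, params.f_max)
    out = np.where(mask_series, 0.0, out)
    return np.where(np.isnan(gamma_series), np.nan, out)


def simulate_grid(
    params: xr.Dataset,
    gamma: xr.DataArray,
    mask: xr.DataArray,
    period: tuple | None = None,
    apply_fmax: bool = True,
) -> xr.DataArray:
    """Vectorised simulation over the whole grid.

    ``params`` is the parameter-map dataset from the calibration stage;
    ``gamma``/``mask`` are (time, lat, lon) fields.  ``period`` is an
    optional (start, end) pair of anything ``DataArray.sel(time=...)``
    accepts; the simulated period is the intersection with the forcing.
    Cells without parameters come out as NaN.
    """
    gamma = gamma.transpose("time", "lat", "lon")
    mask = mask.transpose("time", "lat", "lon")
    if period is not None:
        gamma = gamma.sel(time=slice(*period))
        mask = mask.sel(time=slice(*period))
        if gamma.sizes["time"] == 0:
            raise ValueError("empty intersection of requested period and forcing")
    if params["m"].shape != gamma.shape[1:]:
        raise ValueError("parameter map does not match the forcing grid")

    v = params["v"].values[None, :, :]
    k = params["k"].values[None, :, :]
    q = params["q"].values[None, :, :]
    g = gamma.values
    # asymmetric sigmoid in log space (safe against overflow)
    t = np.log(v) - k * (g - q)
    fw = np.exp(-np.logaddexp(0.0, t) / v)

    status = params["status"].values[None, :, :]
    f_const = params["f_const"].values[None, :, :]
    fw = np.where(status == CellStatus.DEGENERATE.code, f_const, fw)
    if apply_fmax:
        fw = np.minimum(fw, params["fmax"].values[None, :, :])
    fw = np.where(status == CellStatus.MASKED.code, 0.0, fw)
    fw = np.where(mask.values, 0.0, fw)
    fw = np.where(np.isnan(g) | (status < 0), np.nan, fw)

    return xr.DataArray(
        fw,
        dims=("time", "lat", "lon"),
        coords={k_: gamma.coords[k_] for k_ in ("time", "lat", "lon")},
        name="fwet",
        attrs={"units": "1", "long_name": "wetland fraction", "valid_range": [0.0, 1.0]},
    )
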