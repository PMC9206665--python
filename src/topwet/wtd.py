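"""Water-table surrogate from layered soil moisture, plus zero-wetland masks.

Coarse reanalyses do not resolve a water table, so the model uses the
soil-moisture saturation deficit

    theta_SD = z_l0 - sum_{l<=l0} theta_l * dz_l / theta_S      [m]

as its surrogate: the depth of the unfrozen column minus the water it
holds, normalised by the saturated water content.  A fully saturated
column gives 0 (water table at the surface), a bone-dry column gives the
column depth.  ``l0`` counts the layers above the first frozen layer
(layer-mean soil temperature < 0 degC); a frozen top layer forces
theta_SD = 0.

Three rules force the wetland fraction of a cell-month to zero outright:
soil temperature at 70 cm below 0 degC, more than 5 soil-freezing days in
the month, or a Koeppen hot-desert (BWh) cell.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import xarray as xr

__all__ = [
    "SoilColumnSeries",
    "MaskInputs",
    "HOT_DESERT_CLASS",
    "FREEZE_DAYS_LIMIT",
    "saturation_deficit",
    "saturation_deficit_grid",
    "st_at_70cm",
    "wet_mask",
    "wet_mask_grid",
]

HOT_DESERT_CLASS = "BWh"
FREEZE_DAYS_LIMIT = 5  # months with more freezing days are masked
ST_PROBE_DEPTH = 0.70  # m, depth of the mask temperature probe
_THETA_TOL = 1e-9


@dataclass
class SoilColumnSeries:
    """Monthly layered soil moisture and temperature of one cell.

    ``layer_bounds`` are the layer interface depths in metres, top-down
    and contiguous from 0 (length n_layers + 1).  ``theta`` and
    ``soil_temp`` have shape (n_months, n_layers); ``theta_s`` is the
    saturated volumetric water content, uniform over depth.
    """

    layer_bounds: np.ndarray
    theta: np.ndarray
    soil_temp: np.ndarray
    theta_s: float

    def __post_init__(self):
        self.layer_bounds = np.asarray(self.layer_bounds, dtype=float)
        self.theta = np.atleast_2d(np.asarray(self.theta, dtype=float))
        self.soil_temp = np.atleast_2d(np.asarray(self.soil_temp, dtype=float))
        if self.layer_bounds[0] != 0.0:
            raise ValueError("layer bounds must start at the surface (0 m)")
        if np.any(np.diff(self.layer_bounds) <= 0):
            raise ValueError("layer bounds must be strictly increasing")
        n_layers = self.layer_bounds.size - 1
        if self.theta.shape[1] != n_layers or self.soil_temp.shape[1] != n_layers:
            raise ValueError("theta/soil_temp layer dimension mismatch")
        if not 0 < self.theta_s <= 1:
            raise ValueError("theta_s must be in (0, 1]")
        if np.nanmax(self.theta, initial=0.0) > self.theta_s + _THETA_TOL:
            raise ValueError(
                "theta exceeds theta_s; inputs must be pre-clipped to saturation"
            )

    @property
    def thickness(self) -> np.ndarray:
        return np.diff(self.layer_bounds)

    @property
    def total_depth(self) -> float:
        return float(self.layer_bounds[-1])

    @property
    def n_months(self) -> int:
        return self.theta.shape[0]


def saturation_deficit(column: SoilColumnSeries, month: int) -> float:
    """theta_SD of one column-month, in metres.

    Frozen layers (soil temperature < 0 degC) truncate the column: only
    layers above the first frozen one contribute, and ``z_l0`` becomes the
    depth of the uppermost frozen layer.  If the first layer is frozen the
    deficit is zero.  NaN soil moisture in a needed layer yields NaN.
    """
    theta = column.theta[month]
    st = column.soil_temp[month]
    frozen = st < 0.0
    if frozen.any():
        l0 = int(np.argmax(frozen))  # layers 0..l0-1 are unfrozen
    else:
        l0 = theta.size
    if l0 == 0:
        return 0.0
    z_l0 = column.layer_bounds[l0]
    dz = column.thickness[:l0]
    stored = np.sum(theta[:l0] * dz) / column.theta_s
    return float(z_l0 - stored)


def saturation_deficit_grid(forcing: xr.Dataset) -> xr.DataArray:
    """Vectorised theta_SD over a forcing dataset.

    Expects variables ``theta`` and ``soil_temp`` with dims
    (time, layer, lat, lon), a ``layer_bounds`` coordinate of length
    n_layers + 1 and a scalar attribute ``theta_s``.
    """
    theta = forcing["theta"].transpose("time", "layer", "lat", "lon")
    st = forcing["soil_temp"].transpose("time", "layer", "lat", "lon")
    theta_s = float(forcing.attrs["theta_s"])
    bounds = np.asarray(forcing["layer_bounds"].values, dtype=float)
    dz = np.diff(bounds)
    if np.nanmax(theta.values, initial=0.0) > theta_s + _THETA_TOL:
        raise ValueError("theta exceeds theta_s; inputs must be pre-clipped")

    frozen = (st.values < 0.0)
    n_layers = dz.size
    # index of the first frozen layer, n_layers when none
    any_frozen = frozen.any(axis=1)
    first_frozen = np.argmax(frozen, axis=1)
    l0 = np.where(any_frozen, first_frozen, n_layers)

    z_l0 = bounds[l0]
    # cumulative stored water above each possible truncation depth
    stored_layers = theta.values * dz[None, :, None, None] / theta_s
    cum = np.concatenate(
        [np.zeros_like(stored_layers[:, :1]), np.cumsum(stored_layers, axis=1)],
        axis=1,
    )
    stored = np.take_along_axis(cum, l0[:, None], axis=1)[:, 0]
    out = z_l0 - stored
    return xr.DataArray(
        out,
        dims=("time", "lat", "lon"),
        coords={k: forcing.coords[k] for k in ("time", "lat", "lon")},
        name="gamma",
        attrs={"units": "m", "long_name": "soil moisture saturation deficit"},
    )


def st_at_70cm(
    st_layers: np.ndarray,
    layer_bounds: np.ndarray,
    method: str = "layer",
) -> np.ndarray | float:
    """Soil temperature at the 70 cm probe depth.

    ``method='layer'`` (default) returns the temperature of the layer
    containing 0.70 m, which is reproducible across heterogeneous layer
    schemes; ``method='interp'`` interpolates linearly between layer
    midpoints.  Columns shallower than 0.70 m fall back to the deepest
    layer with a warning.
    """
    st_layers = np.asarray(st_layers, dtype=float)
    layer_bounds = np.asarray(layer_bounds, dtype=float)
    n_layers = layer_bounds.size - 1
    if layer_bounds[-1] < ST_PROBE_DEPTH:
        warnings.warn(
            f"soil column shallower than {ST_PROBE_DEPTH} m; "
            "using the deepest layer temperature"
        )
        return st_layers[..., n_layers - 1]
    if method == "layer":
        # containing layer: bounds[i] <= 0.70 < bounds[i+1]
        idx = int(np.searchsorted(layer_bounds, ST_PROBE_DEPTH, side="right") - 1)
        idx = min(idx, n_layers - 1)
        return st_layers[..., idx]
    if method == "interp":
        mids = 0.5 * (layer_bounds[:-1] + layer_bounds[1:])
        flat = st_layers.reshape(-1, n_layers)
        out = np.array([np.interp(ST_PROBE_DEPTH, mids, row) for row in flat])
        return out.reshape(st_layers.shape[:-1]) if st_layers.ndim > 1 else float(out[0])
    raise ValueError(f"unknown method {method!r}")


@dataclass
class MaskInputs:
    """Per-cell inputs of the zero-wetland mask rules."""

    st70: np.ndarray  # degC, per month
    freeze_days: np.ndarray  # days per month, integers in [0, 31]
    climate_class: str  # Koeppen label

    def __post_init__(self):
        self.st70 = np.atleast_1d(np.asarray(self.st70, dtype=float))
        self.freeze_days = np.atleast_1d(np.asarray(self.freeze_days))
        fd = self.freeze_days
        if np.any((fd < 0) | (fd > 31)):
            raise ValueError("freeze_days must be within [0, 31]")


def wet_mask(mask_inputs: MaskInputs, month: int) -> bool:
    """True when the cell-month must have zero wetland fraction.

    Fires when the 70 cm soil temperature is below 0 degC, when the month
    counts more than 5 soil-freezing days, or when the cell is Koeppen
    hot desert (BWh).
    """
    return bool(
        mask_inputs.st70[month] < 0.0
        or mask_inputs.freeze_days[month] > FREEZE_DAYS_LIMIT
        or mask_inputs.climate_class == HOT_DESERT_CLASS
    )


def wet_mask_grid(forcing: xr.Dataset, st_method: str = "layer") -> xr.DataArray:
    """Vectorised zero-wetland mask (time, lat, lon); True = force zero.

    Expects ``soil_temp`` (time, layer, lat, lon) with ``layer_bounds``,
    ``freeze_days`` (time, lat, lon) and ``climate_class`` (lat, lon) in
    the forcing dataset.
    """
    bounds = np.asarray(forcing["layer_bounds"].values, dtype=float)
    st = forcing["soil_temp"].transpose("time", "lat", "lon", "layer").values
    st70 = st_at_70cm(st, bounds, method=st_method)
    frozen = st70 < 0.0
    many_freeze_days = forcing["freeze_days"].values > FREEZE_DAYS_LIMIT
    desert = (forcing["climate_class"].values == HOT_DESERT_CLASS)[None, :, :]
    mask = frozen | many_freeze_days | desert
    return xr.DataArray(
        mask,
        dims=("time", "lat", "lon"),
        coords={k: forcing.coords[k] for k in ("time", "lat", "lon")},
        name="zero_wetland_mask",
    )
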