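"""Seeded synthetic inputs: CTI subgrids, soil forcing, masks, truth observations.

The generator emulates the statistical shape of the real inputs — a
right-skewed subgrid CTI distribution per coarse cell, seasonal layered
soil-moisture cycles bounded by saturation, seasonal soil freezing in a
configurable fraction of cells, a hot-desert class fraction — and
produces ground-truth wetland observations by running the forward model
itself under a hidden per-cell parameterisation, so calibration can be
tested as an exact recovery problem.

All randomness flows from a single integer seed; identical configs give
bitwise-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr

from . import evaluation
from .core import CTIGrid, CTISubgrid, DEFAULT_GAMMA_GRID, empirical_curve, fit_sigmoid
from .calibration import params_to_dataset, CellParams, CellStatus
from .simulate import simulate_grid
from .wtd import saturation_deficit_grid, wet_mask_grid

__all__ = [
    "SynthConfig",
    "gen_cti_field",
    "gen_forcing",
    "gen_true_m",
    "gen_truth_obs",
]


@dataclass(frozen=True)
class SynthConfig:
    """Configuration of the synthetic world.

    Defaults describe a desk-scale study domain: a 10 x 10 cell grid at
    0.25 degrees, 2,500 pixels per cell, ten years of monthly forcing.
    The CTI law is a three-parameter (shifted) gamma distribution —
    right-skewed like observed topographic-index histograms.  Soil
    moisture follows theta_S * (baseline + amplitude * sin) per layer,
    clipped to [0, theta_S], with i.i.d. Gaussian noise per layer-month.
    """

    lat0: float = 40.0          # southern edge, degrees
    lon0: float = 0.0           # western edge, degrees
    n_lat: int = 10
    n_lon: int = 10
    resolution: float = 0.25    # degrees
    pixels_per_cell: int = 2500
    cti_loc: float = 2.0        # location of the shifted gamma law
    cti_shape: float = 3.0
    cti_scale: float = 1.5
    n_months: int = 120
    start: str = "2000-01"      # first month (YYYY-MM)
    layer_thicknesses: tuple = (0.1, 0.3, 0.6, 1.0)  # m, top-down
    theta_s: float = 0.45       # saturated volumetric water content
    sm_baseline: float = 0.75   # fraction of theta_s
    sm_amplitude: float = 0.18  # seasonal amplitude, fraction of theta_s
    sm_phase: float = 3.0       # months; peak moisture ~3 months after phase
    sm_noise: float = 0.02      # Gaussian sd, volumetric units
    freezing_fraction: float = 0.15
    desert_fraction: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.pixels_per_cell < 100:
            raise ValueError("pixels_per_cell must be at least 100")
        if self.n_months < 12:
            raise ValueError("need at least 12 months")
        if not 0 < self.theta_s <= 1:
            raise ValueError("theta_s must be in (0, 1]")
        if self.sm_noise < 0:
            raise ValueError("sm_noise must be non-negative")
        if self.resolution <= 0 or self.n_lat <= 0 or self.n_lon <= 0:
            raise ValueError("grid extent and resolution must be positive")
        if self.cti_shape <= 0 or self.cti_scale <= 0:
            raise ValueError("CTI shape and scale must be positive")
        if not 0 <= self.freezing_fraction + self.desert_fraction <= 1:
            raise ValueError("class fractions must sum to at most 1")

    @property
    def lat(self) -> np.ndarray:
        """Cell-center latitudes, ascending."""
        return self.lat0 + self.resolution * (np.arange(self.n_lat) + 0.5)

    @property
    def lon(self) -> np.ndarray:
        return self.lon0 + self.resolution * (np.arange(self.n_lon) + 0.5)

    @property
    def times(self) -> pd.DatetimeIndex:
        return pd.date_range(self.start, periods=self.n_months, freq="MS")

    @property
    def cti_mean(self) -> float:
        """Analytic mean of the shifted-gamma CTI law."""
        return self.cti_loc + self.cti_shape * self.cti_scale

    def rng(self, stream: int) -> np.random.Generator:
        """Independent generator per named stream, all derived from seed."""
        return np.random.default_rng(np.random.SeedSequence([self.seed, stream]))


_STREAM_CTI, _STREAM_FORCING, _STREAM_CLASSES, _STREAM_M = 1, 2, 3, 4


def gen_cti_field(config: SynthConfig) -> CTIGrid:
    """One CTI subgrid per cell, equal pixel areas summing to the cell area."""
    rng = config.rng(_STREAM_CTI)
    cells = {}
    res = config.resolution
    for i, lat_c in enumerate(config.lat):
        area = evaluation.cell_area((lat_c - res / 2, lat_c + res / 2), res)
        pixel_area = area / config.pixels_per_cell
        for j in range(config.n_lon):
            cti = config.cti_loc + rng.gamma(
                config.cti_shape, config.cti_scale, config.pixels_per_cell
            )
            cells[(i, j)] = CTISubgrid(
                row=i, col=j, cti=cti,
                areas=np.full(config.pixels_per_cell, pixel_area),
                total_area=area,
            )
    return CTIGrid(lat=config.lat, lon=config.lon, subgrids=cells)


def gen_classes(config: SynthConfig) -> xr.DataArray:
    """Koeppen-like class map: BWh deserts, Dfc freezing cells, Cfb rest."""
    rng = config.rng(_STREAM_CLASSES)
    n = config.n_lat * config.n_lon
    n_desert = int(round(config.desert_fraction * n))
    n_freeze = int(round(config.freezing_fraction * n))
    labels = np.array(["Cfb"] * n, dtype="U3")
    chosen = rng.choice(n, size=n_desert + n_freeze, replace=False)
    labels[chosen[:n_desert]] = "BWh"
    labels[chosen[n_desert:]] = "Dfc"
    return xr.DataArray(
        labels.reshape(config.n_lat, config.n_lon),
        dims=("lat", "lon"),
        coords={"lat": config.lat, "lon": config.lon},
        name="climate_class",
    )


def gen_forcing(config: SynthConfig) -> xr.Dataset:
    """Monthly layered soil moisture/temperature, freeze days, classes.

    theta_l(t) = clip(theta_S * (b + a * sin(2 pi (t - phase)/12)) + eps,
    0, theta_S) per layer.  Soil temperature follows a seasonal cycle that
    crosses 0 degC only in cells classed Dfc; monthly freezing-day counts
    are consistent with the top-layer temperature sign.
    """
    classes = gen_classes(config)
    rng = config.rng(_STREAM_FORCING)
    nt, nl = config.n_months, len(config.layer_thicknesses)
    nlat, nlon = config.n_lat, config.n_lon
    t = np.arange(nt, dtype=float)
    seasonal = np.sin(2 * np.pi * (t - config.sm_phase) / 12.0)

    base = config.theta_s * (
        config.sm_baseline + config.sm_amplitude * seasonal
    )[:, None, None, None]
    eps = rng.normal(0.0, config.sm_noise, size=(nt, nl, nlat, nlon)) \
        if config.sm_noise > 0 else np.zeros((nt, nl, nlat, nlon))
    theta = np.clip(base + eps, 0.0, config.theta_s)

    freezing = (classes.values == "Dfc")
    # seasonal temperature, phase-locked to moisture; freezing cells dip to
    # about -8 degC in winter, others bottom out near +4 degC
    t_mean = np.where(freezing, 2.0, 12.0)
    t_amp = np.where(freezing, 10.0, 8.0)
    st_cycle = -np.cos(2 * np.pi * (t - config.sm_phase) / 12.0)
    soil_temp = (
        t_mean[None, :, :] + t_amp[None, :, :] * st_cycle[:, None, None]
    )[:, None, :, :] * np.ones((1, nl, 1, 1))

    st_top = soil_temp[:, 0]
    freeze_days = np.where(
        st_top >= 0.0, 0,
        np.ceil(31.0 * np.clip(-st_top / 5.0, 0.0, 1.0)).astype(int),
    ).astype(np.int16)

    bounds = np.concatenate([[0.0], np.cumsum(config.layer_thicknesses)])
    ds = xr.Dataset(
        {
            "theta": (("time", "layer", "lat", "lon"), theta),
            "soil_temp": (("time", "layer", "lat", "lon"), soil_temp),
            "freeze_days": (("time", "lat", "lon"), freeze_days),
            "climate_class": classes,
        },
        coords={
            "time": config.times,
            "layer": np.arange(nl),
            "lat": config.lat,
            "lon": config.lon,
            "layer_bounds": ("layer_edge", bounds),
        },
        attrs={"theta_s": config.theta_s},
    )
    ds["theta"].attrs.update(units="m3 m-3", long_name="volumetric soil moisture")
    ds["soil_temp"].attrs.update(units="degC", long_name="soil temperature")
    ds["freeze_days"].attrs.update(units="days", long_name="soil freezing days")
    return ds


def gen_true_m(config: SynthConfig) -> xr.DataArray:
    """Hidden per-cell truth for the transmissivity-decay parameter M."""
    rng = config.rng(_STREAM_M)
    m = rng.integers(1, 16, size=(config.n_lat, config.n_lon)).astype(np.int32)
    return xr.DataArray(
        m, dims=("lat", "lon"),
        coords={"lat": config.lat, "lon": config.lon}, name="true_m",
    )


def gen_truth_obs(
    cti_field: CTIGrid,
    forcing: xr.Dataset,
    true_m_map: xr.DataArray,
    gamma_grid: np.ndarray | None = None,
) -> tuple[xr.DataArray, xr.DataArray]:
    """Ground-truth monthly observations from the forward model.

    Runs the unconstrained forward simulation (empirical curve at the true
    M, sigmoid reduction, mask rules) and returns ``(monthly, max)``: the
    monthly wetland-fraction field and its per-cell long-term maximum.
    """
    m_map = true_m_map.values
    if m_map.shape != cti_field.shape:
        raise ValueError("true_m_map does not match the CTI grid")
    if not np.all((m_map >= 1) & (m_map <= 15)):
        raise ValueError("true M values must be integers in [1, 15]")
    if gamma_grid is None:
        gamma_grid = DEFAULT_GAMMA_GRID

    params = {}
    for (i, j), sg in cti_field.items():
        curve = empirical_curve(sg, int(m_map[i, j]), gamma_grid)
        sp = fit_sigmoid(curve)
        params[(i, j)] = CellParams(
            m=int(m_map[i, j]), v=sp.v, k=sp.k, q=sp.q,
            f_max=1.0, cal_rmse=np.nan, status=CellStatus.CALIBRATED,
        )
    params_ds = params_to_dataset(params, cti_field.lat, cti_field.lon)
    gamma = saturation_deficit_grid(forcing)
    mask = wet_mask_grid(forcing)
    monthly = simulate_grid(params_ds, gamma, mask, apply_fmax=False)
    return monthly, monthly.max("time").rename("fwet_max")
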