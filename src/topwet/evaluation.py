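"""Validation metric suite: areas, RMSE maps, cycles, variability, correlations.

Regional wetland areas are totals of fraction times spherical cell area
(Earth radius 6371 km), reported in Mkm^2.  Interannual variability is
summarised by annual-statistic series (both annual maxima and annual
means are provided), their standard deviations and Pearson correlations
with two-sided t-test p-values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr
from scipy import stats

from .calibration import CalMode, reduce_series

__all__ = [
    "EARTH_RADIUS_KM",
    "RegionSpec",
    "cell_area",
    "cell_area_map",
    "area_series",
    "seasonal_cycle",
    "annual_stat_series",
    "iav_stats",
    "rmse_map",
    "month_of_max",
    "reference_correlation_map",
]

EARTH_RADIUS_KM = 6371.0

#: Cells whose observed maximum fraction is below this are flagged in maps.
DISPLAY_THRESHOLD = 0.01


@dataclass(frozen=True)
class RegionSpec:
    """A named latitude band (or explicit cell mask) for area aggregation."""

    name: str
    lat_min: float = -90.0
    lat_max: float = 90.0
    mask: xr.DataArray | None = None

    def __post_init__(self):
        if not (-90.0 <= self.lat_min < self.lat_max <= 90.0):
            raise ValueError("need -90 <= lat_min < lat_max <= 90")

    def select(self, lat: xr.DataArray) -> xr.DataArray:
        band = (lat >= self.lat_min) & (lat < self.lat_max)
        if self.mask is not None:
            band = band & self.mask
        return band


GLOBAL = RegionSpec("global")
#: The three standard latitude zones plus the globe.
STANDARD_REGIONS = (
    GLOBAL,
    RegionSpec("60S-30N", -60.0, 30.0),
    RegionSpec("30N-50N", 30.0, 50.0),
    RegionSpec("50N-90N", 50.0, 90.0),
)


def cell_area(lat_bounds, lon_width: float) -> float:
    """Spherical area of a lat/lon cell, km^2: R^2 dlambda (sin p2 - sin p1)."""
    phi1, phi2 = (np.radians(b) for b in lat_bounds)
    if phi2 < phi1:
        raise ValueError("inverted latitude bounds")
    return float(
        EARTH_RADIUS_KM**2 * np.radians(lon_width) * (np.sin(phi2) - np.sin(phi1))
    )


def cell_area_map(lat: np.ndarray, lon: np.ndarray, resolution: float) -> xr.DataArray:
    """Per-cell areas (km^2) of a regular grid given cell-center coords."""
    lat = np.asarray(lat, dtype=float)
    half = resolution / 2.0
    areas = np.array([cell_area((p - half, p + half), resolution) for p in lat])
    return xr.DataArray(
        np.broadcast_to(areas[:, None], (lat.size, len(lon))).copy(),
        dims=("lat", "lon"),
        coords={"lat": lat, "lon": np.asarray(lon, dtype=float)},
        name="cell_area",
        attrs={"units": "km2"},
    )


def area_series(
    field: xr.DataArray,
    region: RegionSpec = GLOBAL,
    resolution: float | None = None,
) -> pd.Series:
    """Total wetland area per month over a region, in Mkm^2.

    Fill values (NaN) are treated as zero contribution, with a coverage
    warning.  ``resolution`` defaults to the latitude spacing.
    """
    lat = field["lat"]
    if resolution is None:
        resolution = float(abs(lat.values[1] - lat.values[0])) if lat.size > 1 else 0.25
    sel = region.select(lat)
    if not bool(sel.any()):
        raise ValueError(f"region {region.name!r} selects no cells")
    areas = cell_area_map(lat.values, field["lon"].values, resolution)
    sub = field.where(sel)
    if bool(sub.isnull().any()) and bool(field.where(sel, drop=True).isnull().any()):
        warnings.warn("missing values treated as zero area", stacklevel=2)
    totals = (sub.fillna(0.0).where(sel, 0.0) * areas).sum(("lat", "lon")) / 1e6
    if "time" in field.dims:
        return pd.Series(
            totals.values, index=pd.DatetimeIndex(field["time"].values), name=region.name
        )
    return pd.Series([float(totals)], name=region.name)


def seasonal_cycle(series: pd.Series) -> pd.Series:
    """Calendar-month means (Jan..Dec) of a monthly series."""
    if series.size < 12:
        raise ValueError("need at least 12 months")
    cyc = series.groupby(series.index.month).mean()
    return cyc.reindex(range(1, 13))


def annual_stat_series(series: pd.Series, stat: str = "max") -> pd.Series:
    """Per-calendar-year maxima or means; partial years are dropped."""
    if stat not in ("max", "mean"):
        raise ValueError("stat must be 'max' or 'mean'")
    counts = series.groupby(series.index.year).count()
    full = counts[counts == 12].index
    if len(full) < len(counts):
        warnings.warn("partial calendar years excluded", stacklevel=2)
    grouped = series.groupby(series.index.year).agg(stat)
    return grouped.loc[full]


def iav_stats(a, b):
    """Pearson r, two-sided p, and the two sample SDs of yearly series.

    Zero-variance input yields NaN correlation and p (an undefined-
    correlation signal), never an exception.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size != b.size or a.size < 3:
        raise ValueError("need equal-length series with at least 3 points")
    sd_a = float(np.std(a, ddof=1))
    sd_b = float(np.std(b, ddof=1))
    if sd_a == 0.0 or sd_b == 0.0:
        return np.nan, np.nan, sd_a, sd_b
    r, p = stats.pearsonr(a, b)
    return float(r), float(p), sd_a, sd_b


def rmse_map(
    sim: xr.DataArray,
    obs: xr.DataArray,
    mode=CalMode.LONG_TERM_MAX,
) -> xr.Dataset:
    """Per-cell RMSE between mode-reduced simulated and observed series.

    Returns a dataset with ``rmse`` and a boolean ``below_threshold`` flag
    marking cells whose observed maximum fraction is under 1% (the
    convention for masking such cells out of displayed maps).
    """
    if sim["lat"].size != obs["lat"].size or sim["lon"].size != obs["lon"].size:
        raise ValueError("sim and obs grids differ")
    mode = CalMode(mode)

    def _reduce(f):
        if "time" not in f.dims:
            return f.values[None, :, :], None
        times = pd.DatetimeIndex(f["time"].values)
        arr = f.transpose("time", "lat", "lon").values
        nlat, nlon = arr.shape[1:]
        cols = arr.reshape(arr.shape[0], -1)
        red = np.stack(
            [reduce_series(cols[:, k], times, mode) for k in range(cols.shape[1])],
            axis=1,
        )
        return red.reshape(red.shape[0], nlat, nlon), times

    sim_red, _ = _reduce(sim)
    obs_red, _ = _reduce(obs)
    if sim_red.shape != obs_red.shape:
        raise ValueError("mode reduction lengths differ between sim and obs")
    err = np.sqrt(np.nanmean((obs_red - sim_red) ** 2, axis=0))
    obs_max = obs.max("time") if "time" in obs.dims else obs
    out = xr.Dataset(
        {
            "rmse": (("lat", "lon"), err),
            "below_threshold": obs_max < DISPLAY_THRESHOLD,
        },
        coords={"lat": sim["lat"], "lon": sim["lon"]},
    )
    return out


def month_of_max(field: xr.DataArray) -> xr.DataArray:
    """Calendar month (1-12) of the mean-seasonal-cycle maximum per cell.

    Ties go to the earliest month; all-zero (or all-NaN) cells are flagged
    with 0.
    """
    times = pd.DatetimeIndex(field["time"].values)
    if len(np.unique(times.year)) < 1 or times.size < 12:
        raise ValueError("need at least one full year")
    cyc = field.groupby("time.month").mean("time")
    cyc = cyc.reindex(month=range(1, 13))
    vals = cyc.transpose("month", "lat", "lon").values
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        best = np.nanargmax(np.nan_to_num(vals, nan=-1.0), axis=0) + 1
    undefined = np.all(np.nan_to_num(vals, nan=0.0) <= 0.0, axis=0)
    best = np.where(undefined, 0, best)
    return xr.DataArray(
        best.astype(np.int8),
        dims=("lat", "lon"),
        coords={"lat": field["lat"], "lon": field["lon"]},
        name="month_of_max",
        attrs={"flag_meanings": "0=undefined, 1..12=calendar month"},
    )


def reference_correlation_map(
    field: xr.DataArray,
    reference: xr.DataArray,
    alpha: tuple[float, ...] = (0.1, 0.05),
) -> xr.Dataset:
    """Per-cell Pearson correlation of monthly series against a reference.

    Both fields are aligned on their common time span, which must cover at
    least 24 months.  Returns ``r``, ``p`` and one boolean significance
    flag per requested level (``sig_10``, ``sig_05`` by default);
    zero-variance cells come out NaN/False.
    """
    common = np.intersect1d(field["time"].values, reference["time"].values)
    if common.size < 24:
        raise ValueError("need at least 24 overlapping months")
    x = field.sel(time=common).transpose("time", "lat", "lon").values
    y = reference.sel(time=common).transpose("time", "lat", "lon").values
    n = x.shape[0]

    xm = x - x.mean(axis=0)
    ym = y - y.mean(axis=0)
    sx = np.sqrt((xm**2).sum(axis=0))
    sy = np.sqrt((ym**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xm * ym).sum(axis=0) / (sx * sy)
        r = np.where((sx == 0) | (sy == 0), np.nan, np.clip(r, -1.0, 1.0))
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r**2, 1e-300))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.isnan(r), np.nan, p)

    data = {
        "r": (("lat", "lon"), r),
        "p": (("lat", "lon"), p),
    }
    for a in alpha:
        key = f"sig_{str(a).split('.')[1]:0<2}"
        data[key] = (("lat", "lon"), (p < a) & np.isfinite(p))
    return xr.Dataset(
        data, coords={"lat": field["lat"], "lon": field["lon"]},
        attrs={"n_months": int(n)},
    )
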