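"""NetCDF product I/O, regridding and the product naming convention.

Products are yearly NetCDF files named

    fwet_[wetland]_max_[sm]_reso025_[yyyy].nc

with dimensions (lon, lat, time) and a single variable ``fwet`` (wetland
fraction of the cell, in [0, 1], 32-bit float with a fill value).  Time
is stored as integer months since 1980-01 on a standard calendar;
longitudes live in [-180, 180) and latitudes are ascending.  Files are
written in the classic NetCDF3 format so payloads are bit-identical
across repeated runs.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr

__all__ = [
    "ProductName",
    "write_product",
    "read_product",
    "regrid",
]

_EPOCH = pd.Timestamp("1980-01-01")
_FILL = np.float32(1.0e20)
_NAME_RE = re.compile(
    r"^fwet_(?P<wetland>[^_]+)_max_(?P<sm>.+)_reso025_(?P<year>\d{4})\.nc$"
)


@dataclass(frozen=True)
class ProductName:
    """Label triple behind the product file naming convention."""

    wetland: str
    sm: str
    year: int

    def __post_init__(self):
        for label in (self.wetland, self.sm):
            if not label or "/" in label or "\\" in label:
                raise ValueError(f"invalid label {label!r}")
        if "_" in self.wetland:
            raise ValueError("wetland label must not contain underscores")
        if not 1000 <= int(self.year) <= 9999:
            raise ValueError("year must be a 4-digit integer")

    @property
    def filename(self) -> str:
        return f"fwet_{self.wetland}_max_{self.sm}_reso025_{self.year}.nc"

    @classmethod
    def parse(cls, filename: str) -> "ProductName":
        m = _NAME_RE.match(Path(filename).name)
        if m is None:
            raise ValueError(f"not a product filename: {filename!r}")
        return cls(wetland=m["wetland"], sm=m["sm"], year=int(m["year"]))


def months_since_epoch(times: pd.DatetimeIndex) -> np.ndarray:
    t = pd.DatetimeIndex(times)
    return ((t.year - _EPOCH.year) * 12 + (t.month - _EPOCH.month)).to_numpy(
        dtype=np.int32
    )


def months_to_datetime(months: np.ndarray) -> pd.DatetimeIndex:
    return pd.DatetimeIndex(
        [_EPOCH + pd.DateOffset(months=int(m)) for m in np.asarray(months)]
    )


def write_product(
    field: xr.DataArray,
    name: ProductName | tuple,
    out_dir,
    overwrite: bool = False,
) -> list[Path]:
    """Write a monthly wetland-fraction field as one NetCDF file per year.

    ``field`` has dims (time, lat, lon); its years are split into separate
    files named per convention (the ``year`` part of ``name`` is replaced
    per file).  Returns the written paths.
    """
    if not isinstance(name, ProductName):
        name = ProductName(*name)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    field = field.transpose("time", "lat", "lon")
    times = pd.DatetimeIndex(field["time"].values)
    paths = []
    for year in np.unique(times.year):
        sel = field.isel(time=times.year == year)
        pname = ProductName(name.wetland, name.sm, int(year))
        path = out_dir / pname.filename
        if path.exists() and not overwrite:
            raise FileExistsError(f"{path} exists (pass overwrite=True)")
        _write_one(sel, path)
        paths.append(path)
    return paths


def _write_one(field: xr.DataArray, path: Path) -> None:
    values = field.transpose("lon", "lat", "time").values.astype(np.float32)
    values = np.where(np.isnan(values), _FILL, values)
    ds = xr.Dataset(
        {"fwet": (("lon", "lat", "time"), values)},
        coords={
            "lon": ("lon", field["lon"].values.astype(np.float64)),
            "lat": ("lat", field["lat"].values.astype(np.float64)),
            "time": (
                "time",
                months_since_epoch(pd.DatetimeIndex(field["time"].values)),
            ),
        },
    )
    ds["fwet"].attrs = {
        "long_name": "wetland fraction",
        "units": "1",
        "valid_min": 0.0,
        "valid_max": 1.0,
    }
    ds["time"].attrs = {"units": "months since 1980-01-01", "calendar": "standard"}
    ds["lat"].attrs = {"units": "degrees_north"}
    ds["lon"].attrs = {"units": "degrees_east"}
    ds.to_netcdf(
        path,
        engine="scipy",
        format="NETCDF3_CLASSIC",
        encoding={"fwet": {"_FillValue": _FILL}},
    )


def read_product(path) -> xr.DataArray:
    """Read one product file back into a (time, lat, lon) fraction field.

    Tolerates either (lon, lat, time) or (lat, lon, time) layouts and
    canonicalises to (time, lat, lon) with ascending latitudes.  Validates
    the value range and the presence of the ``fwet`` variable.
    """
    try:
        with xr.open_dataset(path, decode_times=False) as raw:
            ds = raw.load()
    except ValueError:
        with xr.open_dataset(path, engine="scipy", decode_times=False) as raw:
            ds = raw.load()
    if "fwet" not in ds:
        raise ValueError(
            f"no 'fwet' variable in {path}; found {sorted(ds.data_vars)}"
        )
    for dim in ("time", "lat", "lon"):
        if dim not in ds.dims:
            raise ValueError(f"missing dimension {dim!r} in {path}")
    if ds.sizes["time"] == 0:
        raise ValueError(f"empty time dimension in {path}")
    fwet = ds["fwet"].transpose("time", "lat", "lon")
    fill = fwet.attrs.get("_FillValue", _FILL)
    vals = fwet.values.astype(np.float64)
    vals = np.where(np.isclose(vals, float(fill)) | (vals >= 1e19), np.nan, vals)
    finite = vals[np.isfinite(vals)]
    if finite.size and (finite.min() < -1e-6 or finite.max() > 1 + 1e-6):
        raise ValueError(f"fwet values outside [0, 1] in {path}")
    out = xr.DataArray(
        vals,
        dims=("time", "lat", "lon"),
        coords={
            "time": months_to_datetime(ds["time"].values),
            "lat": ds["lat"].values,
            "lon": ds["lon"].values,
        },
        name="fwet",
        attrs={k: v for k, v in fwet.attrs.items() if k != "_FillValue"},
    )
    if out["lat"].values[0] > out["lat"].values[-1]:
        out = out.isel(lat=slice(None, None, -1))
    return out


def read_products(paths) -> xr.DataArray:
    """Concatenate yearly product files along time."""
    fields = [read_product(p) for p in sorted(paths)]
    return xr.concat(fields, dim="time")


def _overlap_weights(src_edges: np.ndarray, dst_edges: np.ndarray) -> np.ndarray:
    """Overlap-length matrix between two 1-D edge sets (n_dst, n_src)."""
    lo = np.maximum(dst_edges[:-1, None], src_edges[None, :-1])
    hi = np.minimum(dst_edges[1:, None], src_edges[None, 1:])
    return np.clip(hi - lo, 0.0, None)


def _edges(centers: np.ndarray, resolution: float | None = None) -> np.ndarray:
    centers = np.asarray(centers, dtype=float)
    if resolution is not None:
        return np.concatenate(
            [centers - resolution / 2.0, [centers[-1] + resolution / 2.0]]
        )
    if centers.size == 1:
        raise ValueError(
            "cannot infer cell edges from a single coordinate; "
            "pass an explicit resolution"
        )
    step = np.diff(centers)
    edges = np.empty(centers.size + 1)
    edges[1:-1] = centers[:-1] + step / 2
    edges[0] = centers[0] - step[0] / 2
    edges[-1] = centers[-1] + step[-1] / 2
    return edges


def regrid(
    field: xr.DataArray,
    target_lat: np.ndarray,
    target_lon: np.ndarray,
    kind: str = "conservative",
    target_resolution: float | None = None,
) -> xr.DataArray:
    """Regrid a regular lat/lon field to a new regular grid.

    ``conservative`` computes the area-weighted mean of overlapping source
    cells (appropriate for fractions and soil moisture); ``nearest`` picks
    the nearest source cell (for categorical fields such as climate
    classes).  Spherical cell areas factorise into sin(lat) and lon terms,
    so the conservative weights are separable.
    """
    target_lat = np.asarray(target_lat, dtype=float)
    target_lon = np.asarray(target_lon, dtype=float)
    if kind == "nearest":
        return field.reindex(
            lat=target_lat, lon=target_lon, method="nearest"
        )
    if kind != "conservative":
        raise ValueError(f"unknown regrid kind {kind!r}")

    src_lat_e = np.sin(np.radians(_edges(field["lat"].values)))
    dst_lat_e = np.sin(np.radians(_edges(target_lat, target_resolution)))
    w_lat = _overlap_weights(src_lat_e, dst_lat_e)  # (n_dst_lat, n_src_lat)
    w_lon = _overlap_weights(
        _edges(field["lon"].values), _edges(target_lon, target_resolution)
    )
    if w_lat.sum() == 0 or w_lon.sum() == 0:
        raise ValueError("source and target domains do not overlap")

    field = field.transpose(..., "lat", "lon")
    vals = field.values
    good = np.isfinite(vals)
    num = np.einsum("ab,...bc,dc->...ad", w_lat, np.where(good, vals, 0.0), w_lon)
    den = np.einsum("ab,...bc,dc->...ad", w_lat, good.astype(float), w_lon)
    with np.errstate(invalid="ignore"):
        out = np.where(den > 0, num / den, np.nan)
    dims = field.dims[:-2] + ("lat", "lon")
    coords = {d: field.coords[d] for d in field.dims[:-2] if d in field.coords}
    coords.update(lat=target_lat, lon=target_lon)
    return xr.DataArray(out, dims=dims, coords=coords, name=field.name, attrs=field.attrs)
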