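"""Per-cell parameter calibration against observed wetland extent.

For each cell the transmissivity-decay parameter M is chosen from the
integers 1..15.  Each candidate M yields an empirical flooded-fraction
curve, its sigmoid reduction (v, k, q), and a simulated monthly series
psi(gamma(t)) with masked months zeroed.  The simulated series is reduced
to the calibration target statistic (long-term maximum by default) and
scored with the root-mean-square error; the M with minimal RMSE wins,
ties broken toward smaller M.  The per-cell cap ``f_max`` is the observed
long-term-maximum fraction of the calibration dataset.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd
import xarray as xr
from joblib import Parallel, delayed

from .core import (
    CTIGrid,
    CTISubgrid,
    DegenerateCurveError,
    SigmoidParams,
    empirical_curve,
    fit_sigmoid,
    psi,
)

__all__ = [
    "CalMode",
    "CalTarget",
    "CellStatus",
    "CellParams",
    "rmse",
    "reduce_series",
    "prepare_obs",
    "max_all",
    "calibrate_cell",
    "calibrate_grid",
    "params_to_dataset",
]

M_CANDIDATES = tuple(range(1, 16))


class CalMode(str, Enum):
    ALL_MONTHS = "all_months"
    SEASONAL_CYCLE = "seasonal_cycle"
    YEARLY_MAX = "yearly_max"
    LONG_TERM_MAX = "long_term_max"


class CellStatus(str, Enum):
    CALIBRATED = "calibrated"
    DEGENERATE = "degenerate"
    MASKED = "masked"

    @property
    def code(self) -> int:
        return {"calibrated": 0, "degenerate": 1, "masked": 2}[self.value]


@dataclass(frozen=True)
class CalTarget:
    """Observation statistic one cell is calibrated against."""

    mode: CalMode
    values: np.ndarray

    def __post_init__(self):
        vals = np.atleast_1d(np.asarray(self.values, dtype=float))
        finite = vals[np.isfinite(vals)]
        if finite.size and (finite.min() < -1e-9 or finite.max() > 1 + 1e-9):
            raise ValueError("target fractions must lie in [0, 1]")
        if CalMode(self.mode) is CalMode.LONG_TERM_MAX and vals.size != 1:
            raise ValueError("long_term_max target must be a single value")
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "mode", CalMode(self.mode))

    @property
    def n(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class CellParams:
    """Calibrated parameter set of one cell."""

    m: int
    v: float
    k: float
    q: float
    f_max: float
    cal_rmse: float
    status: CellStatus = CellStatus.CALIBRATED
    f_const: float = np.nan  # constant fallback for degenerate cells

    @property
    def sigmoid(self) -> SigmoidParams:
        return SigmoidParams(v=self.v, k=self.k, q=self.q)


def rmse(observed, simulated) -> float:
    """Root-mean-square error between two equal-length series."""
    o = np.atleast_1d(np.asarray(observed, dtype=float))
    p = np.atleast_1d(np.asarray(simulated, dtype=float))
    if o.shape != p.shape:
        raise ValueError(f"length mismatch: {o.shape} vs {p.shape}")
    if o.size < 1:
        raise ValueError("need at least one sample")
    return float(np.sqrt(np.nanmean((o - p) ** 2)))


def reduce_series(values: np.ndarray, times: pd.DatetimeIndex, mode) -> np.ndarray:
    """Reduce a monthly series to the calibration statistic.

    long_term_max -> single maximum; yearly_max -> one maximum per
    calendar year (chronological); seasonal_cycle -> 12 calendar-month
    means (Jan..Dec); all_months -> unchanged.
    """
    mode = CalMode(mode)
    values = np.asarray(values, dtype=float)
    if mode is CalMode.ALL_MONTHS:
        return values
    if mode is CalMode.LONG_TERM_MAX:
        return np.array([np.nanmax(values)])
    if times is None or len(times) != values.size:
        raise ValueError("time labels required for yearly/seasonal reductions")
    s = pd.Series(values, index=times)
    if mode is CalMode.YEARLY_MAX:
        return s.groupby(s.index.year).max().to_numpy()
    if mode is CalMode.SEASONAL_CYCLE:
        cyc = s.groupby(s.index.month).mean()
        return cyc.reindex(range(1, 13)).to_numpy()
    raise ValueError(f"unknown mode {mode}")  # pragma: no cover


def _as_fields(raw_obs) -> list[xr.DataArray]:
    if isinstance(raw_obs, (list, tuple)):
        return list(raw_obs)
    return [raw_obs]


def max_all(fields) -> xr.DataArray:
    """Per-cell union (element-wise maximum) of long-term-maximum maps."""
    maxima = [
        f.max("time") if "time" in f.dims else f for f in _as_fields(fields)
    ]
    out = maxima[0]
    for m in maxima[1:]:
        if m.shape != out.shape:
            raise ValueError("wetland fields must share the grid")
        out = np.maximum(out, m)
    return out.rename("fwet_max")


def prepare_obs(
    raw_obs,
    rice_fraction: xr.DataArray | None = None,
    mode=CalMode.LONG_TERM_MAX,
) -> tuple[xr.DataArray, xr.DataArray]:
    """Turn raw wetland observations into a calibration target and f_max map.

    Rice-paddy area is removed by subtract-and-clip,
    ``max(0, f_obs - f_rice)``.  ``raw_obs`` may be one monthly field, one
    static map, or a list of fields whose long-term maxima are combined by
    per-cell union (the multi-dataset MAX map).  Returns ``(target, fmax)``
    where ``target`` has a leading ``tstat`` dimension whose length depends
    on the mode, and ``fmax`` is the per-cell long-term maximum of the
    calibration data.
    """
    mode = CalMode(mode)
    fields = _as_fields(raw_obs)
    if rice_fraction is not None:
        fields = [
            (f - rice_fraction).clip(min=0.0, max=1.0).rename(f.name)
            for f in fields
        ]
    fmax = max_all(fields)

    if mode is CalMode.LONG_TERM_MAX:
        target = fmax.expand_dims(tstat=[0])
        return target, fmax

    if len(fields) != 1:
        raise ValueError("dynamic calibration modes need a single monthly field")
    f = fields[0]
    if "time" not in f.dims:
        raise ValueError(f"mode {mode.value} needs a monthly field")
    times = pd.DatetimeIndex(f["time"].values)
    if mode is CalMode.ALL_MONTHS:
        reduced = f.transpose("time", "lat", "lon").values
    elif mode is CalMode.YEARLY_MAX:
        reduced = f.groupby("time.year").max("time").transpose(
            "year", "lat", "lon"
        ).values
    elif mode is CalMode.SEASONAL_CYCLE:
        reduced = f.groupby("time.month").mean("time").transpose(
            "month", "lat", "lon"
        ).values
    target = xr.DataArray(
        reduced,
        dims=("tstat", "lat", "lon"),
        coords={"lat": f["lat"], "lon": f["lon"]},
        name="cal_target",
    )
    return target, fmax


_TRIVIAL = dict(v=1.0, k=-1.0, q=0.0)


def calibrate_cell(
    subgrid: CTISubgrid,
    gamma_series: np.ndarray,
    mask_series: np.ndarray,
    target: CalTarget,
    f_max: float | None = None,
    times: pd.DatetimeIndex | None = None,
    m_values=M_CANDIDATES,
    gamma_grid: np.ndarray | None = None,
) -> CellParams:
    """Choose M (and its fitted v, k, q) minimising the target RMSE.

    The simulated series scored here is the *unconstrained* sigmoid output
    (the f_max cap is applied only to final products; capping before
    scoring would make all M with max(psi) >= f_max indistinguishable).
    Masked months enter the simulated series as zeros.  An observed
    ``f_max`` of zero short-circuits to a masked cell whose simulated
    fraction is identically zero.
    """
    gamma_series = np.asarray(gamma_series, dtype=float)
    mask_series = np.asarray(mask_series, dtype=bool)
    if gamma_series.shape != mask_series.shape:
        raise ValueError("gamma and mask series must share their shape")
    if f_max is None:
        f_max = float(np.nanmax(target.values))

    if f_max <= 0.0:
        return CellParams(
            m=min(m_values), f_max=0.0, cal_rmse=0.0,
            status=CellStatus.MASKED, **_TRIVIAL,
        )

    best = None
    for m in m_values:
        curve = empirical_curve(subgrid, m, gamma_grid)
        try:
            sp = fit_sigmoid(curve)
        except DegenerateCurveError as err:
            sim = np.where(mask_series, 0.0, err.constant_value)
            sim = np.where(np.isnan(gamma_series), np.nan, sim)
            reduced = reduce_series(sim, times, target.mode)
            score = rmse(target.values, reduced)
            cand = (score, m, _TRIVIAL["v"], _TRIVIAL["k"], _TRIVIAL["q"],
                    True, err.constant_value)
        else:
            sim = psi(gamma_series, sp)
            sim = np.where(mask_series, 0.0, sim)
            reduced = reduce_series(sim, times, target.mode)
            score = rmse(target.values, reduced)
            cand = (score, m, sp.v, sp.k, sp.q, False, np.nan)
        # strict < keeps the smallest M on ties (ascending scan)
        if best is None or cand[0] < best[0]:
            best = cand

    score, m, v, k, q, is_degen, f_const = best
    status = CellStatus.DEGENERATE if is_degen else CellStatus.CALIBRATED
    return CellParams(
        m=int(m), v=v, k=k, q=q, f_max=float(f_max),
        cal_rmse=float(score), status=status, f_const=f_const,
    )


def _calibrate_one(key, subgrid, gamma, mask, tvals, fmax, mode, times, gamma_grid):
    target = CalTarget(mode=mode, values=tvals)
    params = calibrate_cell(
        subgrid, gamma, mask, target,
        f_max=fmax, times=times, gamma_grid=gamma_grid,
    )
    return key, params


def calibrate_grid(
    cti_grid: CTIGrid,
    gamma: xr.DataArray,
    mask: xr.DataArray,
    target: xr.DataArray,
    fmax: xr.DataArray,
    mode=CalMode.LONG_TERM_MAX,
    gamma_grid: np.ndarray | None = None,
    n_jobs: int | None = None,
) -> xr.Dataset:
    """Calibrate every cell independently; never aborts on a bad cell.

    ``target``/``fmax`` come from :func:`prepare_obs`; ``gamma`` and
    ``mask`` are (time, lat, lon) fields.  Returns the parameter map
    dataset (m, v, k, q, fmax, cal_rmse, status, f_const on lat/lon).
    """
    mode = CalMode(mode)
    gamma = gamma.transpose("time", "lat", "lon")
    mask = mask.transpose("time", "lat", "lon")
    if gamma.shape[1:] != cti_grid.shape:
        raise ValueError("gamma field does not match the CTI grid")
    times = pd.DatetimeIndex(gamma["time"].values)
    tvals = target.transpose("tstat", "lat", "lon").values
    fvals = fmax.values
    gvals = gamma.values
    mvals = mask.values

    jobs = [
        delayed(_calibrate_one)(
            key, sg, gvals[:, key[0], key[1]], mvals[:, key[0], key[1]],
            tvals[:, key[0], key[1]], float(fvals[key[0], key[1]]),
            mode, times, gamma_grid,
        )
        for key, sg in cti_grid.items()
    ]
    results = Parallel(n_jobs=n_jobs or 1)(jobs)
    return params_to_dataset(dict(results), cti_grid.lat, cti_grid.lon)


def params_to_dataset(params: dict, lat: np.ndarray, lon: np.ndarray) -> xr.Dataset:
    """Pack per-cell :class:`CellParams` into a gridded parameter map."""
    shape = (len(lat), len(lon))
    arrays = {
        name: np.full(shape, np.nan)
        for name in ("v", "k", "q", "fmax", "cal_rmse", "f_const")
    }
    m_arr = np.full(shape, -1, dtype=np.int32)
    status = np.full(shape, -1, dtype=np.int8)
    for (i, j), p in params.items():
        m_arr[i, j] = p.m
        status[i, j] = p.status.code
        arrays["v"][i, j] = p.v
        arrays["k"][i, j] = p.k
        arrays["q"][i, j] = p.q
        arrays["fmax"][i, j] = p.f_max
        arrays["cal_rmse"][i, j] = p.cal_rmse
        arrays["f_const"][i, j] = p.f_const
    data = {name: (("lat", "lon"), arr) for name, arr in arrays.items()}
    data["m"] = (("lat", "lon"), m_arr)
    data["status"] = (("lat", "lon"), status)
    ds = xr.Dataset(data, coords={"lat": lat, "lon": lon})
    ds["status"].attrs["flag_meanings"] = (
        "0=calibrated 1=degenerate 2=masked -1=missing"
    )
    return ds


def dataset_to_params(ds: xr.Dataset) -> dict[tuple[int, int], CellParams]:
    """Inverse of :func:`params_to_dataset` (missing cells skipped)."""
    out = {}
    codes = {0: CellStatus.CALIBRATED, 1: CellStatus.DEGENERATE, 2: CellStatus.MASKED}
    m = ds["m"].values
    for i in range(m.shape[0]):
        for j in range(m.shape[1]):
            if m[i, j] < 0:
                continue
            out[(i, j)] = CellParams(
                m=int(m[i, j]),
                v=float(ds["v"].values[i, j]),
                k=float(ds["k"].values[i, j]),
                q=float(ds["q"].values[i, j]),
                f_max=float(ds["fmax"].values[i, j]),
                cal_rmse=float(ds["cal_rmse"].values[i, j]),
                status=codes[int(ds["status"].values[i, j])],
                f_const=float(ds["f_const"].values[i, j]),
            )
    return out
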