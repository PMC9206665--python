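"""TOPMODEL subgrid flooding core.

The analytical heart of the diagnostic wetland model.  A coarse grid cell
holds a collection of fine pixels, each with a compound topographic index
(CTI, the log of the ratio of upslope contributing area to local slope).
Given a grid-mean water-table depth surrogate ``gamma`` (metres, positive
downward; a pixel floods when its local water table reaches the surface),
the fraction of the cell that is flooded is the area fraction of pixels
whose CTI exceeds a threshold

    cti_star = mean_cti + M * gamma

where ``M`` is an integer transmissivity-decay parameter (1..15).  Scanning
``gamma`` over a plausible range (-1 m to 2 m) produces an empirical
flooded-fraction curve per cell, which is then reduced to a cheap
three-parameter asymmetric sigmoid

    psi(gamma) = (1 + v * exp(-k * (gamma - q)))**(-1/v)

so that long monthly series can be simulated without touching the pixel
data again.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "CTISubgrid",
    "CTIGrid",
    "EmpiricalCurve",
    "SigmoidParams",
    "DegenerateCellError",
    "DegenerateCurveError",
    "SigmoidFitWarning",
    "DEFAULT_GAMMA_GRID",
    "cti_threshold",
    "flooded_fraction",
    "empirical_curve",
    "fit_sigmoid",
    "psi",
]

#: Water-table scan grid: 301 points, 0.01 m step, spanning -1 m .. 2 m.
DEFAULT_GAMMA_GRID = np.linspace(-1.0, 2.0, 301)

M_MIN, M_MAX = 1, 15

#: Flat-curve tolerance below which a sigmoid fit is meaningless.
FLAT_CURVE_TOL = 1e-6


class DegenerateCellError(ValueError):
    """Raised for cells with no usable pixels."""


class DegenerateCurveError(ValueError):
    """Raised when an empirical curve is flat (zero range of f)."""

    def __init__(self, constant_value: float):
        super().__init__(f"flat empirical curve (f == {constant_value:g} everywhere)")
        self.constant_value = float(constant_value)


class SigmoidFitWarning(UserWarning):
    """Emitted when the nonlinear fit falls back to interpolation."""


@dataclass(frozen=True)
class CTISubgrid:
    """Fine-pixel CTI values of one coarse cell.

    Parameters
    ----------
    row, col
        Cell indices on the coarse grid.
    cti
        Pixel topographic-index values (dimensionless).
    areas
        Pixel areas (km^2), all positive.
    total_area
        Total cell area A_x (km^2).  May exceed ``areas.sum()``: pixels
        removed as lakes/ice leave a gap that is treated as never flooded.
    """

    row: int
    col: int
    cti: np.ndarray
    areas: np.ndarray
    total_area: float

    def __post_init__(self):
        cti = np.asarray(self.cti, dtype=float)
        areas = np.asarray(self.areas, dtype=float)
        if cti.size == 0:
            raise DegenerateCellError(f"cell ({self.row},{self.col}) has no pixels")
        if cti.shape != areas.shape:
            raise ValueError("cti and areas must have matching shapes")
        if np.any(areas <= 0):
            raise ValueError("all pixel areas must be positive")
        if areas.sum() > self.total_area * (1 + 1e-9):
            raise ValueError("pixel areas exceed the total cell area")
        object.__setattr__(self, "cti", cti)
        object.__setattr__(self, "areas", areas)

    @property
    def n_pixels(self) -> int:
        return self.cti.size

    @property
    def mean_cti(self) -> float:
        """Area-weighted mean CTI of the cell."""
        return float(np.average(self.cti, weights=self.areas))


@dataclass(frozen=True)
class EmpiricalCurve:
    """Flooded fraction as a function of the water-table surrogate.

    ``f`` is non-increasing along ``gamma`` (a deeper water table floods
    fewer pixels) and lives in [0, 1].
    """

    gamma: np.ndarray
    f: np.ndarray
    m: int

    def __post_init__(self):
        object.__setattr__(self, "gamma", np.asarray(self.gamma, dtype=float))
        object.__setattr__(self, "f", np.asarray(self.f, dtype=float))

    @property
    def f_range(self) -> float:
        return float(self.f.max() - self.f.min())


@dataclass(frozen=True)
class SigmoidParams:
    """Parameters of the asymmetric sigmoid psi(gamma).

    ``v`` is dimensionless and strictly positive (it appears as the
    exponent -1/v), ``k`` has units 1/m and is unconstrained in sign
    (negative for curves that dry out with depth), ``q`` is in metres.
    """

    v: float
    k: float
    q: float
    fit_rmse: float = field(default=np.nan)

    def __post_init__(self):
        if not self.v > 0:
            raise ValueError(f"v must be positive, got {self.v}")

    def __call__(self, gamma):
        return psi(gamma, self)


class CTIGrid:
    """Collection of :class:`CTISubgrid` cells on a regular lat/lon grid.

    Cells are keyed by (row, col) = (lat index, lon index) with latitudes
    ascending.  Serialises to a ragged NetCDF layout: one flat pixel
    dimension with per-cell index pointers.
    """

    def __init__(self, lat: np.ndarray, lon: np.ndarray, subgrids):
        self.lat = np.asarray(lat, dtype=float)
        self.lon = np.asarray(lon, dtype=float)
        self._cells: dict[tuple[int, int], CTISubgrid] = dict(subgrids)
        for (i, j) in self._cells:
            if not (0 <= i < self.lat.size and 0 <= j < self.lon.size):
                raise ValueError(f"cell index ({i},{j}) outside the grid")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.lat.size, self.lon.size)

    def __len__(self) -> int:
        return len(self._cells)

    def __contains__(self, key) -> bool:
        return key in self._cells

    def cell(self, row: int, col: int) -> CTISubgrid:
        return self._cells[(row, col)]

    def items(self):
        """Iterate ((row, col), subgrid) in row-major order."""
        return iter(sorted(self._cells.items()))

    def to_dataset(self):
        """Ragged-layout dataset: pixel values + per-cell index pointers."""
        import xarray as xr

        keys = sorted(self._cells)
        nlat, nlon = self.shape
        ptr = np.zeros(nlat * nlon + 1, dtype=np.int64)
        total_area = np.full((nlat, nlon), np.nan)
        counts = np.zeros(nlat * nlon, dtype=np.int64)
        for (i, j) in keys:
            sg = self._cells[(i, j)]
            counts[i * nlon + j] = sg.n_pixels
            total_area[i, j] = sg.total_area
        ptr[1:] = np.cumsum(counts)
        flat_values = np.empty(ptr[-1])
        flat_areas = np.empty(ptr[-1])
        for (i, j) in keys:
            sg = self._cells[(i, j)]
            k = i * nlon + j
            flat_values[ptr[k]:ptr[k + 1]] = sg.cti
            flat_areas[ptr[k]:ptr[k + 1]] = sg.areas
        return xr.Dataset(
            {
                "cti_values": ("pixel", flat_values),
                "pixel_areas": ("pixel", flat_areas),
                "cell_ptr": ("cell_edge", ptr),
                "cell_total_area": (("lat", "lon"), total_area),
            },
            coords={"lat": self.lat, "lon": self.lon},
            attrs={"layout": "ragged row-major (lat, lon) with index pointers"},
        )

    @classmethod
    def from_dataset(cls, ds) -> "CTIGrid":
        lat = np.asarray(ds["lat"].values, dtype=float)
        lon = np.asarray(ds["lon"].values, dtype=float)
        ptr = np.asarray(ds["cell_ptr"].values, dtype=np.int64)
        values = np.asarray(ds["cti_values"].values, dtype=float)
        areas = np.asarray(ds["pixel_areas"].values, dtype=float)
        total_area = np.asarray(ds["cell_total_area"].values, dtype=float)
        nlon = lon.size
        cells = {}
        for k in range(lat.size * nlon):
            if ptr[k + 1] > ptr[k]:
                i, j = divmod(k, nlon)
                cells[(i, j)] = CTISubgrid(
                    row=i,
                    col=j,
                    cti=values[ptr[k]:ptr[k + 1]],
                    areas=areas[ptr[k]:ptr[k + 1]],
                    total_area=float(total_area[i, j]),
                )
        return cls(lat=lat, lon=lon, subgrids=cells)

    def to_netcdf(self, path) -> None:
        self.to_dataset().to_netcdf(path, engine="scipy")

    @classmethod
    def from_netcdf(cls, path) -> "CTIGrid":
        import xarray as xr

        with xr.open_dataset(path, engine="scipy") as ds:
            return cls.from_dataset(ds.load())


def cti_threshold(mean_cti: float, m: int, gamma_mean: float) -> float:
    """Threshold CTI above which a pixel is flooded.

    Derived from the linear subgrid redistribution of the water table:
    pixel i floods when its local water table reaches the surface, which
    happens for CTI_i >= mean_cti + m * gamma_mean.
    """
    return mean_cti + m * gamma_mean


def flooded_fraction(subgrid: CTISubgrid, cti_star) -> float | np.ndarray:
    """Area fraction of pixels with CTI >= ``cti_star``.

    Normalised by the full cell area ``total_area``; any area gap from
    removed lake/ice pixels counts as never flooded.  Accepts a scalar or
    an array of thresholds.
    """
    cti_star = np.asarray(cti_star, dtype=float)
    order = np.argsort(subgrid.cti)
    cti_sorted = subgrid.cti[order]
    # cumulative area of pixels with CTI >= value, from the dry end
    tail_area = np.concatenate(
        [np.cumsum(subgrid.areas[order][::-1])[::-1], [0.0]]
    )
    idx = np.searchsorted(cti_sorted, cti_star, side="left")
    frac = tail_area[idx] / subgrid.total_area
    if cti_star.ndim == 0:
        return float(frac)
    return frac


def empirical_curve(
    subgrid: CTISubgrid, m: int, gamma_grid: np.ndarray | None = None
) -> EmpiricalCurve:
    """Scan the water-table surrogate and record the flooded fraction.

    ``gamma_grid`` must be sorted ascending; defaults to the 301-point
    grid over [-1 m, 2 m].
    """
    if not (M_MIN <= m <= M_MAX):
        raise ValueError(f"M must be in [{M_MIN}, {M_MAX}], got {m}")
    if gamma_grid is None:
        gamma_grid = DEFAULT_GAMMA_GRID
    gamma_grid = np.asarray(gamma_grid, dtype=float)
    if np.any(np.diff(gamma_grid) <= 0):
        raise ValueError("gamma_grid must be strictly increasing")
    thresholds = cti_threshold(subgrid.mean_cti, m, gamma_grid)
    f = flooded_fraction(subgrid, thresholds)
    return EmpiricalCurve(gamma=gamma_grid, f=f, m=int(m))


def psi(gamma, params: SigmoidParams) -> np.ndarray | float:
    """Evaluate the asymmetric sigmoid, numerically safe.

    Computed in log space, ``psi = exp(-logaddexp(0, log v - k (g - q)) / v)``,
    which keeps the result in (0, 1) for any argument without overflow.
    """
    return _psi_raw(np.asarray(gamma, dtype=float), params.v, params.k, params.q)


def _psi_raw(gamma, v, k, q):
    with np.errstate(invalid="ignore"):  # NaN forcing passes through
        t = np.log(v) - k * (gamma - q)
        out = np.exp(-np.logaddexp(0.0, t) / v)
    if np.ndim(gamma) == 0:
        return float(out)
    return out


def _fit_residuals(p, gamma, f):
    v, k, q = p
    return _psi_raw(gamma, v, k, q) - f


def fit_sigmoid(curve: EmpiricalCurve, max_nfev: int = 2000) -> SigmoidParams:
    """Least-squares reduction of an empirical curve to sigmoid parameters.

    The sigmoid is ill-conditioned in ``v``, so the bounded fit is
    multi-started over v in {0.5, 1, 2, 5, 10}, with ``q`` initialised at
    the half-maximum crossing and ``k`` from the finite-difference slope
    there.  Raises :class:`DegenerateCurveError` for flat curves (the
    caller substitutes a constant function); emits
    :class:`SigmoidFitWarning` if no start converges below an RMSE of
    0.2 (a fit that poor indicates a pathological curve).
    """
    gamma = curve.gamma
    f = curve.f
    if gamma.size < 10:
        raise ValueError("need at least 10 curve points to fit")
    if curve.f_range < FLAT_CURVE_TOL:
        raise DegenerateCurveError(float(f.mean()))

    f_lo, f_hi = float(f.min()), float(f.max())
    half = 0.5 * (f_lo + f_hi)
    i_half = int(np.argmin(np.abs(f - half)))
    q0 = float(gamma[i_half])
    # local slope df/dgamma at the knee; for the logistic (v=1) the slope
    # at the midpoint is k/4
    i0, i1 = max(i_half - 5, 0), min(i_half + 5, gamma.size - 1)
    slope = (f[i1] - f[i0]) / (gamma[i1] - gamma[i0])
    k0 = float(np.clip(4.0 * slope, -500.0, 500.0))
    if k0 == 0.0:
        k0 = -1.0

    lower = np.array([1e-3, -1e4, -10.0])
    upper = np.array([1e3, 1e4, 10.0])
    best = None
    for v0 in (0.5, 1.0, 2.0, 5.0, 10.0):
        x0 = np.clip(np.array([v0, k0, q0]), lower, upper)
        try:
            res = least_squares(
                _fit_residuals,
                x0,
                bounds=(lower, upper),
                args=(gamma, f),
                max_nfev=max_nfev,
            )
        except Exception:  # pragma: no cover - scipy internal failure
            continue
        if best is None or res.cost < best.cost:
            best = res

    if best is None:  # pragma: no cover - all starts crashed
        warnings.warn(
            "sigmoid fit failed for all starts; falling back to interpolation",
            SigmoidFitWarning,
        )
        raise DegenerateCurveError(float(f.mean()))

    v, k, q = best.x
    rmse = float(np.sqrt(2.0 * best.cost / gamma.size))
    if rmse > 0.2:
        warnings.warn(
            f"sigmoid fit converged poorly (rmse={rmse:.3f})", SigmoidFitWarning
        )
    return SigmoidParams(v=float(v), k=float(k), q=float(q), fit_rmse=rmse)
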