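"""Gridded data model: monthly stacks, static maps, pixel masks, NetCDF I/O.

All analysis modules operate on these containers. Conventions:

* cell-center registration; latitude descending (north at index 0) is the
  writer default, but any declared uniform axis is accepted;
* time is a contiguous sequence of calendar months, held as a pandas
  ``PeriodIndex`` with monthly frequency;
* missing cells are NaN in the value array; ``missing_mask`` exposes the
  boolean view.  NetCDF files use an explicit ``_FillValue``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import xarray as xr

__all__ = [
    "GridAxes",
    "MonthlyRaster",
    "StaticMap",
    "PixelMask",
    "read_monthly_stack",
    "write_monthly_stack",
    "read_static_map",
    "write_static_map",
    "aggregate_to_grid",
    "combine_masks",
    "GridFormatError",
    "GeometryError",
    "UnitError",
]

FILL_VALUE = -9999.0

#: canonical units per recognised monthly variable
VARIABLE_UNITS: Mapping[str, str] = {
    "ndvi": "1",
    "precip_mm": "mm",
    "temp_C": "degC",
    "radiation_MJ_m2_d": "MJ m-2 d-1",
    "wet_days": "1",
    "sunshine_h": "h",
}

STATIC_KINDS = (
    "elevation_m",
    "cti",
    "sbd_g_cm3",
    "pawc_mm",
    "landcover_class",
    "ecoregion_id",
    "ecozone_id",
    "builtup_flag",
)

_CATEGORICAL_KINDS = {"landcover_class", "ecoregion_id", "ecozone_id", "builtup_flag"}


class GridFormatError(ValueError):
    """Malformed file or time axis."""


class GeometryError(ValueError):
    """Axis/shape mismatch between grids."""


class UnitError(ValueError):
    """Declared variable does not match units found in a file."""


def _check_uniform(axis: np.ndarray, name: str) -> float:
    if axis.ndim != 1 or axis.size < 1:
        raise GeometryError(f"{name} axis must be 1-D and non-empty")
    if axis.size == 1:
        return 0.0
    steps = np.diff(axis)
    if np.any(np.abs(steps - steps[0]) > 1e-9):
        raise GeometryError(f"{name} axis spacing is not uniform")
    return float(steps[0])


@dataclass(frozen=True)
class GridAxes:
    """Uniform lat/lon cell-center axes (degrees)."""

    lat: np.ndarray
    lon: np.ndarray
    cell_size: float = 0.5

    def __post_init__(self) -> None:
        object.__setattr__(self, "lat", np.asarray(self.lat, dtype=float))
        object.__setattr__(self, "lon", np.asarray(self.lon, dtype=float))
        dlat = _check_uniform(self.lat, "lat")
        dlon = _check_uniform(self.lon, "lon")
        for d, name in ((dlat, "lat"), (dlon, "lon")):
            if d and abs(abs(d) - self.cell_size) > 1e-9:
                raise GeometryError(f"{name} spacing {abs(d)} != cell_size {self.cell_size}")
        if self.lat.min() < -90 or self.lat.max() > 90:
            raise GeometryError("latitudes outside [-90, 90]")
        if self.lon.min() < -180 or self.lon.max() >= 360:
            raise GeometryError("longitudes outside [-180, 360)")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.lat.size, self.lon.size)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GridAxes):
            return NotImplemented
        return (
            self.lat.shape == other.lat.shape
            and self.lon.shape == other.lon.shape
            and np.allclose(self.lat, other.lat, atol=1e-9)
            and np.allclose(self.lon, other.lon, atol=1e-9)
        )

    @classmethod
    def regular(cls, n_lat: int, n_lon: int, cell_size: float = 0.5,
                lat0: float = 50.0, lon0: float = 80.0) -> "GridAxes":
        """Build a north-at-top grid starting at (lat0, lon0) cell centers."""
        lat = lat0 - cell_size * np.arange(n_lat)
        lon = lon0 + cell_size * np.arange(n_lon)
        return cls(lat, lon, cell_size)


def _monthly_periods(times: Sequence) -> pd.PeriodIndex:
    """Accept (year, month) pairs or a PeriodIndex; enforce contiguity."""
    if isinstance(times, pd.PeriodIndex):
        idx = times.asfreq("M")
    else:
        idx = pd.PeriodIndex([pd.Period(year=y, month=m, freq="M") for y, m in times])
    if len(idx) == 0:
        raise GridFormatError("empty time axis")
    expected = pd.period_range(idx[0], periods=len(idx), freq="M")
    if not idx.equals(expected):
        raise GridFormatError("time axis has gaps, repeats or is unsorted")
    return idx


def _validate_monthly_values(variable: str, values: np.ndarray, times: pd.PeriodIndex) -> None:
    finite = np.isfinite(values)
    if variable == "ndvi":
        bad = finite & ((values < -1) | (values > 1))
        if bad.any():
            raise ValueError("NDVI outside [-1, 1]")
    elif variable == "precip_mm":
        if (finite & (values < 0)).any():
            raise ValueError("negative precipitation")
    elif variable == "wet_days":
        dim = np.array([p.days_in_month for p in times])[:, None, None]
        if (finite & ((values < 0) | (values > dim))).any():
            raise ValueError("wet_days outside [0, days-in-month]")


@dataclass
class MonthlyRaster:
    """One variable on a (time, lat, lon) monthly grid; NaN marks missing."""

    axes: GridAxes
    times: pd.PeriodIndex
    values: np.ndarray
    variable: str
    units: str = ""

    #: subclasses representing anomalies relax physical range checks
    _check_ranges = True

    def __post_init__(self) -> None:
        self.times = _monthly_periods(self.times)
        self.values = np.asarray(self.values, dtype=float)
        if self.variable not in VARIABLE_UNITS:
            raise ValueError(f"unknown variable {self.variable!r}")
        if not self.units:
            self.units = VARIABLE_UNITS[self.variable]
        expected = (len(self.times),) + self.axes.shape
        if self.values.shape != expected:
            raise GeometryError(f"values shape {self.values.shape} != {expected}")
        if self._check_ranges:
            _validate_monthly_values(self.variable, self.values, self.times)

    @property
    def missing_mask(self) -> np.ndarray:
        return ~np.isfinite(self.values)

    @property
    def years(self) -> np.ndarray:
        return np.asarray(self.times.year)

    @property
    def months(self) -> np.ndarray:
        return np.asarray(self.times.month)

    def select_years(self, start: int, end: int) -> "MonthlyRaster":
        keep = (self.years >= start) & (self.years <= end)
        return type(self)(self.axes, self.times[keep], self.values[keep],
                          self.variable, self.units)

    def to_dataset(self) -> xr.Dataset:
        time = self.times.to_timestamp()
        da = xr.DataArray(
            self.values,
            dims=("time", "lat", "lon"),
            coords={"time": time, "lat": self.axes.lat, "lon": self.axes.lon},
            name=self.variable,
            attrs={"units": self.units},
        )
        ds = da.to_dataset()
        ds.attrs["Conventions"] = "CF-1.8"
        ds.attrs["cell_size_deg"] = self.axes.cell_size
        ds.attrs["registration"] = "cell-center"
        ds["lat"].attrs.update(units="degrees_north", standard_name="latitude")
        ds["lon"].attrs.update(units="degrees_east", standard_name="longitude")
        return ds


class AnomalyRaster(MonthlyRaster):
    """Deviation from a per-calendar-month climatology; same layout as
    :class:`MonthlyRaster` but physical range checks do not apply."""

    _check_ranges = False


@dataclass
class StaticMap:
    """Single static (lat, lon) field, real-valued or categorical."""

    axes: GridAxes
    values: np.ndarray
    kind: str
    code_table: dict | None = None

    def __post_init__(self) -> None:
        if self.kind not in STATIC_KINDS:
            raise ValueError(f"unknown static kind {self.kind!r}")
        self.values = np.asarray(self.values)
        if self.values.shape != self.axes.shape:
            raise GeometryError("static map shape mismatch")
        if self.kind in _CATEGORICAL_KINDS:
            finite = self.values[np.isfinite(self.values.astype(float))]
            if finite.size and not np.allclose(finite, np.round(finite.astype(float))):
                raise ValueError(f"{self.kind} requires integer codes")

    @property
    def is_categorical(self) -> bool:
        return self.kind in _CATEGORICAL_KINDS


@dataclass
class PixelMask:
    """Boolean validity per pixel (True = analysed)."""

    axes: GridAxes
    valid: np.ndarray

    def __post_init__(self) -> None:
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.valid.shape != self.axes.shape:
            raise GeometryError("mask shape mismatch")

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())


# ---------------------------------------------------------------------------
# NetCDF I/O (scipy backend, NetCDF3 classic)
# ---------------------------------------------------------------------------

def write_monthly_stack(raster: MonthlyRaster, path) -> None:
    """Write a CF-style NetCDF file with (time, lat, lon) dims."""
    ds = raster.to_dataset()
    enc = {raster.variable: {"_FillValue": FILL_VALUE}}
    ds.to_netcdf(path, engine="scipy", encoding=enc)


def read_monthly_stack(path, variable: str) -> MonthlyRaster:
    """Read a monthly stack written by :func:`write_monthly_stack`.

    Raises :class:`GridFormatError` for a broken time axis and
    :class:`UnitError` if the file's units contradict the declared variable.
    """
    with xr.open_dataset(path, engine="scipy") as ds:
        ds = ds.load()
    if variable not in ds:
        raise GridFormatError(f"variable {variable!r} not in {path}")
    da = ds[variable]
    units = da.attrs.get("units", "")
    expected_units = VARIABLE_UNITS.get(variable)
    if units and expected_units and units != expected_units:
        raise UnitError(f"units {units!r} do not match variable {variable!r}")
    time = pd.DatetimeIndex(da["time"].values)
    periods = pd.PeriodIndex(time, freq="M")
    expected = pd.period_range(periods[0], periods=len(periods), freq="M")
    if not periods.equals(expected):
        raise GridFormatError("file time axis is not contiguous monthly")
    cell = float(ds.attrs.get("cell_size_deg", _infer_cell(da)))
    axes = GridAxes(da["lat"].values, da["lon"].values, cell)
    values = da.values.astype(float)
    values[values == FILL_VALUE] = np.nan
    return MonthlyRaster(axes, periods, values, variable, expected_units or units)


def _infer_cell(da: xr.DataArray) -> float:
    lat = da["lat"].values
    lon = da["lon"].values
    for ax in (lat, lon):
        if ax.size > 1:
            return float(abs(ax[1] - ax[0]))
    return 0.5


def write_static_map(smap: StaticMap, path) -> None:
    da = xr.DataArray(
        np.asarray(smap.values, dtype=float),
        dims=("lat", "lon"),
        coords={"lat": smap.axes.lat, "lon": smap.axes.lon},
        name=smap.kind,
    )
    ds = da.to_dataset()
    ds.attrs["cell_size_deg"] = smap.axes.cell_size
    if smap.code_table:
        ds.attrs["code_table"] = repr(sorted(smap.code_table.items()))
    ds.to_netcdf(path, engine="scipy", encoding={smap.kind: {"_FillValue": FILL_VALUE}})


def read_static_map(path, kind: str) -> StaticMap:
    with xr.open_dataset(path, engine="scipy") as ds:
        ds = ds.load()
    if kind not in ds:
        raise GridFormatError(f"kind {kind!r} not in {path}")
    da = ds[kind]
    cell = float(ds.attrs.get("cell_size_deg", _infer_cell(da)))
    axes = GridAxes(da["lat"].values, da["lon"].values, cell)
    values = da.values.astype(float)
    values[values == FILL_VALUE] = np.nan
    if kind in _CATEGORICAL_KINDS:
        out = np.full(values.shape, -1, dtype=int)
        finite = np.isfinite(values)
        out[finite] = np.round(values[finite]).astype(int)
        values = out
    return StaticMap(axes, values, kind)


# ---------------------------------------------------------------------------
# Grid operations
# ---------------------------------------------------------------------------

def aggregate_to_grid(fine: MonthlyRaster, target: GridAxes,
                      method: str = "mean") -> MonthlyRaster:
    """Block-aggregate a finer grid onto ``target``.

    For ``method='mean'`` the fine cell size must divide the target cell
    size; missing cells are ignored and an output cell is missing iff all
    contributing cells are missing.  ``method='nearest'`` picks the fine
    cell containing each target cell center.
    """
    ratio = target.cell_size / fine.axes.cell_size
    factor = int(round(ratio))
    if method == "mean" and abs(ratio - factor) > 1e-9:
        raise GeometryError("fine cell size does not divide target cell size")
    nlat, nlon = target.shape
    t = len(fine.times)
    if method == "mean":
        need = (nlat * factor, nlon * factor)
        if fine.axes.shape != need:
            raise GeometryError(f"fine grid shape {fine.axes.shape} != {need}")
        blocks = fine.values.reshape(t, nlat, factor, nlon, factor)
        import warnings
        with np.errstate(invalid="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN blocks
            out = np.nanmean(blocks, axis=(2, 4))
    elif method == "nearest":
        li = np.abs(target.lat[:, None] - fine.axes.lat[None, :]).argmin(axis=1)
        lj = np.abs(target.lon[:, None] - fine.axes.lon[None, :]).argmin(axis=1)
        out = fine.values[:, li][:, :, lj]
    else:
        raise ValueError(f"unknown method {method!r}")
    return type(fine)(target, fine.times, out, fine.variable, fine.units)


def combine_masks(masks: Iterable[PixelMask]) -> PixelMask:
    """Logical AND of validity across masks sharing one grid."""
    masks = list(masks)
    if not masks:
        raise ValueError("no masks given")
    axes = masks[0].axes
    valid = np.ones(axes.shape, dtype=bool)
    for m in masks:
        if m.axes != axes:
            raise GeometryError("mask axes differ")
        valid &= m.valid
    return PixelMask(axes, valid)
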