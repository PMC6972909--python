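"""Seasonal modes of the precipitation-vegetation relationship.

For each growing-season season (spring Apr-May, summer Jun-Aug, autumn
Sep-Oct) the seasonal NDVI anomaly is partially correlated (controlling
temperature and radiation over the same window) with precipitation
anomalies at four temporal configurations:

* ``Ra0``      — same season;
* ``Ra-1``     — previous season;
* ``Ra(-1,0)`` — previous season through current season (two-season sum);
* ``Ra(-2,-1)``— the two seasons before the current one.

Season arithmetic runs winter (Nov-Mar, labelled by its Jan-Mar year) ->
spring -> summer -> autumn, so spring's previous season is winter (reaching
Nov-Dec of the prior year) and its previous two seasons are the prior
year's autumn and winter.  Seasonal NDVI averages its months' anomalies;
precipitation sums anomalies over the window; control variables average
over the precipitation window.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import xarray as xr

from . import stats
from .grids import GeometryError, MonthlyRaster, PixelMask

__all__ = ["MODES", "SEASON_CHAIN", "seasonal_window", "seasonal_series",
           "SeasonalResponseModel", "SeasonalResponseResults"]

MODES = ("Ra0", "Ra-1", "Ra(-1,0)", "Ra(-2,-1)")
NDVI_SEASONS = ("spring", "summer", "autumn")

#: months of each season as (month, year_offset) pairs relative to the label year
_SEASON_MONTHS: dict[str, tuple[tuple[int, int], ...]] = {
    "winter": ((11, -1), (12, -1), (1, 0), (2, 0), (3, 0)),
    "spring": ((4, 0), (5, 0)),
    "summer": ((6, 0), (7, 0), (8, 0)),
    "autumn": ((9, 0), (10, 0)),
}

SEASON_CHAIN = ("winter", "spring", "summer", "autumn")


def _previous(season: str, steps: int) -> tuple[str, int]:
    """Season ``steps`` back in the chain, with the year offset it incurs."""
    i = SEASON_CHAIN.index(season)
    j = i - steps
    return SEASON_CHAIN[j % 4], -((-j + 3) // 4) if j < 0 else 0


def seasonal_window(season: str, mode: str) -> tuple[tuple[int, int], ...]:
    """(month, year_offset) pairs of the precipitation window for a mode."""
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}")
    steps = {"Ra0": (0,), "Ra-1": (1,), "Ra(-1,0)": (1, 0), "Ra(-2,-1)": (2, 1)}[mode]
    window: list[tuple[int, int]] = []
    for s in steps:
        name, yoff = _previous(season, s)
        window.extend((m, off + yoff) for m, off in _SEASON_MONTHS[name])
    return tuple(window)


def seasonal_series(stack: MonthlyRaster, season: str, mode: str,
                    years: Sequence[int], statistic: str = "sum") -> np.ndarray:
    """Per-year values over the mode's window: shape (n_years, nlat, nlon).

    ``statistic='sum'`` for precipitation anomalies, ``'mean'`` for NDVI and
    the control variables.  Years whose window months are not in the stack
    come out as NaN.
    """
    window = seasonal_window(season, mode)
    index = {(y, m): i for i, (y, m) in enumerate(zip(stack.years, stack.months))}
    out = np.full((len(years),) + stack.axes.shape, np.nan)
    for yi, year in enumerate(years):
        rows = []
        ok = True
        for m, off in window:
            key = (year + off, m)
            if key not in index:
                ok = False
                break
            rows.append(index[key])
        if not ok:
            continue
        vals = stack.values[rows]
        out[yi] = vals.sum(axis=0) if statistic == "sum" else vals.mean(axis=0)
    return out


class SeasonalResponseModel:
    """Second-order partial correlation per (season, mode) pair.

    Built from monthly *anomaly* stacks; seasonal aggregation happens
    internally (the sum/mean of monthly anomalies equals the anomaly of
    the seasonal aggregate for fixed windows).
    """

    def __init__(self, ndvi_ano: MonthlyRaster, precip_ano: MonthlyRaster,
                 temp_ano: MonthlyRaster, rad_ano: MonthlyRaster,
                 mask: PixelMask | None = None,
                 years: tuple[int, int] = (1982, 2015),
                 alpha: float = 0.05):
        axes = ndvi_ano.axes
        for s in (precip_ano, temp_ano, rad_ano):
            if s.axes != axes or not s.times.equals(ndvi_ano.times):
                raise GeometryError("anomaly stacks not aligned")
        if years[1] - years[0] + 1 < 6:
            raise ValueError("need at least 6 analysis years")
        self.axes = axes
        self.ndvi_ano, self.precip_ano = ndvi_ano, precip_ano
        self.temp_ano, self.rad_ano = temp_ano, rad_ano
        self.mask = mask
        self.years = years
        self.alpha = alpha

    def fit(self) -> "SeasonalResponseResults":
        yrs = np.arange(self.years[0], self.years[1] + 1)
        n_s, n_m = len(NDVI_SEASONS), len(MODES)
        nlat, nlon = self.axes.shape
        r = np.full((n_s, n_m, nlat, nlon), np.nan)
        p = np.full_like(r, np.nan)
        for si, season in enumerate(NDVI_SEASONS):
            x = seasonal_series(self.ndvi_ano, season, "Ra0", yrs, "mean")
            for mi, mode in enumerate(MODES):
                y = seasonal_series(self.precip_ano, season, mode, yrs, "sum")
                z1 = seasonal_series(self.temp_ano, season, mode, yrs, "mean")
                z2 = seasonal_series(self.rad_ano, season, mode, yrs, "mean")
                rr, pp, _ = stats.partial_second_stack(x, y, z1, z2)
                r[si, mi] = rr
                p[si, mi] = pp
        if self.mask is not None:
            r[:, :, ~self.mask.valid] = np.nan
            p[:, :, ~self.mask.valid] = np.nan
        return SeasonalResponseResults(self, r, p)


@dataclass
class SeasonalResponseResults:
    """12 maps of r and p: (season in spring/summer/autumn) x (4 modes)."""

    model: SeasonalResponseModel
    r: np.ndarray   # (season, mode, lat, lon)
    p: np.ndarray

    def get(self, season: str, mode: str) -> tuple[np.ndarray, np.ndarray]:
        si = NDVI_SEASONS.index(season)
        mi = MODES.index(mode)
        return self.r[si, mi], self.p[si, mi]

    def significant(self, season: str, mode: str) -> np.ndarray:
        _, p = self.get(season, mode)
        return np.nan_to_num(p, nan=1.0) < self.model.alpha

    def to_dataset(self) -> xr.Dataset:
        axes = self.model.axes
        ds = xr.Dataset(
            {
                "r_seasonal": (("season", "mode", "lat", "lon"), self.r),
                "p_seasonal": (("season", "mode", "lat", "lon"), self.p),
            },
            coords={"season": list(NDVI_SEASONS), "mode": list(MODES),
                    "lat": axes.lat, "lon": axes.lon},
        )
        ds.attrs["alpha"] = self.model.alpha
        return ds

    def to_netcdf(self, path) -> None:
        # NetCDF3 cannot store variable-length strings as coords; use indices
        ds = self.to_dataset()
        ds = ds.assign_coords(season=np.arange(len(NDVI_SEASONS)),
                              mode=np.arange(len(MODES)))
        # ';' separator: the mode names themselves contain commas
        ds.attrs["season_names"] = ";".join(NDVI_SEASONS)
        ds.attrs["mode_names"] = ";".join(MODES)
        ds.to_netcdf(path, engine="scipy")

    def summary(self) -> str:
        rows = []
        for season in NDVI_SEASONS:
            for mode in MODES:
                r, _ = self.get(season, mode)
                sig = self.significant(season, mode)
                n_valid = int(np.isfinite(r).sum())
                rows.append({
                    "season": season, "mode": mode,
                    "median_r": float(np.nanmedian(r)) if n_valid else float("nan"),
                    "pct_significant": 100.0 * sig.sum() / n_valid if n_valid else float("nan"),
                })
        frame = pd.DataFrame(rows)
        return ("Seasonal precipitation-NDVI partial correlations\n"
                "================================================\n"
                + frame.to_string(index=False,
                                  float_format=lambda v: f"{v:.3f}"))
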