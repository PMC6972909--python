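"""Temporal response of vegetation to precipitation anomalies.

The design crosses 4 time lags (0-3 months) with 6 cumulation periods
(1-6 months): combination j (1..24, lag-major: j = lag*6 + cumper) pairs
each growing-season month's NDVI anomaly series with the precipitation
anomaly summed over the window covering months lag .. lag+cumper-1 before
(and including, at lag 0) that month.  With growing-season months
April..October this yields 7 x 24 = 168 second-order partial correlation
analyses per pixel, controlling temperature and radiation anomalies
accumulated over the same window.  Per combination the signed maximum over
the 7 months gives r_j; the signed maximum over the 24 combinations gives
r_max and the best (lag, cumper) — the per-pixel temporal fingerprint of
the precipitation-vegetation relationship.

Organised as a model/results pair: build :class:`TemporalResponseModel`
from anomaly stacks (or raw stacks via :meth:`from_rasters`), call
``fit()`` and read maps, share tables and the summary off the results.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
import xarray as xr

from . import stats
from .grids import GeometryError, MonthlyRaster, PixelMask
from .preprocess import GROWING_MONTHS, monthly_anomalies

__all__ = ["LagCumCombo", "design_combos", "TemporalResponseModel",
           "TemporalResponseResults"]


class LagCumCombo(NamedTuple):
    """One cell of the lag x cumulation design."""

    j: int        # 1..24, lag-major
    lag: int      # months before the NDVI month (0 = current)
    cumper: int   # number of consecutive months summed

    @property
    def window_label(self) -> str:
        lo, hi = self.lag, self.lag + self.cumper - 1
        return str(lo) if lo == hi else f"{lo}–{hi}"


def design_combos(lags: Sequence[int] = (0, 1, 2, 3),
                  cumpers: Sequence[int] = (1, 2, 3, 4, 5, 6)) -> list[LagCumCombo]:
    """Enumerate the full design in lag-major order (j = lag*6 + cumper)."""
    combos = []
    for li, lag in enumerate(lags):
        for ci, cum in enumerate(cumpers):
            combos.append(LagCumCombo(li * len(cumpers) + ci + 1, lag, cum))
    return combos


def _window_series(ano: np.ndarray, lag: int, cum: int) -> np.ndarray:
    """Windowed sums along axis 0; NaN where the window is incomplete."""
    T = ano.shape[0]
    out = np.full_like(ano, np.nan)
    lead = lag + cum - 1
    acc = np.zeros_like(ano[lead:])
    for k in range(cum):
        acc = acc + ano[lead - lag - k: T - lag - k]
    out[lead:] = acc
    return out


class TemporalResponseModel:
    """Per-pixel lag/cumulation partial-correlation analysis.

    Parameters
    ----------
    ndvi_ano, precip_ano, temp_ano, rad_ano
        Monthly anomaly stacks on one grid.  The precipitation record must
        extend at least 8 months before the first analysis April (the
        deepest window is lag 3 + cumulation 6).
    mask
        Optional pixel validity mask; invalid pixels come out as NaN.
    years
        Inclusive analysis years (the correlation sample, one value per
        year per month).
    alpha
        Two-sided significance level of the t-tests.
    controls_window
        ``'matched'`` accumulates the temperature/radiation controls over
        the same (lag, cumper) window as precipitation; ``'lag0'`` keeps
        the controls at lag 0 with the same cumulation period.
    """

    def __init__(self, ndvi_ano: MonthlyRaster, precip_ano: MonthlyRaster,
                 temp_ano: MonthlyRaster, rad_ano: MonthlyRaster,
                 mask: PixelMask | None = None,
                 years: tuple[int, int] = (1982, 2015),
                 months: Sequence[int] = GROWING_MONTHS,
                 alpha: float = 0.05,
                 controls_window: str = "matched"):
        stacks = (ndvi_ano, precip_ano, temp_ano, rad_ano)
        axes = ndvi_ano.axes
        for s in stacks[1:]:
            if s.axes != axes or not s.times.equals(ndvi_ano.times):
                raise GeometryError("anomaly stacks not aligned")
        if controls_window not in ("matched", "lag0"):
            raise ValueError("controls_window must be 'matched' or 'lag0'")
        if not 0 < alpha < 1:
            raise ValueError("alpha out of (0, 1)")
        self.axes = axes
        self.times = ndvi_ano.times
        self.ndvi_ano, self.precip_ano = ndvi_ano, precip_ano
        self.temp_ano, self.rad_ano = temp_ano, rad_ano
        self.mask = mask
        self.years = years
        self.months = tuple(months)
        self.alpha = alpha
        self.controls_window = controls_window
        self.combos = design_combos()
        # the deepest window of the design must stay inside the record
        first_needed = pd.Period(year=years[0], month=min(self.months), freq="M") - 8
        if self.times[0] > first_needed:
            raise ValueError(
                f"anomaly record must start at or before {first_needed} "
                "(lag 3 + cumulation 6 reaches 8 months back)")
        if self.times[-1] < pd.Period(year=years[1], month=max(self.months), freq="M"):
            raise ValueError("anomaly record ends before the last analysis month")

    @classmethod
    def from_rasters(cls, ndvi: MonthlyRaster, precip: MonthlyRaster,
                     temp: MonthlyRaster, rad: MonthlyRaster,
                     base_period: tuple[int, int] = (1982, 2015),
                     **kwargs) -> "TemporalResponseModel":
        """Build the model from raw stacks, computing monthly anomalies."""
        return cls(monthly_anomalies(ndvi, base_period),
                   monthly_anomalies(precip, base_period),
                   monthly_anomalies(temp, base_period),
                   monthly_anomalies(rad, base_period), **kwargs)

    def _month_rows(self, month: int) -> np.ndarray:
        y0, y1 = self.years
        yrs = np.asarray(self.times.year)
        mos = np.asarray(self.times.month)
        rows = np.nonzero((yrs >= y0) & (yrs <= y1) & (mos == month))[0]
        return rows

    def fit(self) -> "TemporalResponseResults":
        """Run all month x combination analyses and collect the cube."""
        nlat, nlon = self.axes.shape
        n_m, n_j = len(self.months), len(self.combos)
        r_cube = np.full((n_m, n_j, nlat, nlon), np.nan)
        p_cube = np.full_like(r_cube, np.nan)
        n_cube = np.zeros((n_m, n_j, nlat, nlon), dtype=int)

        ndvi = self.ndvi_ano.values
        rows_by_month = {m: self._month_rows(m) for m in self.months}

        for jx, combo in enumerate(self.combos):
            w_p = _window_series(self.precip_ano.values, combo.lag, combo.cumper)
            clag = combo.lag if self.controls_window == "matched" else 0
            w_t = _window_series(self.temp_ano.values, clag, combo.cumper)
            w_r = _window_series(self.rad_ano.values, clag, combo.cumper)
            for mx, month in enumerate(self.months):
                rows = rows_by_month[month]
                r, p, n = stats.partial_second_stack(
                    ndvi[rows], w_p[rows], w_t[rows], w_r[rows])
                r_cube[mx, jx] = r
                p_cube[mx, jx] = p
                n_cube[mx, jx] = n

        if self.mask is not None:
            invalid = ~self.mask.valid
            r_cube[:, :, invalid] = np.nan
            p_cube[:, :, invalid] = np.nan
        return TemporalResponseResults(self, r_cube, p_cube, n_cube)


@dataclass
class TemporalResponseResults:
    """Correlation cube and its growing-season summaries."""

    model: TemporalResponseModel
    r_cube: np.ndarray   # (month, combo, lat, lon)
    p_cube: np.ndarray
    n_cube: np.ndarray

    def __post_init__(self) -> None:
        self._summarize()

    def _summarize(self) -> None:
        with np.errstate(invalid="ignore"):
            all_nan = np.isnan(self.r_cube).all(axis=0)
            filled_cube = np.where(np.isnan(self.r_cube), -np.inf, self.r_cube)
            self.r_j = np.where(all_nan, np.nan, filled_cube.max(axis=0))
            # significance of r_j: p-value at the maximising month
            arg = filled_cube.argmax(axis=0)
            self.p_j = np.take_along_axis(self.p_cube, arg[None], axis=0)[0]
            self.p_j = np.where(all_nan, np.nan, self.p_j)

            all_nan_j = np.isnan(self.r_j).all(axis=0)
            filled = np.where(np.isnan(self.r_j), -np.inf, self.r_j)
            self.r_max = np.where(all_nan_j, np.nan, filled.max(axis=0))
            # argmax in lag-major order implements the documented tie rule:
            # smallest lag first, then smallest cumulation period
            best = filled.argmax(axis=0)
            self.best_j = np.where(all_nan_j, -1, best + 1)
        combos = self.model.combos
        lag_of = np.array([c.lag for c in combos])
        cum_of = np.array([c.cumper for c in combos])
        self.best_lag = np.where(self.best_j > 0, lag_of[best], -1)
        self.best_cumper = np.where(self.best_j > 0, cum_of[best], -1)
        with np.errstate(invalid="ignore"):
            self.any_significant = (np.nan_to_num(self.p_j, nan=1.0)
                                    < self.model.alpha).any(axis=0)
        self.any_significant &= ~all_nan_j

    # -- restricted argmax maps ------------------------------------------

    def _restricted_best(self, keep: np.ndarray, attr: str) -> np.ndarray:
        """Argmax of r_j over a subset of combos, reported as lag or cumper."""
        combos = [c for c in self.model.combos]
        idx = [i for i, c in enumerate(combos) if keep[i]]
        sub = self.r_j[idx]
        filled = np.where(np.isnan(sub), -np.inf, sub)
        all_nan = np.isnan(sub).all(axis=0)
        best = filled.argmax(axis=0)
        vals = np.array([getattr(combos[i], attr) for i in idx])
        return np.where(all_nan, -1, vals[best])

    def best_lag_map(self) -> np.ndarray:
        """Best lag among the cumulation-period-1 analyses (-1 = undefined)."""
        keep = np.array([c.cumper == 1 for c in self.model.combos])
        return self._restricted_best(keep, "lag")

    def best_cum_map(self) -> np.ndarray:
        """Best cumulation period among the lag-0 analyses (-1 = undefined)."""
        keep = np.array([c.lag == 0 for c in self.model.combos])
        return self._restricted_best(keep, "cumper")

    def _share_table(self, values: np.ndarray, levels: Sequence[int],
                     name: str) -> pd.Series:
        sel = self.any_significant & (values >= 0)
        counts = pd.Series({lv: int(((values == lv) & sel).sum()) for lv in levels},
                           name="share_pct")
        counts.index.name = name
        total = counts.sum()
        return 100.0 * counts / total if total else counts.astype(float)

    def lag_share_table(self) -> pd.Series:
        """Percentage of significantly correlated pixels per best lag
        (cumulation period fixed at 1 month)."""
        return self._share_table(self.best_lag_map(), (0, 1, 2, 3), "lag")

    def cum_share_table(self) -> pd.Series:
        """Percentage of significantly correlated pixels per best cumulation
        period (no time lag)."""
        return self._share_table(self.best_cum_map(), (1, 2, 3, 4, 5, 6), "cumper")

    def significance_fraction(self) -> float:
        """Fraction of valid pixels with >= 1 of the 24 analyses significant."""
        valid = ~np.isnan(self.r_max)
        if self.model.mask is not None:
            valid &= self.model.mask.valid
        n = valid.sum()
        return float((self.any_significant & valid).sum() / n) if n else float("nan")

    def r_max_masked(self) -> np.ndarray:
        """r_max with non-significant pixels blanked (the headline map)."""
        return np.where(self.any_significant, self.r_max, np.nan)

    # -- export -----------------------------------------------------------

    def to_dataset(self) -> xr.Dataset:
        axes = self.model.axes
        coords = {"month": list(self.model.months),
                  "combo": [c.j for c in self.model.combos],
                  "lat": axes.lat, "lon": axes.lon}
        ds = xr.Dataset(
            {
                "r_cube": (("month", "combo", "lat", "lon"), self.r_cube),
                "p_cube": (("month", "combo", "lat", "lon"), self.p_cube),
                "r_j": (("combo", "lat", "lon"), self.r_j),
                "r_max": (("lat", "lon"), self.r_max),
                "best_lag": (("lat", "lon"), self.best_lag.astype(float)),
                "best_cumper": (("lat", "lon"), self.best_cumper.astype(float)),
                "any_significant": (("lat", "lon"), self.any_significant.astype(float)),
            },
            coords=coords,
        )
        ds.attrs["alpha"] = self.model.alpha
        ds.attrs["controls_window"] = self.model.controls_window
        return ds

    def to_netcdf(self, path) -> None:
        self.to_dataset().to_netcdf(path, engine="scipy")

    def summary(self) -> str:
        lag_share = self.lag_share_table()
        cum_share = self.cum_share_table()
        lines = [
            "Temporal response of NDVI to precipitation anomalies",
            "====================================================",
            f"grid: {self.axes_shape[0]} x {self.axes_shape[1]} pixels, "
            f"years {self.model.years[0]}-{self.model.years[1]}",
            f"design: {len(self.model.combos)} (lag, cumper) combinations x "
            f"{len(self.model.months)} months = "
            f"{len(self.model.combos) * len(self.model.months)} analyses/pixel",
            f"alpha = {self.model.alpha}, controls window = {self.model.controls_window}",
            f"pixels with any significant correlation: "
            f"{100 * self.significance_fraction():.1f}%",
            f"median r_max over significant pixels: "
            f"{np.nanmedian(self.r_max_masked()):.3f}",
            "",
            "best-lag shares (cumper = 1), % of significant pixels:",
            lag_share.round(1).to_string(),
            "",
            "best-cumulation shares (lag = 0), % of significant pixels:",
            cum_share.round(1).to_string(),
        ]
        return "\n".join(lines)

    @property
    def axes_shape(self) -> tuple[int, int]:
        return self.model.axes.shape
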