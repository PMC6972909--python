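"""Anomaly preprocessing for monthly grids.

Turns raw stacks into analysis-ready series: maximum-value compositing of
sub-monthly NDVI, quality masking, per-calendar-month climatology and
anomalies, seasonal aggregation, lag/cumulation window sums, area-weighted
regional series and an OLS trend.

Seasons follow the growing-season convention: spring = Apr-May,
summer = Jun-Aug, autumn = Sep-Oct, growing season = Apr-Oct.  The
non-growing (winter) season is Nov-Mar, labelled by the year of its
Jan-Mar part, so the four seasons partition the calendar year.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .grids import (AnomalyRaster, GeometryError, GridAxes, MonthlyRaster,
                    PixelMask, StaticMap)

__all__ = [
    "SEASONS",
    "Season",
    "YearlyField",
    "TrendResult",
    "mvc_monthly",
    "qc_mask",
    "monthly_anomalies",
    "seasonal_aggregate",
    "accumulate_window",
    "area_weighted_mean",
    "ols_trend",
]

GROWING_MONTHS = (4, 5, 6, 7, 8, 9, 10)


@dataclass(frozen=True)
class Season:
    """A named window of calendar months; ``offsets`` gives the year offset
    of each month relative to the labelling year (winter reaches back)."""

    name: str
    months: tuple[int, ...]

    @property
    def offsets(self) -> tuple[int, ...]:
        # months >= 11 in a Nov-Mar window belong to the previous year
        if self.name == "winter":
            return tuple(-1 if m >= 11 else 0 for m in self.months)
        return tuple(0 for _ in self.months)


SEASONS: dict[str, Season] = {
    "spring": Season("spring", (4, 5)),
    "summer": Season("summer", (6, 7, 8)),
    "autumn": Season("autumn", (9, 10)),
    "winter": Season("winter", (11, 12, 1, 2, 3)),
    "growing": Season("growing", GROWING_MONTHS),
}


@dataclass
class YearlyField:
    """One value per (year, lat, lon) — a seasonally aggregated stack."""

    axes: GridAxes
    years: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.years.size,) + self.axes.shape:
            raise GeometryError("yearly field shape mismatch")


@dataclass(frozen=True)
class TrendResult:
    """OLS fit of a yearly series against calendar year."""

    slope: float
    intercept: float
    r_squared: float
    p_value: float


def mvc_monthly(composites: Sequence[MonthlyRaster]) -> MonthlyRaster:
    """Maximum-value composite: per month, the max over sub-monthly layers.

    A cell is missing only where every composite is missing.
    """
    if not composites:
        raise ValueError("no composites given")
    first = composites[0]
    stack = np.stack([c.values for c in composites])
    for c in composites[1:]:
        if c.axes != first.axes or not c.times.equals(first.times):
            raise GeometryError("composites not aligned")
    with np.errstate(invalid="ignore"):
        out = np.nanmax(stack, axis=0)
    return MonthlyRaster(first.axes, first.times, out, first.variable, first.units)


def qc_mask(ndvi: MonthlyRaster,
            builtup: StaticMap | None = None,
            abnormal_rule: Callable[[np.ndarray], np.ndarray] | None = None,
            months: Sequence[int] = GROWING_MONTHS,
            require_complete: bool = True) -> PixelMask:
    """Pixel validity: not built-up, no abnormal growing-season value,
    and (optionally) no missing month in the required window.

    The default abnormal rule flags NDVI <= 0 during the growing season —
    contaminated retrievals around water bodies and mountains.
    """
    if abnormal_rule is None:
        abnormal_rule = lambda v: v <= 0.0
    sel = np.isin(ndvi.months, list(months))
    vals = ndvi.values[sel]
    finite = np.isfinite(vals)
    with np.errstate(invalid="ignore"):
        abnormal = (finite & abnormal_rule(vals)).any(axis=0)
    valid = ~abnormal
    if require_complete:
        valid &= finite.all(axis=0)
    if builtup is not None:
        if builtup.axes != ndvi.axes:
            raise GeometryError("builtup map axes differ from NDVI")
        valid &= ~(np.asarray(builtup.values) > 0)
    return PixelMask(ndvi.axes, valid)


def monthly_anomalies(stack: MonthlyRaster,
                      base_period: tuple[int, int] = (1982, 2015)) -> AnomalyRaster:
    """Deviation from the per-calendar-month mean over ``base_period``.

    Anomalies are defined for *all* months in the stack (including years
    before the base period, which exist only to feed lagged windows) using
    the base-period climatology.
    """
    y0, y1 = base_period
    if y1 - y0 + 1 < 2:
        raise ValueError("base period must span at least 2 years")
    years = stack.years
    if y0 < years.min() or y1 > years.max():
        raise ValueError("base period outside stack years")
    months = stack.months
    out = np.empty_like(stack.values)
    in_base = (years >= y0) & (years <= y1)
    for m in range(1, 13):
        sel = months == m
        if not sel.any():
            continue
        base = stack.values[sel & in_base]
        with np.errstate(invalid="ignore"):
            clim = np.nanmean(base, axis=0) if base.size else np.nan
        out[sel] = stack.values[sel] - clim
    return AnomalyRaster(stack.axes, stack.times, out, stack.variable, stack.units)


def seasonal_aggregate(stack: MonthlyRaster, season: Season | str,
                       statistic: str = "mean") -> YearlyField:
    """Aggregate a monthly stack to one value per year for a season.

    NDVI-style variables use ``mean``; precipitation uses ``sum``.  Winter
    (Nov-Mar) is labelled by the year of its Jan-Mar part; a year whose
    previous Nov-Dec is not in the stack gets a missing winter.  A year is
    missing if any of the season's months is absent from the stack.
    """
    if isinstance(season, str):
        season = SEASONS[season]
    if statistic not in ("mean", "sum"):
        raise ValueError("statistic must be 'mean' or 'sum'")
    years_all = np.unique(stack.years)
    index = {(y, m): i for i, (y, m) in enumerate(zip(stack.years, stack.months))}
    nlat, nlon = stack.axes.shape
    out = np.full((years_all.size, nlat, nlon), np.nan)
    for yi, year in enumerate(years_all):
        idx = []
        ok = True
        for m, off in zip(season.months, season.offsets):
            key = (year + off, m)
            if key not in index:
                ok = False
                break
            idx.append(index[key])
        if not ok:
            continue
        vals = stack.values[idx]
        out[yi] = vals.sum(axis=0) if statistic == "sum" else vals.mean(axis=0)
    return YearlyField(stack.axes, years_all, out)


def accumulate_window(precip_ano: MonthlyRaster, lag: int, cumper: int,
                      at_month: int, at_year: int) -> np.ndarray:
    """Sum of anomalies over the ``cumper`` consecutive months ending
    ``lag`` months before (and including, when lag = 0) the target month.

    Window semantics: lag l, cumulation c covers months l .. l+c-1 before
    the current month — e.g. lag 2, cumper 4 at month t sums t-2 .. t-5.
    """
    if lag < 0 or cumper < 1:
        raise ValueError("lag must be >= 0 and cumper >= 1")
    target = pd.Period(year=at_year, month=at_month, freq="M")
    first = precip_ano.times[0]
    start = target - lag - (cumper - 1)
    if start < first:
        raise ValueError("window precedes start of anomaly record")
    out = np.zeros(precip_ano.axes.shape)
    for k in range(cumper):
        p = target - lag - k
        out = out + precip_ano.values[precip_ano.times.get_loc(p)]
    return out


def area_weighted_mean(field: MonthlyRaster | YearlyField,
                       mask: PixelMask | None = None) -> pd.Series:
    """cos(latitude)-weighted spatial mean over valid pixels per time step.

    Weights are renormalised over the pixels that are valid and non-missing
    at each step; a step with no valid pixel is an error.
    """
    values = field.values
    axes = field.axes
    if mask is not None:
        if mask.axes != axes:
            raise GeometryError("mask axes differ")
        valid2d = mask.valid
    else:
        valid2d = np.ones(axes.shape, dtype=bool)
    w = np.cos(np.deg2rad(axes.lat))[:, None] * np.ones(axes.shape)
    w = np.where(valid2d, w, 0.0)
    finite = np.isfinite(values)
    wt = finite * w
    denom = wt.sum(axis=(1, 2))
    if np.any(denom == 0):
        raise ValueError("a time step has no valid pixels")
    num = np.where(finite, values, 0.0) * w
    series = num.sum(axis=(1, 2)) / denom
    if isinstance(field, YearlyField):
        index = pd.Index(field.years, name="year")
    else:
        index = field.times
    return pd.Series(series, index=index)


def ols_trend(series: pd.Series) -> TrendResult:
    """OLS of a yearly series on calendar year (two-sided slope test)."""
    y = np.asarray(series.values, dtype=float)
    x = np.asarray(series.index, dtype=float)
    keep = np.isfinite(y)
    y, x = y[keep], x[keep]
    if y.size < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0:
        raise ValueError("constant time axis")
    if np.ptp(y) == 0:
        # flat series: zero slope, no explained variance
        return TrendResult(0.0, float(y[0]), 0.0, 1.0)
    model = sm.OLS(y, sm.add_constant(x)).fit()
    return TrendResult(slope=float(model.params[1]),
                       intercept=float(model.params[0]),
                       r_squared=float(model.rsquared),
                       p_value=float(model.pvalues[1]))
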