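"""Precipitation-characteristic indices and Angstrom radiation.

Three per-pixel indices summarise the precipitation regime:

* MAP — mean annual precipitation (mm/yr), mean over years of the
  12-month totals;
* FPD — fraction of precipitation days: wet-day count over days in the
  year (leap-aware), averaged over years;
* PCI — precipitation concentration index,
  ``PCI = 100 * sum(p_i^2) / (sum(p_i))^2`` over the 12 monthly totals
  p_1..p_12 of a year: 100/12 for perfectly uniform rainfall, 100 when a
  single month receives everything.  Multi-year maps compute PCI per year
  and average (configurable to PCI of the mean climatology).

Solar radiation can be estimated from sunshine duration with the Angstrom
formula R_s = (a_s + b_s * n/N) * R_a; the FAO-56 coefficients
a_s = 0.25, b_s = 0.50 are the defaults.
"""

from __future__ import annotations

import calendar
from dataclasses import dataclass

import numpy as np

from .grids import GeometryError, GridAxes, MonthlyRaster, PixelMask

__all__ = [
    "PrecipIndexMaps",
    "ThresholdRanges",
    "mean_annual_precip",
    "fraction_precip_days",
    "pci",
    "pci_map",
    "angstrom_radiation",
    "threshold_select",
]

PCI_UNIFORM = 100.0 / 12.0


def _full_year_matrix(stack: MonthlyRaster, years: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    """Return (years_used, values reshaped to (n_years, 12, nlat, nlon))."""
    y0, y1 = years
    yr = stack.years
    mo = stack.months
    out_years = np.arange(y0, y1 + 1)
    sel = (yr >= y0) & (yr <= y1)
    if sel.sum() != out_years.size * 12 or mo[sel][0] != 1 or mo[sel][-1] != 12:
        raise ValueError("index computation requires full calendar years")
    vals = stack.values[sel].reshape(out_years.size, 12, *stack.axes.shape)
    return out_years, vals


def mean_annual_precip(precip: MonthlyRaster, years: tuple[int, int]) -> np.ndarray:
    """Mean over years of annual precipitation totals (mm/yr)."""
    _, vals = _full_year_matrix(precip, years)
    return vals.sum(axis=1).mean(axis=0)


def fraction_precip_days(wet_days: MonthlyRaster, years: tuple[int, int]) -> np.ndarray:
    """Wet-day count over days in the year, leap-aware, averaged over years."""
    yrs, vals = _full_year_matrix(wet_days, years)
    days = np.array([366.0 if calendar.isleap(y) else 365.0 for y in yrs])
    annual = vals.sum(axis=1) / days[:, None, None]
    return annual.mean(axis=0)


def pci(p_monthly: np.ndarray) -> float:
    """PCI of one year's 12 monthly totals; undefined (NaN) for a dry year."""
    p = np.asarray(p_monthly, dtype=float)
    if p.shape[-1] != 12 and p.size != 12:
        raise ValueError("need 12 monthly values")
    total = p.sum()
    if not np.isfinite(total) or total <= 0:
        return float("nan")
    return float(100.0 * (p * p).sum() / (total * total))


def pci_map(precip: MonthlyRaster, years: tuple[int, int],
            per_year: bool = True) -> np.ndarray:
    """Per-pixel PCI map; per-year PCI averaged over years by default,
    else PCI of the mean monthly climatology."""
    _, vals = _full_year_matrix(precip, years)
    if not per_year:
        vals = vals.mean(axis=0, keepdims=True)
    totals = vals.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        yearly = 100.0 * (vals * vals).sum(axis=1) / (totals * totals)
    yearly = np.where(totals > 0, yearly, np.nan)
    with np.errstate(invalid="ignore"):
        return np.nanmean(yearly, axis=0)


def angstrom_radiation(n, N, R_a, a_s: float = 0.25, b_s: float = 0.50):
    """Angstrom estimate R_s = (a_s + b_s * n/N) * R_a (MJ m-2 d-1)."""
    n = np.asarray(n, dtype=float)
    N = np.asarray(N, dtype=float)
    if a_s <= 0 or b_s <= 0:
        raise ValueError("Angstrom coefficients must be positive")
    if np.any(n < 0) or np.any(n > N):
        raise ValueError("sunshine hours must satisfy 0 <= n <= N")
    out = (a_s + b_s * n / N) * np.asarray(R_a, dtype=float)
    return float(out) if out.ndim == 0 else out


@dataclass
class PrecipIndexMaps:
    """Per-pixel MAP / FPD / PCI on one grid."""

    axes: GridAxes
    map_mm: np.ndarray
    fpd: np.ndarray
    pci: np.ndarray

    @classmethod
    def from_stacks(cls, precip: MonthlyRaster, wet_days: MonthlyRaster,
                    years: tuple[int, int], pci_per_year: bool = True) -> "PrecipIndexMaps":
        if precip.axes != wet_days.axes:
            raise GeometryError("precip and wet-day grids differ")
        return cls(
            axes=precip.axes,
            map_mm=mean_annual_precip(precip, years),
            fpd=fraction_precip_days(wet_days, years),
            pci=pci_map(precip, years, per_year=pci_per_year),
        )


@dataclass(frozen=True)
class ThresholdRanges:
    """Closed index ranges defining the high-response precipitation regime:
    semi-arid amounts, intermediate frequency, concentrated but not extreme
    seasonality."""

    map_range: tuple[float, float] = (150.0, 500.0)
    fpd_range: tuple[float, float] = (0.075, 0.275)
    pci_range: tuple[float, float] = (19.0, 23.0)

    def __post_init__(self) -> None:
        for lo, hi in (self.map_range, self.fpd_range, self.pci_range):
            if not lo < hi:
                raise ValueError("each range needs lower < upper")


def threshold_select(indices: PrecipIndexMaps, ranges: ThresholdRanges | None = None,
                     mode: str = "overlap"):
    """Select pixels whose indices fall inside the given closed ranges.

    ``mode='each'`` returns ``{'map': PixelMask, 'fpd': ..., 'pci': ...}``;
    ``mode='overlap'`` returns their conjunction as one mask.
    """
    ranges = ranges or ThresholdRanges()

    def _in(vals, rng):
        with np.errstate(invalid="ignore"):
            ok = (vals >= rng[0]) & (vals <= rng[1])
        return np.where(np.isfinite(vals), ok, False)

    masks = {
        "map": PixelMask(indices.axes, _in(indices.map_mm, ranges.map_range)),
        "fpd": PixelMask(indices.axes, _in(indices.fpd, ranges.fpd_range)),
        "pci": PixelMask(indices.axes, _in(indices.pci, ranges.pci_range)),
    }
    if mode == "each":
        return masks
    if mode == "overlap":
        valid = masks["map"].valid & masks["fpd"].valid & masks["pci"].valid
        return PixelMask(indices.axes, valid)
    raise ValueError("mode must be 'each' or 'overlap'")
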