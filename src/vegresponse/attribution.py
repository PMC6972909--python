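"""Attribution of the r_max spatial pattern to climate and landscape gradients.

Binned-average profiles along covariates (MAP, FPD, PCI, elevation, CTI,
soil properties), zonal box statistics by ecological zone (the intersection
of one land-cover class with one terrestrial ecoregion), and per-zone
median temporal profiles over the 24 (lag, cumulation) analyses.

Bins are uniform, anchored at 0 and left-closed/right-open; bins or zones
with fewer than ``min_count`` pixels (default 10) are excluded.  Quantiles
interpolate linearly between order statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grids import GeometryError, PixelMask, StaticMap
from .stats import critical_r

__all__ = [
    "BinnedProfile",
    "ZoneSummary",
    "binned_average",
    "eco_zone_intersect",
    "zone_boxstats",
    "zone_temporal_medians",
    "critical_r",
]

DEFAULT_BIN_WIDTHS = {
    "map": 50.0, "fpd": 0.025, "pci": 1.0,
    "elevation": 1000.0, "cti": 1.0, "sbd": 0.1, "pawc": 50.0,
}


@dataclass
class BinnedProfile:
    """Binned means of a per-pixel statistic along one covariate."""

    covariate: str
    bin_edges: np.ndarray     # len = n_bins + 1
    mean: np.ndarray          # NaN where excluded
    sd: np.ndarray
    count: np.ndarray
    included: np.ndarray      # count >= min_count
    min_count: int

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def errorbar_halfwidth(self) -> np.ndarray:
        """Half an SD per bin — the error-bar convention of the profiles."""
        return self.sd / 2.0

    @property
    def peak_bin(self) -> int:
        """Index of the included bin with the largest mean (-1 if none)."""
        if not self.included.any():
            return -1
        filled = np.where(self.included, self.mean, -np.inf)
        return int(np.argmax(filled))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "bin_left": self.bin_edges[:-1], "bin_right": self.bin_edges[1:],
            "mean": self.mean, "sd": self.sd, "count": self.count,
            "included": self.included.astype(int),
        })


def binned_average(values: np.ndarray, covariate: np.ndarray | StaticMap,
                   bin_width: float, min_count: int = 10,
                   covariate_name: str = "covariate",
                   selection: PixelMask | None = None) -> BinnedProfile:
    """Mean/SD of ``values`` in uniform covariate bins anchored at 0.

    Pixels missing either the value or the covariate (or outside
    ``selection``) are skipped; bins with fewer than ``min_count``
    contributing pixels are flagged excluded and carry no mean/SD.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if isinstance(covariate, StaticMap):
        cov = np.asarray(covariate.values, dtype=float)
        covariate_name = covariate.kind
    else:
        cov = np.asarray(covariate, dtype=float)
    vals = np.asarray(values, dtype=float)
    if cov.shape != vals.shape:
        raise GeometryError("covariate and value maps differ in shape")
    keep = np.isfinite(vals) & np.isfinite(cov)
    if selection is not None:
        keep &= selection.valid
    v = vals[keep]
    c = cov[keep]
    if v.size == 0:
        return BinnedProfile(covariate_name, np.array([0.0, bin_width]),
                             np.array([np.nan]), np.array([np.nan]),
                             np.array([0]), np.array([False]), min_count)
    idx = np.floor(c / bin_width).astype(int)
    lo, hi = idx.min(), idx.max()
    n_bins = hi - lo + 1
    edges = (lo + np.arange(n_bins + 1)) * bin_width
    count = np.bincount(idx - lo, minlength=n_bins)
    sums = np.bincount(idx - lo, weights=v, minlength=n_bins)
    sq = np.bincount(idx - lo, weights=v * v, minlength=n_bins)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = sums / count
        var = np.maximum(sq / count - mean * mean, 0.0)
        sd = np.sqrt(var)
    included = count >= min_count
    mean = np.where(included, mean, np.nan)
    sd = np.where(included, sd, np.nan)
    return BinnedProfile(covariate_name, edges, mean, sd, count, included, min_count)


def eco_zone_intersect(landcover: StaticMap, ecoregion: StaticMap) -> StaticMap:
    """Ecological zones: one id per observed (land-cover, ecoregion) pair."""
    if landcover.axes != ecoregion.axes:
        raise GeometryError("landcover and ecoregion grids differ")
    lc = np.asarray(landcover.values).astype(int)
    er = np.asarray(ecoregion.values).astype(int)
    pairs = np.stack([lc.ravel(), er.ravel()], axis=1)
    uniq, inverse = np.unique(pairs, axis=0, return_inverse=True)
    zone = inverse.reshape(lc.shape)
    code_table = {int(i): (int(a), int(b)) for i, (a, b) in enumerate(uniq)}
    return StaticMap(landcover.axes, zone, "ecozone_id", code_table=code_table)


@dataclass
class ZoneSummary:
    """Box-plot statistics of a per-pixel statistic within one zone."""

    zone_id: int
    label: str
    count: int
    p5: float
    p25: float
    p50: float
    p75: float
    p95: float
    r_crit_05: float
    r_crit_001: float

    def as_dict(self) -> dict:
        return {
            "zone_id": self.zone_id, "label": self.label, "count": self.count,
            "p5": self.p5, "p25": self.p25, "p50": self.p50,
            "p75": self.p75, "p95": self.p95,
            "r_crit_05": self.r_crit_05, "r_crit_001": self.r_crit_001,
        }


def zone_boxstats(values: np.ndarray, zones: StaticMap,
                  selection: PixelMask | None = None,
                  min_pixels: int = 10, n_sample: int = 34,
                  n_controls: int = 2) -> list[ZoneSummary]:
    """Per-zone quantiles (5/25/50/75/95) of a per-pixel statistic.

    Zones with fewer than ``min_pixels`` contributing pixels are omitted.
    The significance reference lines are the two-sided critical |r| at
    alpha = 0.05 and 0.001 for the analysis sample size.
    """
    vals = np.asarray(values, dtype=float)
    zmap = np.asarray(zones.values).astype(int)
    if vals.shape != zmap.shape:
        raise GeometryError("value and zone maps differ in shape")
    keep = np.isfinite(vals)
    if selection is not None:
        keep &= selection.valid
    rc05 = critical_r(0.05, n_sample, n_controls)
    rc001 = critical_r(0.001, n_sample, n_controls)
    out = []
    for zid in np.unique(zmap[keep]):
        zvals = vals[keep & (zmap == zid)]
        if zvals.size < min_pixels:
            continue
        q = np.quantile(zvals, [0.05, 0.25, 0.50, 0.75, 0.95])
        label = str(zones.code_table.get(int(zid), zid)) if zones.code_table else str(zid)
        out.append(ZoneSummary(int(zid), label, int(zvals.size),
                               *map(float, q), rc05, rc001))
    return out


def zone_temporal_medians(r_j: np.ndarray, zones: StaticMap,
                          selection: PixelMask | None = None,
                          min_pixels: int = 10) -> pd.DataFrame:
    """Per-zone median of each of the 24 r_j maps.

    ``r_j`` has shape (24, nlat, nlon); the result is indexed by zone id
    with one column per design combination (j = 1..24, lag-major), ready
    for lag/cumulation profile plots.
    """
    r_j = np.asarray(r_j, dtype=float)
    if r_j.ndim != 3:
        raise ValueError("r_j must be (combo, lat, lon)")
    zmap = np.asarray(zones.values).astype(int)
    keep = np.isfinite(r_j).all(axis=0)
    if selection is not None:
        keep &= selection.valid
    rows = {}
    for zid in np.unique(zmap[keep]):
        sel = keep & (zmap == zid)
        if sel.sum() < min_pixels:
            continue
        rows[int(zid)] = np.median(r_j[:, sel], axis=1)
    frame = pd.DataFrame.from_dict(rows, orient="index",
                                   columns=[f"j{j}" for j in range(1, r_j.shape[0] + 1)])
    frame.index.name = "zone_id"
    return frame
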