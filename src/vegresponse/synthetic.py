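"""Synthetic gridded climate/NDVI stacks with a known lag-cumulation response.

The generator emulates the *shape* of a monthly 0.5-degree climate archive
(1981-2015 by default): gamma-distributed monthly precipitation around a
seasonal cycle typical of a semi-arid monsoon regime, sinusoidal temperature
and radiation cycles with Gaussian noise, binomial-style wet-day counts,
sunshine hours, and static landscape maps (ecological zones, elevation, CTI,
soil bulk density, available water capacity, built-up flags).

NDVI is generated as a pixel baseline seasonal cycle plus an anomaly

    NDVIano(t) = beta * z(P_acc(t; l*, c*)) + gamma * z(Tano(t))
               + delta * z(Rano(t)) + eps,   eps ~ N(0, sigma^2)

where (l*, c*) is the pixel's true lag/cumulation window, P_acc is the
precipitation anomaly summed over that window, and z(.) standardises per
calendar month over the generation period, so beta is expressed in NDVI
units per SD of accumulated precipitation anomaly and is comparable across
pixels and seasons.  The per-pixel truth table keyed by (lat_idx, lon_idx)
supports parameter-recovery experiments.

All randomness derives from one integer seed through named substreams, so
identical configurations produce bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import ndimage

from .grids import GridAxes, MonthlyRaster, StaticMap
from .preprocess import monthly_anomalies

__all__ = [
    "SyntheticConfig",
    "SyntheticTruth",
    "generate_climate",
    "generate_ndvi",
    "generate_landscape",
    "generate_dataset",
]

# monthly means for a semi-arid, summer-peaked reference pixel (~364 mm/yr).
# The concentration is deliberately moderate: with stronger seasonality the
# dry months contribute so little anomaly variance that adjacent cumulation
# windows become statistically indistinguishable, defeating the purpose of
# an embedded, recoverable response structure.  Interannual concentration
# (per-year PCI ~ 19) comes from the gamma dispersion instead, which scales
# all monthly variances proportionally and leaves the window geometry intact.
DEFAULT_PRECIP_MEANS = (16.0, 16.0, 18.0, 20.0, 28.0, 45.0, 70.0, 62.0, 35.0, 21.0, 17.0, 16.0)
DEFAULT_WETDAY_FRACTIONS = (0.07, 0.08, 0.10, 0.12, 0.18, 0.25, 0.30, 0.28, 0.20, 0.12, 0.08, 0.07)
# grassland-like NDVI baseline cycle (Jan..Dec)
DEFAULT_NDVI_BASELINE = (0.12, 0.12, 0.15, 0.22, 0.32, 0.45, 0.55, 0.52, 0.40, 0.28, 0.17, 0.13)

_STREAMS = ("precip", "temp", "radiation", "wet_days", "sunshine",
            "response", "ndvi_noise", "landscape", "semimonthly", "regime")


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for the synthetic experiment."""

    n_lat: int = 20
    n_lon: int = 20
    year_start: int = 1981
    year_end: int = 2015
    seed: int = 0
    cell_size: float = 0.5

    # climate marginals
    precip_monthly_mean: tuple = DEFAULT_PRECIP_MEANS
    precip_disp: float = 1.0          # gamma: var = disp * mean^2; 0 = deterministic
    # smooth per-pixel regime fields (None = spatially constant): multiply the
    # monthly precipitation means, the gamma dispersion and the wet-day
    # fractions, giving the domain MAP / PCI / FPD gradients to bin along
    map_scale_range: tuple | None = (0.4, 1.6)
    disp_scale_range: tuple | None = (0.7, 1.3)
    wetday_scale_range: tuple | None = (0.5, 1.5)
    temp_mean: float = 8.0            # degC
    temp_amplitude: float = 14.0
    temp_noise_sd: float = 0.8
    rad_mean: float = 15.0            # MJ m-2 d-1
    rad_amplitude: float = 8.0
    rad_noise_sd: float = 0.8
    wetday_fraction: tuple = DEFAULT_WETDAY_FRACTIONS
    wetday_noise_sd: float = 1.5      # days; 0 = deterministic
    sunshine_fraction_mean: float = 0.55
    sunshine_fraction_sd: float = 0.10
    max_sunshine_h: float = 12.0

    # vegetation response
    ndvi_baseline: tuple = DEFAULT_NDVI_BASELINE
    lag_choices: tuple = (0, 1, 2, 3)
    cum_choices: tuple = (1, 2, 3, 4, 5, 6)
    beta: float = 0.08                # NDVI units per SD of accumulated precip anomaly
    gamma: float = 0.02
    delta: float = 0.02
    noise_sd: float = 0.024           # NDVI anomaly noise sigma (= 0.3 * beta)

    # landscape
    builtup_fraction: float = 0.02
    landcover_probs: tuple = (0.4, 0.35, 0.25)
    n_ecoregions: int = 2

    def __post_init__(self) -> None:
        if self.year_end - self.year_start + 1 < 3:
            raise ValueError("need at least 3 years for an estimable climatology")
        for name in ("precip_disp", "temp_noise_sd", "rad_noise_sd",
                     "wetday_noise_sd", "sunshine_fraction_sd", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if any(l not in (0, 1, 2, 3) for l in self.lag_choices):
            raise ValueError("lags must lie in 0..3")
        if any(c not in (1, 2, 3, 4, 5, 6) for c in self.cum_choices):
            raise ValueError("cumulation periods must lie in 1..6")
        if not (0 <= self.builtup_fraction <= 1):
            raise ValueError("builtup_fraction must be in [0, 1]")
        if abs(sum(self.landcover_probs) - 1.0) > 1e-9:
            raise ValueError("landcover_probs must sum to 1")

    @property
    def n_years(self) -> int:
        return self.year_end - self.year_start + 1

    @property
    def axes(self) -> GridAxes:
        return GridAxes.regular(self.n_lat, self.n_lon, self.cell_size)

    @property
    def times(self) -> pd.PeriodIndex:
        return pd.period_range(f"{self.year_start}-01", periods=self.n_years * 12, freq="M")

    def rng(self, stream: str) -> np.random.Generator:
        idx = _STREAMS.index(stream)
        return np.random.default_rng(np.random.SeedSequence(self.seed, spawn_key=(idx,)))


@dataclass
class SyntheticTruth:
    """Per-pixel true response parameters, aligned to the generated grids."""

    axes: GridAxes
    lag: np.ndarray
    cum: np.ndarray
    beta: np.ndarray
    gamma: np.ndarray
    delta: np.ndarray
    noise_sd: float
    zone_id: np.ndarray | None = None

    @property
    def recoverable(self) -> np.ndarray:
        """Pixels whose precipitation effect is large relative to the noise."""
        if self.noise_sd == 0:
            return np.abs(self.beta) > 0
        return np.abs(self.beta) >= 2.0 * self.noise_sd

    def to_frame(self) -> pd.DataFrame:
        ii, jj = np.meshgrid(np.arange(self.axes.shape[0]),
                             np.arange(self.axes.shape[1]), indexing="ij")
        zone = self.zone_id if self.zone_id is not None else np.full(self.axes.shape, -1)
        return pd.DataFrame({
            "lat_idx": ii.ravel(), "lon_idx": jj.ravel(),
            "lag": self.lag.ravel(), "cum": self.cum.ravel(),
            "beta": self.beta.ravel(), "gamma": self.gamma.ravel(),
            "delta": self.delta.ravel(), "zone_id": np.asarray(zone).ravel(),
            "recoverable": self.recoverable.ravel().astype(int),
        })

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _seasonal_cycle(mean: float, amplitude: float, peak_month: float,
                    months: np.ndarray) -> np.ndarray:
    return mean + amplitude * np.cos(2 * np.pi * (months - peak_month) / 12.0)


def regime_fields(config: SyntheticConfig) -> dict[str, np.ndarray]:
    """Smooth per-pixel multipliers for the precipitation regime."""
    rng = config.rng("regime")
    shape = config.axes.shape
    out = {}
    for name, rng_range in (("map_scale", config.map_scale_range),
                            ("disp_scale", config.disp_scale_range),
                            ("wetday_scale", config.wetday_scale_range)):
        if rng_range is None:
            out[name] = np.ones(shape)
        else:
            out[name] = _smooth_field(rng, shape, rng_range[0], rng_range[1], sigma=3.0)
    return out


def generate_climate(config: SyntheticConfig) -> dict[str, MonthlyRaster]:
    """Monthly precipitation, temperature, radiation, wet days and sunshine."""
    axes = config.axes
    times = config.times
    months = np.asarray(times.month)
    shape = (len(times),) + axes.shape
    regime = regime_fields(config)

    pm = (np.asarray(config.precip_monthly_mean)[months - 1][:, None, None]
          * regime["map_scale"][None, :, :])
    if config.precip_disp == 0:
        precip = np.broadcast_to(pm, shape).copy()
    else:
        k = 1.0 / (config.precip_disp * regime["disp_scale"])[None, :, :]
        precip = config.rng("precip").gamma(shape=np.broadcast_to(k, shape),
                                            scale=pm / k, size=shape)

    tcyc = _seasonal_cycle(config.temp_mean, config.temp_amplitude, 7.0, months)[:, None, None]
    temp = tcyc + config.temp_noise_sd * config.rng("temp").standard_normal(shape)

    rcyc = _seasonal_cycle(config.rad_mean, config.rad_amplitude, 6.5, months)[:, None, None]
    rad = rcyc + config.rad_noise_sd * config.rng("radiation").standard_normal(shape)
    rad = np.clip(rad, 0.0, None)

    dim = np.array([p.days_in_month for p in times], dtype=float)[:, None, None]
    wfrac = np.clip(np.asarray(config.wetday_fraction)[months - 1][:, None, None]
                    * regime["wetday_scale"][None, :, :], 0.0, 0.95)
    wet = dim * wfrac
    if config.wetday_noise_sd > 0:
        wet = wet + config.wetday_noise_sd * config.rng("wet_days").standard_normal(shape)
    wet = np.clip(np.round(wet), 0, dim)

    sfrac = config.sunshine_fraction_mean
    if config.sunshine_fraction_sd > 0:
        sfrac = sfrac + config.sunshine_fraction_sd * config.rng("sunshine").standard_normal(shape)
    sun = np.clip(config.max_sunshine_h * np.broadcast_to(sfrac, shape),
                  0.0, config.max_sunshine_h)

    return {
        "precip": MonthlyRaster(axes, times, precip, "precip_mm"),
        "temp": MonthlyRaster(axes, times, temp, "temp_C"),
        "radiation": MonthlyRaster(axes, times, rad, "radiation_MJ_m2_d"),
        "wet_days": MonthlyRaster(axes, times, wet, "wet_days"),
        "sunshine": MonthlyRaster(axes, times, sun.copy(), "sunshine_h"),
    }


def _window_sums(values: np.ndarray, lag: int, cum: int) -> np.ndarray:
    """Sum over the window [t-lag-cum+1 .. t-lag]; NaN where incomplete."""
    T = values.shape[0]
    out = np.full_like(values, np.nan)
    lead = lag + cum - 1
    acc = np.zeros_like(values[lead:])
    for k in range(cum):
        sl = slice(lead - lag - k, T - lag - k)
        acc = acc + values[sl]
    out[lead:] = acc
    return out


def _standardize_by_month(values: np.ndarray, months: np.ndarray) -> np.ndarray:
    """z-score per calendar month over the whole record (NaN-aware)."""
    out = np.full_like(values, np.nan)
    for m in range(1, 13):
        sel = months == m
        if not sel.any():
            continue
        block = values[sel]
        with np.errstate(invalid="ignore"):
            mu = np.nanmean(block, axis=0)
            sd = np.nanstd(block, axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            z = (block - mu) / sd
        out[sel] = np.where(sd > 0, z, 0.0)
    return out


def generate_ndvi(climate: dict[str, MonthlyRaster], config: SyntheticConfig,
                  semimonthly: bool = False,
                  zones: Optional[StaticMap] = None):
    """NDVI stack responding to lag/accumulated precipitation anomalies.

    Returns ``(ndvi_monthly, composites_or_None, truth)``.  When
    ``semimonthly`` is set, the optional pair of composites is built so
    that one equals the monthly value and the other carries a non-negative
    depression — a maximum-value composite recovers the monthly stack
    exactly.
    """
    axes = config.axes
    times = config.times
    months = np.asarray(times.month)
    base = (config.year_start, config.year_end)
    if not climate["precip"].times.equals(times):
        raise ValueError("climate stacks do not cover the configured years")

    p_ano = monthly_anomalies(climate["precip"], base).values
    t_ano = monthly_anomalies(climate["temp"], base).values
    r_ano = monthly_anomalies(climate["radiation"], base).values
    z_t = _standardize_by_month(t_ano, months)
    z_r = _standardize_by_month(r_ano, months)

    rng = config.rng("response")
    lag_f = rng.choice(np.asarray(config.lag_choices), size=axes.shape)
    cum_f = rng.choice(np.asarray(config.cum_choices), size=axes.shape)
    beta_f = np.full(axes.shape, float(config.beta))
    gamma_f = np.full(axes.shape, float(config.gamma))
    delta_f = np.full(axes.shape, float(config.delta))

    # one windowed-sum pass per (lag, cum) actually present, then gather
    z_acc = np.zeros((len(times),) + axes.shape)
    for lag in np.unique(lag_f):
        for cum in np.unique(cum_f[lag_f == lag]):
            px = (lag_f == lag) & (cum_f == cum)
            w = _window_sums(p_ano, int(lag), int(cum))
            z = _standardize_by_month(w, months)
            z_acc[:, px] = np.nan_to_num(z[:, px], nan=0.0)

    noise = config.noise_sd * config.rng("ndvi_noise").standard_normal(z_acc.shape)
    anomaly = (beta_f * z_acc + gamma_f * np.nan_to_num(z_t)
               + delta_f * np.nan_to_num(z_r) + noise)
    baseline = np.asarray(config.ndvi_baseline)[months - 1][:, None, None]
    ndvi_vals = np.clip(baseline + anomaly, -1.0, 1.0)
    ndvi = MonthlyRaster(axes, times, ndvi_vals, "ndvi")

    truth = SyntheticTruth(axes, lag_f.astype(int), cum_f.astype(int),
                           beta_f, gamma_f, delta_f, config.noise_sd,
                           zone_id=None if zones is None else np.asarray(zones.values))

    composites = None
    if semimonthly:
        depress = config.rng("semimonthly").uniform(0.0, 0.05, size=ndvi_vals.shape)
        low = np.clip(ndvi_vals - depress, -1.0, 1.0)
        composites = (MonthlyRaster(axes, times, ndvi_vals.copy(), "ndvi"),
                      MonthlyRaster(axes, times, low, "ndvi"))
    return ndvi, composites, truth


def _smooth_field(rng: np.random.Generator, shape, lo: float, hi: float,
                  sigma: float = 2.0) -> np.ndarray:
    raw = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=sigma, mode="nearest")
    span = raw.max() - raw.min()
    unit = (raw - raw.min()) / span if span > 0 else np.zeros(shape)
    return lo + (hi - lo) * unit


def generate_landscape(config: SyntheticConfig) -> dict[str, StaticMap]:
    """Categorical ecological-zone maps plus smooth continuous rasters."""
    from .attribution import eco_zone_intersect  # local import avoids a cycle

    axes = config.axes
    shape = axes.shape
    rng = config.rng("landscape")

    probs = np.asarray(config.landcover_probs)
    landcover = rng.choice(probs.size, size=shape, p=probs)
    # ecoregions as contiguous longitude bands
    bands = np.linspace(0, shape[1], config.n_ecoregions + 1).astype(int)
    ecoregion = np.zeros(shape, dtype=int)
    for b in range(config.n_ecoregions):
        ecoregion[:, bands[b]:bands[b + 1]] = b

    lc_map = StaticMap(axes, landcover, "landcover_class")
    er_map = StaticMap(axes, ecoregion, "ecoregion_id")
    ecozone = eco_zone_intersect(lc_map, er_map)

    builtup = (rng.random(shape) < config.builtup_fraction).astype(int)
    return {
        "landcover": lc_map,
        "ecoregion": er_map,
        "ecozone": ecozone,
        "elevation": StaticMap(axes, _smooth_field(rng, shape, 500.0, 3000.0), "elevation_m"),
        "cti": StaticMap(axes, _smooth_field(rng, shape, 2.0, 12.0), "cti"),
        "sbd": StaticMap(axes, _smooth_field(rng, shape, 0.9, 1.7), "sbd_g_cm3"),
        "pawc": StaticMap(axes, _smooth_field(rng, shape, 20.0, 250.0), "pawc_mm"),
        "builtup": StaticMap(axes, builtup, "builtup_flag"),
    }


def generate_dataset(config: SyntheticConfig, semimonthly: bool = False) -> dict:
    """Full bundle: climate stacks, landscape maps, NDVI and truth table."""
    climate = generate_climate(config)
    landscape = generate_landscape(config)
    ndvi, composites, truth = generate_ndvi(climate, config, semimonthly=semimonthly,
                                            zones=landscape["ecozone"])
    out = dict(climate)
    out.update(landscape)
    out["ndvi"] = ndvi
    out["truth"] = truth
    if composites is not None:
        out["ndvi_composites"] = composites
    return out
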