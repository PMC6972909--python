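"""End-to-end orchestration: one config drives generate -> preprocess ->
indices -> temporal -> seasonal -> attribution, with a hashed manifest.

The shipped defaults reproduce the full synthetic experiment on a
20 x 20 grid, 1981-2015, with the analysis parameters used throughout the
package: alpha = 0.05, bins of 50 mm MAP / 0.025 FPD / 1 PCI, minimum bin
and zone populations of 10, and index thresholds 150-500 mm MAP,
0.075-0.275 FPD, 19-23 PCI.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import attribution as attr
from .grids import (read_monthly_stack, read_static_map, write_monthly_stack,
                    write_static_map)
from .indices import PrecipIndexMaps, ThresholdRanges, threshold_select
from .preprocess import (area_weighted_mean, monthly_anomalies, ols_trend,
                         qc_mask, seasonal_aggregate)
from .seasonal import SeasonalResponseModel
from .synthetic import SyntheticConfig, generate_dataset
from .temporal import TemporalResponseModel

__all__ = ["PipelineConfig", "default_config", "validate_config", "run_full"]

log = logging.getLogger("vegresponse")


@dataclass
class PipelineConfig:
    """Everything a full run needs; exactly one of synthetic/inputs set."""

    synthetic: SyntheticConfig | None = field(default_factory=SyntheticConfig)
    inputs: dict | None = None          # paths: ndvi, precip, temp, radiation,
                                        # wet_days, builtup, landcover, ecoregion, ...
    base_period: tuple[int, int] = (1982, 2015)
    analysis_years: tuple[int, int] = (1982, 2015)
    alpha: float = 0.05
    controls_window: str = "matched"
    thresholds: ThresholdRanges = field(default_factory=ThresholdRanges)
    bin_widths: dict = field(default_factory=lambda: dict(attr.DEFAULT_BIN_WIDTHS))
    min_count: int = 10
    seed: int = 0

    def to_dict(self) -> dict:
        d = {
            "base_period": list(self.base_period),
            "analysis_years": list(self.analysis_years),
            "alpha": self.alpha,
            "controls_window": self.controls_window,
            "thresholds": {
                "map": list(self.thresholds.map_range),
                "fpd": list(self.thresholds.fpd_range),
                "pci": list(self.thresholds.pci_range),
            },
            "bin_widths": dict(self.bin_widths),
            "min_count": self.min_count,
            "seed": self.seed,
        }
        if self.synthetic is not None:
            syn = dataclasses.asdict(self.synthetic)
            d["synthetic"] = {k: list(v) if isinstance(v, tuple) else v
                              for k, v in syn.items()}
        if self.inputs is not None:
            d["inputs"] = dict(self.inputs)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        kw: dict = {}
        if "synthetic" in d and d["synthetic"] is not None:
            syn = dict(d["synthetic"])
            for key, val in syn.items():
                if isinstance(val, list):
                    syn[key] = tuple(val)
            kw["synthetic"] = SyntheticConfig(**syn)
        else:
            kw["synthetic"] = None
        kw["inputs"] = d.get("inputs")
        for key in ("alpha", "controls_window", "min_count", "seed"):
            if key in d:
                kw[key] = d[key]
        for key in ("base_period", "analysis_years"):
            if key in d:
                kw[key] = tuple(d[key])
        if "thresholds" in d:
            t = d["thresholds"]
            kw["thresholds"] = ThresholdRanges(tuple(t["map"]), tuple(t["fpd"]),
                                               tuple(t["pci"]))
        if "bin_widths" in d:
            kw["bin_widths"] = dict(d["bin_widths"])
        return cls(**kw)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def default_config(seed: int = 0) -> PipelineConfig:
    """The shipped synthetic-experiment configuration."""
    cfg = PipelineConfig()
    cfg.seed = seed
    cfg.synthetic = replace(cfg.synthetic, seed=seed)
    return cfg


def validate_config(config: PipelineConfig) -> list[str]:
    """Range/consistency checks; returns human-readable failure messages."""
    failures: list[str] = []
    if (config.synthetic is None) == (config.inputs is None):
        failures.append("exactly one of {synthetic block, input paths} must be set")
    if not 0 < config.alpha < 1:
        failures.append(f"alpha out of (0,1): {config.alpha}")
    if config.controls_window not in ("matched", "lag0"):
        failures.append(f"controls_window must be matched|lag0: {config.controls_window}")
    for name, rng in (("map", config.thresholds.map_range),
                      ("fpd", config.thresholds.fpd_range),
                      ("pci", config.thresholds.pci_range)):
        if not rng[0] < rng[1]:
            failures.append(f"threshold range {name}: lower >= upper")
    if config.min_count < 1:
        failures.append("min_count must be >= 1")
    for name, w in config.bin_widths.items():
        if w <= 0:
            failures.append(f"bin width {name} must be positive")
    if config.base_period[0] > config.base_period[1]:
        failures.append("base_period reversed")
    if config.inputs is not None:
        for key in ("ndvi", "precip", "temp", "radiation", "wet_days"):
            if key not in config.inputs:
                failures.append(f"inputs missing required path {key!r}")
            elif not Path(config.inputs[key]).exists():
                failures.append(f"input file not found: {config.inputs[key]}")
    return failures


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _load_inputs(config: PipelineConfig, out: Path) -> dict:
    if config.synthetic is not None:
        syn = replace(config.synthetic, seed=config.seed)
        log.info("generating synthetic dataset (%dx%d, %d-%d, seed %d)",
                 syn.n_lat, syn.n_lon, syn.year_start, syn.year_end, syn.seed)
        data = generate_dataset(syn)
        inp = out / "inputs"
        inp.mkdir(parents=True, exist_ok=True)
        for key in ("ndvi", "precip", "temp", "radiation", "wet_days", "sunshine"):
            write_monthly_stack(data[key], inp / f"{key}.nc")
        for key in ("landcover", "ecoregion", "ecozone", "elevation",
                    "cti", "sbd", "pawc", "builtup"):
            write_static_map(data[key], inp / f"{key}.nc")
        data["truth"].write_csv(inp / "truth.csv")
        return data
    data = {}
    for key in ("ndvi", "precip", "temp", "radiation", "wet_days"):
        data[key] = read_monthly_stack(config.inputs[key], _VAR_OF[key])
    for key in ("landcover", "ecoregion", "builtup", "elevation", "cti", "sbd", "pawc"):
        if key in config.inputs:
            data[key] = read_static_map(config.inputs[key], _KIND_OF[key])
    if "landcover" in data and "ecoregion" in data:
        data["ecozone"] = attr.eco_zone_intersect(data["landcover"], data["ecoregion"])
    return data


_VAR_OF = {"ndvi": "ndvi", "precip": "precip_mm", "temp": "temp_C",
           "radiation": "radiation_MJ_m2_d", "wet_days": "wet_days"}
_KIND_OF = {"landcover": "landcover_class", "ecoregion": "ecoregion_id",
            "builtup": "builtup_flag", "elevation": "elevation_m", "cti": "cti",
            "sbd": "sbd_g_cm3", "pawc": "pawc_mm"}


def run_full(config: PipelineConfig, out_dir) -> dict:
    """Execute every stage and return the output manifest (also written).

    The manifest lists each produced file with a SHA-256 content hash plus
    the parameter echo — two runs with one config and seed must be
    identical.
    """
    failures = validate_config(config)
    if failures:
        raise ValueError("invalid config: " + "; ".join(failures))
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}

    def stage(name):
        timings[name] = time.perf_counter()

    def done(name):
        timings[name] = round(time.perf_counter() - timings[name], 3)
        log.info("stage %-18s %.2fs", name, timings[name])

    stage("inputs")
    data = _load_inputs(config, out)
    done("inputs")

    stage("preprocess")
    ndvi = data["ndvi"]
    builtup = data.get("builtup")
    mask = qc_mask(ndvi.select_years(*config.analysis_years), builtup=builtup)
    anos = {k: monthly_anomalies(data[k], config.base_period)
            for k in ("ndvi", "precip", "temp", "radiation")}
    growing = seasonal_aggregate(ndvi.select_years(*config.analysis_years), "growing")
    series = area_weighted_mean(growing, mask)
    trend = ols_trend(series)
    pd.DataFrame({"year": series.index, "ndvi": series.values}).to_csv(
        out / "growing_season_series.csv", index=False)
    with open(out / "trend.json", "w") as fh:
        json.dump({"slope_per_yr": trend.slope, "intercept": trend.intercept,
                   "r_squared": trend.r_squared, "p_value": trend.p_value}, fh,
                  indent=1, sort_keys=True)
    done("preprocess")

    stage("indices")
    index_maps = PrecipIndexMaps.from_stacks(data["precip"], data["wet_days"],
                                             config.analysis_years)
    overlap = threshold_select(index_maps, config.thresholds, mode="overlap")
    idx_frame = pd.DataFrame({
        "map_mm": index_maps.map_mm.ravel(), "fpd": index_maps.fpd.ravel(),
        "pci": index_maps.pci.ravel(), "in_overlap": overlap.valid.ravel().astype(int),
    })
    idx_frame.to_csv(out / "precip_indices.csv", index=False)
    done("indices")

    stage("temporal")
    tmodel = TemporalResponseModel(anos["ndvi"], anos["precip"], anos["temp"],
                                   anos["radiation"], mask=mask,
                                   years=config.analysis_years, alpha=config.alpha,
                                   controls_window=config.controls_window)
    tres = tmodel.fit()
    tres.to_netcdf(out / "temporal_response.nc")
    tres.lag_share_table().to_csv(out / "lag_shares.csv")
    tres.cum_share_table().to_csv(out / "cum_shares.csv")
    (out / "temporal_summary.txt").write_text(tres.summary() + "\n")
    done("temporal")

    stage("seasonal")
    smodel = SeasonalResponseModel(anos["ndvi"], anos["precip"], anos["temp"],
                                   anos["radiation"], mask=mask,
                                   years=config.analysis_years, alpha=config.alpha)
    sres = smodel.fit()
    sres.to_netcdf(out / "seasonal_response.nc")
    (out / "seasonal_summary.txt").write_text(sres.summary() + "\n")
    done("seasonal")

    stage("attribution")
    rmax = tres.r_max_masked()
    covs = {"map": index_maps.map_mm, "fpd": index_maps.fpd, "pci": index_maps.pci}
    for key in ("elevation", "cti", "sbd", "pawc"):
        if key in data:
            covs[key] = np.asarray(data[key].values, dtype=float)
    profiles = []
    for name, cov in covs.items():
        prof = attr.binned_average(rmax, cov, config.bin_widths[name],
                                   min_count=config.min_count, covariate_name=name)
        frame = prof.to_frame()
        frame.insert(0, "covariate", name)
        profiles.append(frame)
    pd.concat(profiles, ignore_index=True).to_csv(out / "binned_profiles.csv",
                                                  index=False)
    n_years = config.analysis_years[1] - config.analysis_years[0] + 1
    if "ecozone" in data:
        boxes = attr.zone_boxstats(rmax, data["ecozone"], selection=overlap,
                                   min_pixels=config.min_count, n_sample=n_years)
        pd.DataFrame([b.as_dict() for b in boxes]).to_csv(
            out / "zone_boxstats.csv", index=False)
        attr.zone_temporal_medians(tres.r_j, data["ecozone"], selection=overlap,
                                   min_pixels=config.min_count).to_csv(
            out / "zone_temporal_medians.csv")
    done("attribution")

    manifest = {
        "config": config.to_dict(),
        "stage_seconds": timings,
        "files": {str(p.relative_to(out)): _sha256(p) for p in sorted(out.rglob("*"))
                  if p.is_file() and p.name != "manifest.json"},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
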