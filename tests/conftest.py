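import numpy as np
import pandas as pd
import pytest

from vegresponse import (GridAxes, MonthlyRaster, SyntheticConfig,
                         generate_dataset, monthly_anomalies, qc_mask)


@pytest.fixture(scope="session")
def small_config():
    return SyntheticConfig(n_lat=8, n_lon=8, seed=42)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return generate_dataset(small_config)


@pytest.fixture(scope="session")
def small_analysis(small_dataset):
    """Anomaly stacks + QC mask for the small synthetic dataset."""
    data = small_dataset
    mask = qc_mask(data["ndvi"].select_years(1982, 2015), builtup=data["builtup"])
    anos = {k: monthly_anomalies(data[k], (1982, 2015))
            for k in ("ndvi", "precip", "temp", "radiation")}
    return {"mask": mask, "anos": anos, "truth": data["truth"], "data": data}


@pytest.fixture()
def rng():
    return np.random.default_rng(7)


def make_raster(values, variable="precip_mm", start="1982-01", cell=0.5):
    """Small helper: wrap a (T, nlat, nlon) array as a MonthlyRaster."""
    values = np.asarray(values, dtype=float)
    t, nlat, nlon = values.shape
    axes = GridAxes.regular(nlat, nlon, cell)
    times = pd.period_range(start, periods=t, freq="M")
    return MonthlyRaster(axes, times, values, variable)


def make_anomaly(values, variable="precip_mm", start="1982-01", cell=0.5):
    """Wrap an array as an AnomalyRaster (no physical range checks)."""
    from vegresponse import AnomalyRaster

    values = np.asarray(values, dtype=float)
    t, nlat, nlon = values.shape
    axes = GridAxes.regular(nlat, nlon, cell)
    times = pd.period_range(start, periods=t, freq="M")
    return AnomalyRaster(axes, times, values, variable)
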