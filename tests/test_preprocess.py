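import numpy as np
import pandas as pd
import pytest

from vegresponse import (GridAxes, MonthlyRaster, StaticMap, accumulate_window,
                         area_weighted_mean, monthly_anomalies, mvc_monthly,
                         ols_trend, qc_mask, seasonal_aggregate)
from vegresponse.preprocess import SEASONS, YearlyField

from conftest import make_anomaly, make_raster


class TestMvc:
    def test_max_of_two_composites(self):
        a = make_raster(np.full((1, 1, 1), 0.41), variable="ndvi")
        b = make_raster(np.full((1, 1, 1), 0.38), variable="ndvi")
        assert mvc_monthly([a, b]).values[0, 0, 0] == 0.41

    def test_missing_composite_skipped(self):
        a = make_raster(np.full((1, 1, 1), np.nan), variable="ndvi")
        b = make_raster(np.full((1, 1, 1), 0.38), variable="ndvi")
        assert mvc_monthly([a, b]).values[0, 0, 0] == 0.38

    def test_matches_elementwise_max_oracle(self, rng):
        va = rng.uniform(-0.1, 0.9, size=(6, 3, 3))
        vb = rng.uniform(-0.1, 0.9, size=(6, 3, 3))
        out = mvc_monthly([make_raster(va, variable="ndvi"),
                           make_raster(vb, variable="ndvi")])
        assert np.array_equal(out.values, np.maximum(va, vb))

    def test_recovers_monthly_from_synthetic_pair(self, small_config):
        from vegresponse import generate_climate, generate_ndvi
        climate = generate_climate(small_config)
        ndvi, comps, _ = generate_ndvi(climate, small_config, semimonthly=True)
        out = mvc_monthly(list(comps))
        assert np.array_equal(out.values, ndvi.values)


class TestQcMask:
    def _ndvi(self, n_months=12):
        vals = np.full((n_months, 2, 2), 0.4)
        return vals

    def test_abnormal_growing_season_value_invalidates(self):
        vals = self._ndvi()
        vals[6, 0, 0] = -0.05  # July
        mask = qc_mask(make_raster(vals, variable="ndvi"))
        assert not mask.valid[0, 0] and mask.valid[1, 1]

    def test_builtup_pixel_excluded_despite_clean_ndvi(self):
        vals = self._ndvi()
        ndvi = make_raster(vals, variable="ndvi")
        flags = np.zeros((2, 2), int)
        flags[1, 0] = 1
        mask = qc_mask(ndvi, builtup=StaticMap(ndvi.axes, flags, "builtup_flag"))
        assert not mask.valid[1, 0] and mask.valid[0, 0]

    def test_missing_required_month_invalidates(self):
        vals = self._ndvi()
        vals[5, 1, 1] = np.nan
        mask = qc_mask(make_raster(vals, variable="ndvi"))
        assert not mask.valid[1, 1]

    def test_all_clean_pixel_valid(self):
        assert qc_mask(make_raster(self._ndvi(), variable="ndvi")).valid.all()


class TestMonthlyAnomalies:
    def test_constant_series_gives_zero(self):
        r = make_raster(np.full((24, 2, 2), 5.0))
        out = monthly_anomalies(r, (1982, 1983))
        assert np.allclose(out.values, 0.0)

    def test_two_year_july_arithmetic(self):
        vals = np.zeros((24, 1, 1))
        vals[6], vals[18] = 1.0, 3.0  # Julys of 1982, 1983
        out = monthly_anomalies(make_raster(vals), (1982, 1983))
        assert out.values[6, 0, 0] == -1.0 and out.values[18, 0, 0] == 1.0

    def test_base_period_sums_to_zero(self, rng):
        r = make_raster(np.abs(rng.normal(20, 5, size=(48, 3, 3))))
        out = monthly_anomalies(r, (1982, 1985))
        for m in range(12):
            sums = out.values[m::12].sum(axis=0)
            assert np.all(np.abs(sums) < 1e-9)

    def test_pre_base_years_use_base_climatology(self, rng):
        vals = np.abs(rng.normal(20, 5, size=(36, 2, 2)))
        r = make_raster(vals, start="1981-01")
        out = monthly_anomalies(r, (1982, 1983))
        clim_jan = vals[12::12][:2].mean(axis=0)  # Jan 1982, Jan 1983
        assert np.allclose(out.values[0], vals[0] - clim_jan)

    def test_idempotence(self, rng):
        r = make_raster(np.abs(rng.normal(20, 5, size=(48, 2, 2))))
        a1 = monthly_anomalies(r, (1982, 1985))
        a2 = monthly_anomalies(a1, (1982, 1985))
        assert np.allclose(a1.values, a2.values, atol=1e-12)

    def test_short_base_period_rejected(self):
        r = make_raster(np.zeros((24, 1, 1)))
        with pytest.raises(ValueError):
            monthly_anomalies(r, (1982, 1982))


class TestSeasonalAggregate:
    def test_spring_mean(self):
        vals = np.zeros((12, 1, 1))
        vals[3], vals[4] = 0.2, 0.4  # Apr, May
        out = seasonal_aggregate(make_raster(vals, variable="ndvi"), "spring")
        assert out.values[0, 0, 0] == pytest.approx(0.3)

    def test_summer_precip_sum(self):
        vals = np.zeros((12, 1, 1))
        vals[5], vals[6], vals[7] = 10.0, 20.0, 30.0
        out = seasonal_aggregate(make_raster(vals), "summer", statistic="sum")
        assert out.values[0, 0, 0] == 60.0

    def test_first_year_winter_missing(self):
        r = make_raster(np.ones((24, 1, 1)))
        out = seasonal_aggregate(r, "winter")
        assert np.isnan(out.values[0, 0, 0]) and np.isfinite(out.values[1, 0, 0])

    def test_winter_crosses_year_boundary(self):
        vals = np.zeros((24, 1, 1))
        vals[10], vals[11] = 5.0, 5.0            # Nov, Dec 1982
        vals[12], vals[13], vals[14] = 1.0, 1.0, 1.0  # Jan-Mar 1983
        out = seasonal_aggregate(make_raster(vals), "winter", statistic="sum")
        assert out.values[1, 0, 0] == 13.0

    def test_matches_loop_oracle(self, rng):
        vals = np.abs(rng.normal(10, 3, size=(36, 2, 2)))
        r = make_raster(vals)
        out = seasonal_aggregate(r, "autumn", statistic="mean")
        for yi in range(3):
            expect = vals[yi * 12 + 8: yi * 12 + 10].mean(axis=0)  # Sep, Oct
            assert np.allclose(out.values[yi], expect, atol=1e-12)

    def test_growing_mean_is_month_weighted_season_means(self, rng):
        vals = np.abs(rng.normal(0.4, 0.05, size=(12, 2, 2)))
        r = make_raster(np.clip(vals, 0, 1), variable="ndvi")
        g = seasonal_aggregate(r, "growing").values[0]
        s = {name: seasonal_aggregate(r, name).values[0]
             for name in ("spring", "summer", "autumn")}
        expect = (2 * s["spring"] + 3 * s["summer"] + 2 * s["autumn"]) / 7
        assert np.allclose(g, expect, atol=1e-12)


class TestAccumulateWindow:
    @pytest.fixture()
    def ano(self, rng):
        return make_anomaly(rng.normal(size=(48, 2, 2)), start="1981-01")

    def test_lag0_cum1_is_current_month(self, ano):
        out = accumulate_window(ano, 0, 1, at_month=7, at_year=1983)
        idx = ano.times.get_loc(pd.Period("1983-07", freq="M"))
        assert np.array_equal(out, ano.values[idx])

    def test_lag2_cum4_window_cells(self, ano):
        out = accumulate_window(ano, 2, 4, at_month=7, at_year=1983)
        t = ano.times.get_loc(pd.Period("1983-07", freq="M"))
        expect = ano.values[t - 2] + ano.values[t - 3] + ano.values[t - 4] + ano.values[t - 5]
        assert np.allclose(out, expect, atol=1e-12)

    def test_lag3_cum6_reaches_eight_back(self, ano):
        out = accumulate_window(ano, 3, 6, at_month=4, at_year=1982)
        t = ano.times.get_loc(pd.Period("1982-04", freq="M"))
        expect = sum(ano.values[t - k] for k in range(3, 9))
        assert np.allclose(out, expect, atol=1e-12)

    def test_window_before_record_rejected(self, ano):
        with pytest.raises(ValueError):
            accumulate_window(ano, 3, 6, at_month=4, at_year=1981)

    def test_additivity_over_unit_windows(self, ano):
        for lag, cum in ((0, 3), (1, 4), (2, 2), (3, 6)):
            whole = accumulate_window(ano, lag, cum, at_month=8, at_year=1984)
            parts = sum(accumulate_window(ano, k, 1, at_month=8, at_year=1984)
                        for k in range(lag, lag + cum))
            assert np.allclose(whole, parts, atol=1e-10)


class TestAreaWeightedMean:
    def test_constant_field_independent_of_weights(self):
        r = make_raster(np.full((3, 4, 4), 2.5))
        s = area_weighted_mean(r)
        assert np.allclose(s.values, 2.5)

    def test_two_pixel_cosine_weighting(self):
        axes = GridAxes(np.array([0.0]), np.array([0.0, 0.5]), 0.5)
        vals = np.zeros((1, 1, 2))
        vals[0, 0, 0] = 1.0
        # replace latitudes: one pixel at 0N, one at 60N via a 2x1 grid
        axes = GridAxes(np.array([60.0, 0.0]), np.array([0.0]), 60.0)
        vals = np.array([[[0.0], [1.0]]])
        r = MonthlyRaster(axes, [(1982, 1)], vals, "precip_mm")
        s = area_weighted_mean(r)
        assert s.values[0] == pytest.approx(np.cos(0) / (np.cos(0) + 0.5), abs=1e-12)

    def test_matches_explicit_sum_oracle(self, rng):
        vals = np.abs(rng.normal(size=(2, 5, 3)))
        r = make_raster(vals)
        w = np.cos(np.deg2rad(r.axes.lat))[:, None] * np.ones((5, 3))
        expect = (vals * w).sum(axis=(1, 2)) / w.sum()
        assert np.allclose(area_weighted_mean(r).values, expect, atol=1e-12)

    def test_no_valid_pixels_rejected(self):
        r = make_raster(np.full((1, 2, 2), np.nan))
        with pytest.raises(ValueError):
            area_weighted_mean(r)


class TestOlsTrend:
    def test_perfect_line(self):
        res = ols_trend(pd.Series([1.0, 2.0, 3.0], index=[2000, 2001, 2002]))
        assert res.slope == pytest.approx(1.0, abs=1e-12)
        assert res.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_constant_series(self):
        res = ols_trend(pd.Series([2.0] * 5, index=range(2000, 2005)))
        assert res.slope == 0.0 and res.r_squared == 0.0

    def test_matches_normal_equations_oracle(self, rng):
        y = rng.normal(size=20)
        x = np.arange(1982, 2002, dtype=float)
        slope = ((x - x.mean()) * (y - y.mean())).sum() / ((x - x.mean()) ** 2).sum()
        res = ols_trend(pd.Series(y, index=x.astype(int)))
        assert res.slope == pytest.approx(slope, abs=1e-10)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            ols_trend(pd.Series([1.0, 2.0], index=[2000, 2001]))
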