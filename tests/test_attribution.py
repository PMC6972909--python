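"""Binned gradients, ecological zones and zonal statistics."""

import numpy as np
import pandas as pd
import pytest

from vegresponse import GridAxes, StaticMap
from vegresponse.attribution import (binned_average, critical_r,
                                     eco_zone_intersect, zone_boxstats,
                                     zone_temporal_medians)
from vegresponse.grids import PixelMask


def _axes(n=20, m=20):
    return GridAxes.regular(n, m)


class TestBinnedAverage:
    def test_single_full_bin(self):
        vals = np.full((3, 4), 0.5)
        cov = np.full((3, 4), 125.0)
        prof = binned_average(vals, cov, 50.0, min_count=10)
        assert prof.included.sum() == 1
        k = prof.peak_bin
        assert prof.mean[k] == 0.5 and prof.sd[k] == 0.0 and prof.count[k] == 12

    def test_bin_below_min_count_excluded(self):
        vals = np.full((3, 3), 0.5)
        cov = np.full((3, 3), 125.0)
        prof = binned_average(vals, cov, 50.0, min_count=10)
        assert not prof.included.any()
        assert np.isnan(prof.mean).all() and prof.count.sum() == 9

    def test_matches_loop_oracle(self, rng):
        vals = rng.normal(0.5, 0.2, size=(20, 20))
        cov = rng.uniform(0, 800, size=(20, 20))
        prof = binned_average(vals, cov, 50.0, min_count=10)
        for b in range(len(prof.bin_edges) - 1):
            lo, hi = prof.bin_edges[b], prof.bin_edges[b + 1]
            sel = (cov >= lo) & (cov < hi)
            assert prof.count[b] == sel.sum()
            if sel.sum() >= 10:
                assert prof.mean[b] == pytest.approx(vals[sel].mean(), abs=1e-12)
                assert prof.sd[b] == pytest.approx(vals[sel].std(ddof=0), abs=1e-12)

    def test_counts_partition_contributing_pixels(self, rng):
        vals = rng.normal(size=(15, 15))
        cov = rng.uniform(0, 10, size=(15, 15))
        vals[0, :5] = np.nan
        prof = binned_average(vals, cov, 1.0, min_count=3)
        assert prof.count.sum() == np.isfinite(vals).sum()

    def test_order_invariance(self, rng):
        vals = rng.normal(size=400)
        cov = rng.uniform(0, 20, size=400)
        p1 = binned_average(vals.reshape(20, 20), cov.reshape(20, 20), 2.0)
        perm = rng.permutation(400)
        p2 = binned_average(vals[perm].reshape(20, 20), cov[perm].reshape(20, 20), 2.0)
        assert np.allclose(p1.mean, p2.mean, equal_nan=True)
        assert np.array_equal(p1.count, p2.count)

    def test_constructed_rise_then_fall_peak_recovered(self):
        # r_max rises to a peak at the 250-300 mm bin then falls
        rng = np.random.default_rng(0)
        cov = rng.uniform(0, 600, size=(40, 40))
        peak = 275.0
        vals = 0.8 - 0.9 * ((cov - peak) / 600.0) ** 2 + rng.normal(0, 0.01, cov.shape)
        prof = binned_average(vals, cov, 50.0, min_count=10)
        assert prof.bin_edges[prof.peak_bin] == 250.0

    def test_selection_mask_respected(self, rng):
        vals = rng.normal(size=(4, 4))
        cov = np.full((4, 4), 10.0)
        sel = PixelMask(_axes(4, 4), np.zeros((4, 4), bool))
        prof = binned_average(vals, cov, 5.0, selection=sel)
        assert prof.count.sum() == 0


class TestEcoZoneIntersect:
    def test_fully_crossed_classes(self):
        axes = _axes(2, 2)
        lc = StaticMap(axes, np.array([[0, 0], [1, 1]]), "landcover_class")
        er = StaticMap(axes, np.array([[0, 1], [0, 1]]), "ecoregion_id")
        zones = eco_zone_intersect(lc, er)
        assert len(np.unique(zones.values)) == 4
        assert len(zones.code_table) == 4

    def test_class_in_single_ecoregion(self):
        axes = _axes(2, 2)
        lc = StaticMap(axes, np.array([[0, 0], [1, 1]]), "landcover_class")
        er = StaticMap(axes, np.zeros((2, 2), int), "ecoregion_id")
        zones = eco_zone_intersect(lc, er)
        assert len(np.unique(zones.values)) == 2

    def test_zone_count_equals_observed_pairs(self, rng):
        axes = _axes(10, 10)
        lc = StaticMap(axes, rng.integers(0, 4, (10, 10)), "landcover_class")
        er = StaticMap(axes, rng.integers(0, 3, (10, 10)), "ecoregion_id")
        zones = eco_zone_intersect(lc, er)
        pairs = {(int(a), int(b)) for a, b in
                 zip(lc.values.ravel(), er.values.ravel())}
        assert len(np.unique(zones.values)) == len(pairs)


class TestZoneBoxstats:
    def _zones(self, codes):
        n, m = codes.shape
        return StaticMap(GridAxes.regular(n, m), codes, "ecozone_id")

    def test_identical_values_collapse_quantiles(self):
        codes = np.zeros((3, 4), int)
        vals = np.full((3, 4), 0.7)
        (summary,) = zone_boxstats(vals, self._zones(codes))
        assert summary.p5 == summary.p25 == summary.p50 == summary.p75 == summary.p95 == 0.7
        assert summary.count == 12

    def test_small_zone_omitted(self):
        codes = np.zeros((3, 4), int)
        codes[0, :3] = 1  # zone 1 has 3 pixels, zone 0 has 9
        vals = np.random.default_rng(0).normal(size=(3, 4))
        out = zone_boxstats(vals, self._zones(codes), min_pixels=5)
        assert [s.zone_id for s in out] == [0]

    def test_matches_sorted_quantile_oracle(self, rng):
        codes = rng.integers(0, 3, (20, 20))
        vals = rng.normal(size=(20, 20))
        out = zone_boxstats(vals, self._zones(codes))
        for s in out:
            zvals = np.sort(vals[codes == s.zone_id])
            for q, attr in ((0.05, "p5"), (0.25, "p25"), (0.5, "p50"),
                            (0.75, "p75"), (0.95, "p95")):
                # linear interpolation between order statistics
                h = (zvals.size - 1) * q
                lo = int(np.floor(h))
                expect = zvals[lo] + (h - lo) * (zvals[min(lo + 1, zvals.size - 1)] - zvals[lo])
                assert getattr(s, attr) == pytest.approx(expect, abs=1e-12)

    def test_quantiles_monotone(self, rng):
        codes = rng.integers(0, 2, (10, 10))
        vals = rng.normal(size=(10, 10))
        for s in zone_boxstats(vals, self._zones(codes)):
            assert s.p5 <= s.p25 <= s.p50 <= s.p75 <= s.p95

    def test_permutation_invariance(self, rng):
        codes = rng.integers(0, 2, (10, 10))
        vals = rng.normal(size=(10, 10))
        a = zone_boxstats(vals, self._zones(codes))
        perm = rng.permutation(100)
        b = zone_boxstats(vals.ravel()[perm].reshape(10, 10),
                          self._zones(codes.ravel()[perm].reshape(10, 10)))
        for x, y in zip(a, b):
            assert x.as_dict() == y.as_dict()


class TestZoneTemporalMedians:
    def test_single_pixel_zone_equals_its_profile(self, rng):
        r_j = rng.uniform(-1, 1, size=(24, 3, 3))
        codes = np.zeros((3, 3), int)
        codes[1, 1] = 5
        zones = StaticMap(GridAxes.regular(3, 3), codes, "ecozone_id")
        out = zone_temporal_medians(r_j, zones, min_pixels=1)
        assert np.allclose(out.loc[5].values, r_j[:, 1, 1])

    def test_matches_loop_median_oracle(self, rng):
        r_j = rng.uniform(-1, 1, size=(24, 12, 12))
        codes = rng.integers(0, 3, (12, 12))
        zones = StaticMap(GridAxes.regular(12, 12), codes, "ecozone_id")
        out = zone_temporal_medians(r_j, zones, min_pixels=1)
        for zid in out.index:
            sel = codes == zid
            for jx in range(24):
                assert out.loc[zid].iloc[jx] == pytest.approx(
                    np.median(r_j[jx][sel]), abs=1e-12)

    def test_uniform_truth_zone_peaks_at_true_combo(self):
        """A zone seeded homogeneously with (lag, cum) = (1, 2) shows its
        24-profile maximum at that combination."""
        from dataclasses import replace
        from vegresponse import (SyntheticConfig, TemporalResponseModel,
                                 generate_dataset, monthly_anomalies)
        cfg = SyntheticConfig(n_lat=5, n_lon=5, seed=13, builtup_fraction=0.0,
                              lag_choices=(1,), cum_choices=(2,))
        data = generate_dataset(cfg)
        anos = {k: monthly_anomalies(data[k], (1982, 2015))
                for k in ("ndvi", "precip", "temp", "radiation")}
        res = TemporalResponseModel(anos["ndvi"], anos["precip"], anos["temp"],
                                    anos["radiation"]).fit()
        zones = StaticMap(data["ndvi"].axes, np.zeros((5, 5), int), "ecozone_id")
        out = zone_temporal_medians(res.r_j, zones)
        j_true = 1 * 6 + 2  # lag-major index of (lag 1, cum 2)
        assert out.loc[0].idxmax() == f"j{j_true}"


class TestPlotting:
    def test_renders_profile_boxes_and_medians(self, rng, tmp_path):
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        from vegresponse.plotting import (plot_binned_profile, plot_zone_boxes,
                                          plot_zone_temporal_profiles)
        vals = rng.normal(0.5, 0.1, size=(20, 20))
        cov = rng.uniform(0, 500, size=(20, 20))
        prof = binned_average(vals, cov, 50.0)
        codes = rng.integers(0, 2, (20, 20))
        zones = StaticMap(GridAxes.regular(20, 20), codes, "ecozone_id")
        boxes = zone_boxstats(vals, zones)
        med = zone_temporal_medians(rng.uniform(-1, 1, (24, 20, 20)), zones)
        for fn, arg in ((plot_binned_profile, prof), (plot_zone_boxes, boxes),
                        (plot_zone_temporal_profiles, med)):
            fig, ax = plt.subplots()
            fn(arg, ax=ax)
            fig.savefig(tmp_path / f"{fn.__name__}.png")
            plt.close(fig)


class TestCriticalR:
    def test_round_trip_and_limits(self):
        from vegresponse import significance
        r = critical_r(0.05, 34, 2)
        assert significance(r, 34, 2)[1] == pytest.approx(0.05, abs=1e-9)
        assert critical_r(0.999, 34, 2) < 1e-3

    def test_decreases_with_sample_size(self):
        rs = [critical_r(0.05, n, 2) for n in (8, 16, 34, 100)]
        assert all(a > b for a, b in zip(rs, rs[1:]))
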