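"""Temporal/spatial covariance, ROI contingency, regressions, fish counts."""
import math

import numpy as np
import pandas as pd
import pytest

import bowerkit as bk
from conftest import make_series


def ev_table(rows):
    return pd.DataFrame(rows, columns=["timestamp_s", "category"])


class TestBinTemporal:
    def _series(self):
        grids = [np.full((10, 10), 580.0)]
        # 1 cm drop over a 100-px patch during the second hour
        g = grids[0].copy()
        g[0:10, 0:10] -= 0.0
        grids = [np.full((10, 10), 580.0) for _ in range(4)]
        for k in (2, 3):
            grids[k] = grids[k].copy()
            grids[k][2:7, 2:7] -= 10.0
        return make_series(grids, np.arange(4) * 3600.0)

    def test_counts_per_category_and_bin(self):
        events = ev_table([(100.0, "bower_scoop"), (200.0, "bower_scoop"),
                           (300.0, "bower_scoop"), (400.0, "quiver")])
        out = bk.bin_temporal(events, self._series())
        assert len(out) == 1
        assert out.loc[0, "bower_scoop"] == 3
        assert out.loc[0, "quiver"] == 1
        assert out.loc[0, "feed_scoop"] == 0

    def test_zero_behavior_bins_absent_even_with_depth_change(self):
        # depth changes in hour 1->2 but all events sit in hour 0
        events = ev_table([(100.0, "bower_scoop")])
        out = bk.bin_temporal(events, self._series())
        assert list(out["bin_start_s"]) == [0.0]

    def test_volume_column_reflects_bin_change(self):
        events = ev_table([(100.0, "quiver"), (3700.0, "quiver")])
        out = bk.bin_temporal(events, self._series())
        # hour 0 -> 1: static; hour 1 -> 2: 25 px x 1 cm x 0.01 = 0.25 cm^3
        assert out.loc[0, "depth_change"] == pytest.approx(0.0)
        assert out.loc[1, "depth_change"] == pytest.approx(0.25)


class TestCorrelate:
    def test_self_and_negated_columns(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=50)
        df = pd.DataFrame({"a": x, "b": x.copy(), "c": -x})
        res = bk.correlate(df)
        assert res.r.loc["a", "b"] == pytest.approx(1.0)
        assert res.r.loc["a", "c"] == pytest.approx(-1.0)

    def test_independent_noise_nearly_uncorrelated(self):
        rng = np.random.default_rng(42)
        df = pd.DataFrame({"a": rng.normal(size=1000),
                           "b": rng.normal(size=1000)})
        assert abs(bk.correlate(df).r.loc["a", "b"]) < 0.1

    def test_matrix_symmetric_with_unit_diagonal(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame(rng.normal(size=(40, 5)),
                          columns=list("abcde"))
        res = bk.correlate(df)
        assert np.allclose(res.r.values, res.r.values.T)
        assert np.allclose(np.diag(res.r.values), 1.0)
        assert np.all(np.abs(res.r.values) <= 1 + 1e-12)
        assert sorted(res.leaf_order) == list("abcde")

    def test_too_few_rows_rejected(self):
        df = pd.DataFrame({"a": [1.0, 2.0], "b": [2.0, 1.0]})
        with pytest.raises(ValueError):
            bk.correlate(df)

    def test_constant_column_dropped_with_warning(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame({"a": rng.normal(size=20),
                           "b": rng.normal(size=20),
                           "flat": np.ones(20)})
        with pytest.warns(UserWarning, match="flat"):
            res = bk.correlate(df)
        assert "flat" not in res.r.columns


class TestKdeSpatial:
    def test_bandwidth_is_half_mean_radius(self):
        dm = bk.kde_spatial(np.array([[5.0, 5.0], [8.0, 8.0]]),
                            np.array([8.0, 12.0]), (20, 20))
        assert dm.bandwidth == pytest.approx(5.0)

    def test_single_event_density_peaks_at_event_pixel(self):
        dm = bk.kde_spatial(np.array([[12.0, 7.0]]), np.array([6.0]),
                            (20, 30))
        r, c = np.unravel_index(np.argmax(dm.grid), dm.grid.shape)
        assert (r, c) == (7, 12)

    def test_two_separated_events_make_two_maxima(self):
        dm = bk.kde_spatial(np.array([[5.0, 5.0], [25.0, 25.0]]),
                            np.array([4.0]* 2), (30, 30))
        g = dm.grid
        interior = g[1:-1, 1:-1]
        local_max = ((interior >= g[:-2, 1:-1]) & (interior >= g[2:, 1:-1])
                     & (interior >= g[1:-1, :-2]) & (interior >= g[1:-1, 2:]))
        peaks = np.argwhere(local_max & (interior > 0.5 * interior.max()))
        assert len({tuple(p // 10) for p in peaks}) >= 2

    def test_zero_events_rejected(self):
        with pytest.raises(ValueError):
            bk.kde_spatial(np.empty((0, 2)), np.array([]), (10, 10))


class TestSpatialCorrelation:
    def test_density_identical_to_change_correlates_perfectly(self):
        rng = np.random.default_rng(6)
        grid = np.abs(rng.normal(0, 1, (15, 15)))
        cmap = bk.HeightChangeMap(grid, (0, 1), "trial")
        dmaps = {"x": bk.DensityMap(grid.copy(), 1.0, 5, "x"),
                 "y": bk.DensityMap(rng.random((15, 15)), 1.0, 5, "y")}
        res = bk.spatial_correlation(dmaps, cmap)
        assert res.r.loc["x", "depth_change"] == pytest.approx(1.0)

    def test_nan_change_pixels_excluded(self):
        grid = np.outer(np.arange(10.0), np.ones(10))
        grid[0, :] = np.nan
        cmap = bk.HeightChangeMap(grid, (0, 1), "trial")
        dens = np.outer(np.arange(10.0), np.ones(10))
        dens[0, :] = -999.0  # would destroy the correlation if included
        other = np.random.default_rng(1).random((10, 10))
        res = bk.spatial_correlation(
            {"a": bk.DensityMap(dens, 1.0, 3), "b": bk.DensityMap(other, 1.0, 3)}, cmap)
        assert res.r.loc["a", "depth_change"] == pytest.approx(1.0)

    def test_all_nan_change_map_rejected(self):
        cmap = bk.HeightChangeMap(np.full((5, 5), np.nan), (0, 1), "trial")
        with pytest.raises(ValueError):
            bk.spatial_correlation(
                {"a": bk.DensityMap(np.ones((5, 5)), 1.0, 1)}, cmap)


def linked_table(rows):
    return pd.DataFrame(rows, columns=["timestamp_s", "category",
                                       "depth_x", "depth_y",
                                       "unlinked_reason"])


class TestRoiEventCounts:
    def _roi(self, shape=(10, 10)):
        mask = np.zeros(shape, dtype=bool)
        mask[:5, :5] = True
        return bk.BowerROI(mask=mask, sign=-1, interval=(0.0, 86400.0),
                           timescale="daily", label=1, centroid=(2.0, 2.0),
                           abs_volume_cm3=5.0)

    def test_perfect_association_chi2_is_twenty(self):
        rows = ([(10.0, "bower_scoop", 2.0, 2.0, "")] * 10
                + [(20.0, "bower_spit", 8.0, 8.0, "")] * 10)
        res = bk.roi_event_counts(linked_table(rows), {0: self._roi()})
        assert (res.scoops_in, res.spits_in) == (10, 0)
        assert (res.scoops_out, res.spits_out) == (0, 10)
        assert res.chi2 == pytest.approx(20.0)

    def test_counts_partition_linked_construction_events(self):
        rng = np.random.default_rng(8)
        rows = [(float(i), rng.choice(["bower_scoop", "bower_spit"]),
                 float(rng.integers(0, 10)), float(rng.integers(0, 10)), "")
                for i in range(60)]
        res = bk.roi_event_counts(linked_table(rows), {0: self._roi()})
        total = (res.scoops_in + res.scoops_out + res.spits_in
                 + res.spits_out)
        assert total == 60

    def test_equal_in_roi_counts_give_unit_ratio(self):
        rows = ([(10.0, "bower_scoop", 2.0, 2.0, "")] * 5
                + [(20.0, "bower_spit", 2.0, 2.0, "")] * 5)
        res = bk.roi_event_counts(linked_table(rows), {0: self._roi()})
        assert res.ratio == pytest.approx(1.0)

    def test_zero_denominator_reported_as_infinity(self):
        rows = [(10.0, "bower_scoop", 2.0, 2.0, "")] * 5
        res = bk.roi_event_counts(linked_table(rows), {0: self._roi()})
        assert math.isinf(res.ratio)


class TestScoopSpitRatioSummary:
    def test_reported_pit_digger_counts_average_to_fifteen(self):
        mean = bk.scoop_spit_ratio_summary(
            [(273, 20), (339, 16), (602, 60)], "scoop_over_spit")
        assert mean == pytest.approx((273 / 20 + 339 / 16 + 602 / 60) / 3)
        assert mean == pytest.approx(15.0, abs=0.1)

    def test_single_subject_ratio_passthrough(self):
        assert bk.scoop_spit_ratio_summary([(10, 5)],
                                           "scoop_over_spit") == 2.0

    def test_zero_denominator_subject_excluded(self):
        with pytest.warns(UserWarning, match="zero denominator"):
            mean = bk.scoop_spit_ratio_summary([(10, 0), (10, 5)],
                                               "scoop_over_spit")
        assert mean == 2.0


class TestHourlyRegression:
    def _series_and_events(self, counts, vol_per_event=2.0):
        """Hourly frames where a 200-px patch deepens by
        counts[i] * vol_per_event cm^3 during hour i."""
        g = np.full((20, 20), 580.0)
        grids, times, rows = [g.copy()], [0.0], []
        level = g.copy()
        for i, n in enumerate(counts):
            drop_cm = n * vol_per_event / (200 * 0.01)
            level = level.copy()
            level[:10, :20] += 10.0 * drop_cm  # distance up = height down
            grids.append(level.copy())
            times.append((i + 1) * 3600.0)
            for k in range(n):
                rows.append((i * 3600.0 + 100.0 + k, "bower_scoop"))
        series = make_series(grids, times,
                             lights_on=[(0.0, len(counts) * 3600.0)])
        return series, ev_table(rows)

    def test_perfect_line_recovers_slope_and_r2(self):
        series, events = self._series_and_events([1, 3, 2, 5, 4, 0])
        res = bk.hourly_regression(events, series, "bower_scoop",
                                   "depressed")
        assert res.slope == pytest.approx(2.0)
        assert res.intercept == pytest.approx(0.0, abs=1e-9)
        assert res.r2 == pytest.approx(1.0)

    def test_constant_counts_rejected(self):
        series, events = self._series_and_events([2, 2, 2, 2])
        with pytest.raises(ValueError, match="constant"):
            bk.hourly_regression(events, series, "bower_scoop", "depressed")

    def test_unrelated_category_gives_low_r2(self):
        series, events = self._series_and_events([1, 3, 2, 5, 4, 0, 2, 1])
        rng = np.random.default_rng(12)
        shuffled = events.copy()
        shuffled["timestamp_s"] = rng.permutation(
            shuffled["timestamp_s"].to_numpy() % 3600.0
        ) + rng.integers(0, 8, len(shuffled)) * 3600.0
        res = bk.hourly_regression(shuffled, series, "bower_scoop",
                                   "depressed")
        assert res.r2 < 0.5


class TestFishCountsByBehavior:
    def test_constant_counts_give_constant_means(self):
        events = ev_table([(10.0, "bower_scoop"), (20.0, "quiver"),
                           (30.0, "feed_scoop")])
        fish = pd.DataFrame({"timestamp_s": [10.0, 20.0, 30.0],
                             "count": [2, 2, 2]})
        res = bk.fish_counts_by_behavior(events, fish)
        assert res.coverage == 1.0
        assert (res.stats["mean"] == 2.0).all()

    def test_event_without_nearby_count_dropped(self):
        events = ev_table([(10.0, "quiver"), (500.0, "quiver")])
        fish = pd.DataFrame({"timestamp_s": [10.5], "count": [3]})
        res = bk.fish_counts_by_behavior(events, fish, max_gap_s=2.0)
        assert res.coverage == pytest.approx(0.5)
        assert len(res.joined) == 1
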