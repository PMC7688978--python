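"""Depth ingestion, interpolation, smoothing and change-map computation."""
import json

import numpy as np
import pytest

import bowerkit as bk
from bowerkit.depth import average_window, interpolate_islands
from conftest import make_series


def write_manifest(tmp_path, grids, timestamps, lights_on=None, rows=None,
                   cols=None):
    entries = []
    for i, (g, t) in enumerate(zip(grids, timestamps)):
        p = tmp_path / f"f{i}.txt.gz"
        np.savetxt(p, g)
        entries.append({"path": p.name, "timestamp_s": t})
    g0 = np.asarray(grids[0])
    man = {"rows": rows or g0.shape[0], "cols": cols or g0.shape[1],
           "frames": entries, "lights_on": lights_on or [],
           "pixel_footprint_cm2": 0.01}
    mp = tmp_path / "manifest.json"
    mp.write_text(json.dumps(man))
    return mp


class TestReadDepthSeries:
    def test_two_valid_frames_sorted(self, tmp_path):
        g = np.full((4, 5), 580.0)
        mp = write_manifest(tmp_path, [g, g + 1], [0.0, 300.0])
        series = bk.read_depth_series(mp)
        assert len(series.frames) == 2
        assert list(series.timestamps) == [0.0, 300.0]
        assert series.calibration.pixel_footprint_cm2 == 0.01

    def test_wrong_shape_rejected_by_name(self, tmp_path):
        mp = write_manifest(tmp_path, [np.full((4, 5), 580.0),
                                       np.full((3, 5), 580.0)],
                            [0.0, 300.0], rows=4, cols=5)
        with pytest.raises(ValueError, match="f1"):
            bk.read_depth_series(mp)

    def test_shuffled_timestamps_reordered_with_warning(self, tmp_path):
        mp = write_manifest(tmp_path, [np.full((2, 2), 500.0),
                                       np.full((2, 2), 510.0),
                                       np.full((2, 2), 520.0)],
                            [600.0, 0.0, 300.0])
        with pytest.warns(UserWarning, match="sorting"):
            series = bk.read_depth_series(mp)
        assert list(series.timestamps) == sorted([600.0, 0.0, 300.0])
        # the 510-valued frame carries timestamp 0 and must come first
        assert series.frames[0].grid[0, 0] == 510.0

    def test_missing_file_reported(self, tmp_path):
        mp = write_manifest(tmp_path, [np.full((2, 2), 500.0)], [0.0])
        man = json.loads(mp.read_text())
        man["frames"].append({"path": "absent.txt.gz", "timestamp_s": 300.0})
        mp.write_text(json.dumps(man))
        with pytest.raises(FileNotFoundError, match="absent"):
            bk.read_depth_series(mp)


class TestAverageWindow:
    def test_nan_ignoring_mean_per_pixel(self):
        frames = [bk.DepthFrame(np.array([[2.0, np.nan, np.nan]]), 0.0),
                  bk.DepthFrame(np.array([[4.0, 6.0, np.nan]]), 10.0),
                  bk.DepthFrame(np.array([[3.0, 8.0, np.nan]]), 20.0)]
        out = average_window(frames)
        assert out.grid[0, 0] == pytest.approx(3.0)
        assert out.grid[0, 1] == pytest.approx(7.0)  # mean of valid only
        assert np.isnan(out.grid[0, 2])              # missing everywhere
        assert out.timestamp == pytest.approx(10.0)  # window midpoint

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            average_window([])


class TestInterpolateIslands:
    def test_single_hole_takes_surrounding_value(self):
        g = np.full((5, 5), 100.0)
        g[2, 2] = np.nan
        out = interpolate_islands(bk.DepthFrame(g, 0.0), max_island_px=4)
        assert out.grid[2, 2] == pytest.approx(100.0)

    def test_island_on_planar_gradient_lies_on_plane(self):
        rr, cc = np.meshgrid(np.arange(10), np.arange(12), indexing="ij")
        plane = 500.0 + 2.0 * rr + 3.0 * cc
        g = plane.copy()
        for r, c in [(4, 5), (4, 6), (5, 5)]:
            g[r, c] = np.nan
        out = interpolate_islands(bk.DepthFrame(g, 0.0), max_island_px=10)
        assert np.allclose(out.grid, plane, atol=1e-9)

    def test_island_above_size_limit_untouched(self):
        g = np.full((8, 8), 100.0)
        g[2:4, 2:4] = np.nan  # 4-px island
        out = interpolate_islands(bk.DepthFrame(g, 0.0), max_island_px=3)
        assert np.isnan(out.grid[2:4, 2:4]).all()
        out2 = interpolate_islands(bk.DepthFrame(g, 0.0), max_island_px=4)
        assert not np.isnan(out2.grid).any()

    def test_valid_pixels_never_modified(self):
        rng = np.random.default_rng(0)
        g = 500.0 + rng.normal(0, 5, (20, 20))
        g[rng.random((20, 20)) < 0.2] = np.nan
        frame = bk.DepthFrame(g.copy(), 0.0)
        out = interpolate_islands(frame, max_island_px=50)
        valid = ~np.isnan(g)
        assert np.array_equal(out.grid[valid], g[valid])

    def test_all_missing_frame_warned_and_unchanged(self):
        g = np.full((3, 3), np.nan)
        with pytest.warns(UserWarning, match="entirely missing"):
            out = interpolate_islands(bk.DepthFrame(g, 0.0), 10)
        assert np.isnan(out.grid).all()


class TestSmoothSeries:
    def test_polynomial_fields_preserved(self):
        # quadratic in space and linear in time: exact for polyorder 2
        rr, cc = np.meshgrid(np.arange(9), np.arange(11), indexing="ij")
        base = 500.0 + 0.5 * rr + 0.2 * cc + 0.05 * rr * cc + 0.03 * cc ** 2
        grids = [base + 0.4 * k for k in range(7)]
        series = make_series(grids, np.arange(7) * 300.0)
        out = bk.smooth_series(series, temporal_window=5, spatial_window=5,
                               polyorder=2)
        for k in range(7):
            assert np.allclose(out.frames[k].grid, grids[k], atol=1e-4)

    def test_gappy_windows_fit_valid_entries_only(self):
        grids = [np.full((6, 6), 500.0 + k) for k in range(7)]
        grids[3] = grids[3].copy()
        grids[3][2, 2] = np.nan
        series = make_series(grids, np.arange(7) * 300.0)
        out = bk.smooth_series(series)
        # the temporal ramp is linear, so the gap is recovered exactly
        assert out.frames[3].grid[2, 2] == pytest.approx(503.0, abs=1e-6)

    def test_too_few_valid_samples_stay_missing(self):
        from bowerkit._sgolay import savgol_masked
        y = np.full(9, 500.0)
        y[[2, 3, 4, 5]] = np.nan  # windows around the gap keep < 3 samples
        out = savgol_masked(y, 5, 2)
        # the left edge window [0..4] keeps only 2 valid samples
        assert np.isnan(out[:6]).all()
        assert np.allclose(out[6:], 500.0)

    def test_invalid_window_combination_rejected(self):
        series = make_series([np.full((6, 6), 500.0)] * 5,
                             np.arange(5) * 300.0)
        with pytest.raises(ValueError):
            bk.smooth_series(series, temporal_window=4)
        with pytest.raises(ValueError):
            bk.smooth_series(series, temporal_window=3, polyorder=3)

    def test_short_series_skips_temporal_pass(self):
        series = make_series([np.full((7, 7), 500.0)] * 3,
                             np.arange(3) * 300.0)
        with pytest.warns(UserWarning, match="skipped"):
            out = bk.smooth_series(series, temporal_window=5)
        assert np.allclose(out.grid_stack(), 500.0)


class TestHeightChange:
    def test_sign_convention_sand_added_is_positive(self):
        series = make_series([np.full((3, 3), 580.0),
                              np.full((3, 3), 570.0)], [0.0, 300.0])
        cmap = bk.height_change(series, 0.0, 300.0)
        assert np.allclose(cmap.grid, 1.0)  # castle-like

    def test_identical_frames_give_zero_map(self):
        series = make_series([np.full((3, 3), 580.0)] * 2, [0.0, 300.0])
        assert np.allclose(bk.height_change(series, 0, 300).grid, 0.0)

    def test_missing_endpoint_pixel_is_nan(self):
        g0 = np.full((3, 3), 580.0)
        g1 = g0.copy()
        g1[1, 1] = np.nan
        series = make_series([g0, g1], [0.0, 300.0])
        cmap = bk.height_change(series, 0, 300)
        assert np.isnan(cmap.grid[1, 1])
        assert np.isfinite(cmap.grid[0, 0])

    def test_reversed_interval_rejected(self):
        series = make_series([np.full((3, 3), 580.0)] * 2, [0.0, 300.0])
        with pytest.raises(ValueError):
            bk.height_change(series, 300.0, 0.0)

    def test_antisymmetry_under_frame_exchange(self):
        rng = np.random.default_rng(1)
        g0 = 580.0 + rng.normal(0, 3, (6, 6))
        g1 = 580.0 + rng.normal(0, 3, (6, 6))
        fwd = bk.height_change(make_series([g0, g1], [0, 300]), 0, 300)
        rev = bk.height_change(make_series([g1, g0], [0, 300]), 0, 300)
        assert np.allclose(fwd.grid, -rev.grid)


class TestRollingChange:
    def test_two_hour_series_yields_thirteen_hourly_maps(self):
        n = 25  # frames at 0, 300, ..., 7200 s
        series = make_series([np.full((3, 3), 580.0)] * n,
                             np.arange(n) * 300.0,
                             lights_on=[(0.0, 7200.0)])
        maps = bk.rolling_change(series, window_s=3600.0, step_s=300.0)
        assert len(maps) == 13
        assert all(np.allclose(m.grid, 0.0) for m in maps)
        assert maps[0].interval == (0.0, 3600.0)

    def test_windows_confined_to_lights_on(self):
        n = 25
        series = make_series([np.full((3, 3), 580.0)] * n,
                             np.arange(n) * 300.0,
                             lights_on=[(0.0, 3600.0)])
        maps = bk.rolling_change(series, 3600.0, 300.0)
        assert len(maps) == 1  # only [0, 3600] fits


class TestVolumeOf:
    def test_thousand_pixels_at_one_cm_is_ten_cm3(self):
        grid = np.zeros((40, 40))
        grid.ravel()[:1000] = 1.0
        cmap = bk.HeightChangeMap(grid, (0, 1), "trial")
        assert bk.volume_of(cmap, bk.GridCalibration(0.01)) == \
            pytest.approx(10.0)

    def test_signed_and_unsigned_sums(self):
        grid = np.zeros((20, 20))
        grid.ravel()[:100] = -0.5
        cmap = bk.HeightChangeMap(grid, (0, 1), "trial")
        cal = bk.GridCalibration(0.01)
        assert bk.volume_of(cmap, cal, signed=True) == pytest.approx(-0.5)
        assert bk.volume_of(cmap, cal, signed=False) == pytest.approx(0.5)

    def test_balanced_pit_and_castle_cancel(self):
        grid = np.zeros((10, 10))
        grid[0, :5] = 2.0
        grid[9, :5] = -2.0
        cmap = bk.HeightChangeMap(grid, (0, 1), "trial")
        assert bk.volume_of(cmap, signed=True) == pytest.approx(0.0)

    def test_empty_mask_is_zero(self):
        cmap = bk.HeightChangeMap(np.ones((5, 5)), (0, 1), "trial")
        assert bk.volume_of(cmap, mask=np.zeros((5, 5), bool)) == 0.0
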