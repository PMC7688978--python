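"""Depth-frame ingestion and height-change computation.

A trial is recorded as a time series of dense depth frames: 2D grids of
sensor-to-surface distance in millimetres, one (averaged) frame per 5-minute
window, with NaN marking pixels the sensor failed to resolve.  This module
turns those raw stacks into physically calibrated maps of surface height
change in centimetres:

1. ``average_window``      - collapse ~10 Hz raw frames into one frame per
                             window with a NaN-ignoring per-pixel mean;
2. ``interpolate_islands`` - fill small connected patches of missing pixels
                             by planar interpolation from their surroundings;
3. ``smooth_series``       - separable Savitzky-Golay smoothing along time,
                             rows and columns, tolerant of remaining gaps;
4. ``height_change``       - subtract two frames to obtain signed height
                             change (positive = surface rose toward the
                             sensor, i.e. castle-like elevation);
5. ``rolling_change``      - rolling hourly change maps in 5-min steps,
                             restricted to lights-on periods;
6. ``volume_of``           - convert a change map into cm^3 moved.

Sign convention: height = -distance.  Sand added at a pixel brings the
surface closer to the downward-looking sensor, so distance decreases and the
height change is positive.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage
from scipy.interpolate import griddata

from ._sgolay import savgol_masked

MM_PER_CM = 10.0

_FOUR_CONN = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


@dataclass(frozen=True)
class GridCalibration:
    """Physical calibration of the depth grid.

    ``pixel_footprint_cm2`` is the sand-surface area seen by one pixel; the
    default 0.01 cm^2 makes a 1000-pixel region with 1 cm of height change
    correspond to 10 cm^3 of sand.  ``mm_per_unit`` converts raw grid values
    to millimetres (raw values are already mm for the supported sensors).
    """
    pixel_footprint_cm2: float = 0.01
    mm_per_unit: float = 1.0

    def __post_init__(self) -> None:
        if not self.pixel_footprint_cm2 > 0:
            raise ValueError("pixel_footprint_cm2 must be > 0")
        if not self.mm_per_unit > 0:
            raise ValueError("mm_per_unit must be > 0")


@dataclass
class DepthFrame:
    """One dense distance grid (mm from sensor, NaN = missing)."""
    grid: np.ndarray
    timestamp: float  # seconds since trial start

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid)
        if self.grid.ndim != 2:
            raise ValueError(f"grid must be 2D, got shape {self.grid.shape}")
        if self.timestamp < 0:
            raise ValueError(f"timestamp must be >= 0, got {self.timestamp}")
        finite = np.isfinite(self.grid)
        if finite.any() and np.nanmin(np.where(finite, self.grid, np.inf)) <= 0:
            raise ValueError("all finite distance entries must be > 0")

    @property
    def missing_fraction(self) -> float:
        return float(np.isnan(self.grid).mean())


@dataclass
class DepthSeries:
    """Ordered stack of depth frames plus trial metadata.

    ``lights_on`` holds [start, end] second intervals (one per day) during
    which behaviour is analysed; frames outside them are retained but
    excluded from rolling/hourly analyses.
    """
    frames: list[DepthFrame]
    lights_on: list[tuple[float, float]] = field(default_factory=list)
    calibration: GridCalibration = field(default_factory=GridCalibration)

    def __post_init__(self) -> None:
        if not self.frames:
            raise ValueError("DepthSeries requires at least one frame")
        shapes = {f.grid.shape for f in self.frames}
        if len(shapes) != 1:
            raise ValueError(f"inconsistent frame shapes: {shapes}")
        ts = self.timestamps
        if np.any(np.diff(ts) <= 0):
            raise ValueError("frame timestamps must be strictly increasing")
        if not self.lights_on:
            self.lights_on = [(float(ts[0]), float(ts[-1]))]

    @property
    def timestamps(self) -> np.ndarray:
        return np.array([f.timestamp for f in self.frames], dtype=float)

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames[0].grid.shape

    @property
    def cadence(self) -> float:
        """Median inter-frame spacing in seconds."""
        ts = self.timestamps
        if len(ts) < 2:
            return float("nan")
        return float(np.median(np.diff(ts)))

    def grid_stack(self, dtype=np.float64) -> np.ndarray:
        return np.stack([f.grid for f in self.frames]).astype(dtype, copy=False)

    def index_near(self, t: float, tol: float | None = None) -> int:
        """Index of the frame nearest ``t``; error beyond half a cadence."""
        ts = self.timestamps
        i = int(np.argmin(np.abs(ts - t)))
        if tol is None:
            cad = self.cadence
            tol = np.inf if np.isnan(cad) else (cad / 2) * (1 + 1e-6)
        if abs(ts[i] - t) > tol:
            raise ValueError(
                f"no frame within {tol:.1f} s of t={t:.1f} s "
                f"(nearest at {ts[i]:.1f} s)")
        return i


@dataclass
class HeightChangeMap:
    """Signed surface-height change in cm over ``interval`` = (t0, t1)."""
    grid: np.ndarray
    interval: tuple[float, float]
    timescale: str  # trial | daily | hourly | rolling

    @property
    def missing_fraction(self) -> float:
        return float(np.isnan(self.grid).mean())


# ---------------------------------------------------------------------------
# frame file and manifest I/O


def _load_grid(path: Path) -> np.ndarray:
    p = str(path)
    if p.endswith(".npy"):
        return np.load(path)
    return np.loadtxt(path)  # handles plain and .gz text grids


def write_grid(path: Path, grid: np.ndarray) -> None:
    if str(path).endswith(".npy"):
        np.save(path, grid)
    else:
        np.savetxt(path, grid)


def read_depth_series(manifest_path: str | Path) -> DepthSeries:
    """Load a depth series described by a JSON manifest.

    The manifest has fields ``rows``, ``cols``, ``frames`` (list of
    ``{path, timestamp_s}`` with paths relative to the manifest),
    ``lights_on`` (list of [start_s, end_s]) and ``pixel_footprint_cm2``.
    """
    manifest_path = Path(manifest_path)
    with open(manifest_path) as fh:
        man = json.load(fh)
    rows, cols = int(man["rows"]), int(man["cols"])
    entries = man.get("frames", [])
    if not entries:
        raise ValueError(f"{manifest_path}: manifest lists no frames")
    frames = []
    for e in entries:
        fp = manifest_path.parent / e["path"]
        if not fp.exists():
            raise FileNotFoundError(f"frame file missing: {fp}")
        grid = _load_grid(fp)
        if grid.shape != (rows, cols):
            raise ValueError(
                f"frame {e['path']}: shape {grid.shape} does not match "
                f"manifest ({rows}, {cols})")
        frames.append(DepthFrame(np.asarray(grid, dtype=np.float64),
                                 float(e["timestamp_s"])))
    ts = [f.timestamp for f in frames]
    if any(b <= a for a, b in zip(ts, ts[1:])):
        if len(set(ts)) != len(ts):
            dup = [t for t in set(ts) if ts.count(t) > 1][0]
            raise ValueError(
                f"{manifest_path}: duplicate frame timestamp {dup}")
        warnings.warn("frame timestamps out of order; sorting by timestamp")
        frames.sort(key=lambda f: f.timestamp)
    lights_on = [(float(a), float(b)) for a, b in man.get("lights_on", [])]
    cal = GridCalibration(
        pixel_footprint_cm2=float(man.get("pixel_footprint_cm2", 0.01)))
    return DepthSeries(frames, lights_on, cal)


def write_change_map(cmap: HeightChangeMap, path: str | Path) -> None:
    """Save a change map grid plus a JSON sidecar (``<path>.json``)."""
    path = Path(path)
    write_grid(path, cmap.grid)
    sidecar = {"t0": cmap.interval[0], "t1": cmap.interval[1],
               "timescale": cmap.timescale, "units": "cm"}
    with open(str(path) + ".json", "w") as fh:
        json.dump(sidecar, fh, indent=2)


def read_change_map(path: str | Path) -> HeightChangeMap:
    path = Path(path)
    grid = _load_grid(path)
    with open(str(path) + ".json") as fh:
        side = json.load(fh)
    return HeightChangeMap(np.asarray(grid, float),
                           (float(side["t0"]), float(side["t1"])),
                           str(side["timescale"]))


# ---------------------------------------------------------------------------
# processing operations


def average_window(raw_frames: list[DepthFrame]) -> DepthFrame:
    """Collapse the raw frames of one window into a single frame.

    Per-pixel NaN-ignoring mean; a pixel missing in every raw frame stays
    missing.  The output timestamp is the window midpoint.
    """
    if not raw_frames:
        raise ValueError("average_window requires at least one raw frame")
    shapes = {f.grid.shape for f in raw_frames}
    if len(shapes) != 1:
        raise ValueError(f"raw frames have inconsistent shapes: {shapes}")
    stack = np.stack([f.grid for f in raw_frames])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        mean = np.nanmean(stack, axis=0)
    ts = [f.timestamp for f in raw_frames]
    return DepthFrame(mean, (min(ts) + max(ts)) / 2)


def interpolate_islands(frame: DepthFrame,
                        max_island_px: int = 100) -> DepthFrame:
    """Fill small NaN islands by planar interpolation from valid neighbours.

    Connected components of missing pixels (4-connectivity) with area
    <= ``max_island_px`` are filled by 2D linear (Delaunay) interpolation
    from the ring of valid pixels surrounding them; islands the convex hull
    cannot cover (at the frame border) fall back to nearest-neighbour.
    Larger components and valid pixels are never modified.
    """
    if max_island_px < 0:
        raise ValueError("max_island_px must be >= 0")
    grid = frame.grid
    missing = np.isnan(grid)
    if missing.all():
        warnings.warn("frame is entirely missing; returned unchanged")
        return DepthFrame(grid.copy(), frame.timestamp)
    if not missing.any() or max_island_px == 0:
        return DepthFrame(grid.copy(), frame.timestamp)
    labels, nlab = ndimage.label(missing, structure=_FOUR_CONN)
    sizes = np.bincount(labels.ravel())
    small = np.zeros(nlab + 1, dtype=bool)
    small[1:] = sizes[1:] <= max_island_px
    fill_mask = small[labels]
    if not fill_mask.any():
        return DepthFrame(grid.copy(), frame.timestamp)
    ring = ndimage.binary_dilation(fill_mask, structure=np.ones((3, 3), bool))
    ring &= ~missing
    pts = np.argwhere(ring)
    vals = grid[ring]
    xi = np.argwhere(fill_mask)
    if len(pts) == 0:
        warnings.warn("no valid pixels adjacent to islands; left unfilled")
        return DepthFrame(grid.copy(), frame.timestamp)
    est = griddata(pts, vals, xi, method="linear")
    bad = np.isnan(est)
    if bad.any():
        est[bad] = griddata(pts, vals, xi[bad], method="nearest")
    out = grid.copy()
    out[xi[:, 0], xi[:, 1]] = est
    return DepthFrame(out, frame.timestamp)


def smooth_series(series: DepthSeries, temporal_window: int = 5,
                  spatial_window: int = 5, polyorder: int = 2) -> DepthSeries:
    """Savitzky-Golay smooth a series along time, then rows, then columns.

    Windows must be odd and larger than ``polyorder``.  Windows containing
    missing values are fitted over valid entries only; positions retaining
    fewer than ``polyorder + 1`` valid samples come out missing.  If the
    series is shorter than ``temporal_window`` the temporal pass is skipped
    with a warning.  Exact for polynomial fields of degree <= ``polyorder``.
    """
    for name, win in (("temporal_window", temporal_window),
                      ("spatial_window", spatial_window)):
        if win % 2 == 0 or win <= polyorder:
            raise ValueError(
                f"{name} must be odd and > polyorder, got {win} "
                f"(polyorder={polyorder})")
    stack = series.grid_stack(dtype=np.float64)
    nt, nr, nc = stack.shape
    if nt >= temporal_window:
        stack = savgol_masked(stack, temporal_window, polyorder, axis=0)
    else:
        warnings.warn(
            f"series length {nt} < temporal window {temporal_window}; "
            "temporal smoothing skipped")
    if nr >= spatial_window:
        stack = savgol_masked(stack, spatial_window, polyorder, axis=1)
    if nc >= spatial_window:
        stack = savgol_masked(stack, spatial_window, polyorder, axis=2)
    frames = [DepthFrame(stack[i].astype(np.float32), f.timestamp)
              for i, f in enumerate(series.frames)]
    return DepthSeries(frames, list(series.lights_on), series.calibration)


def height_change(series: DepthSeries, t0: float, t1: float,
                  timescale: str = "trial",
                  tol: float | None = None) -> HeightChangeMap:
    """Signed height change (cm) between the frames nearest t0 and t1.

    Positive entries mean the surface rose toward the sensor (castle-like);
    pixels missing in either endpoint frame are NaN.
    """
    if t1 <= t0:
        raise ValueError(f"t1 must be > t0, got t0={t0}, t1={t1}")
    if len(series.frames) < 2:
        raise ValueError("height change requires at least 2 frames")
    i0 = series.index_near(t0, tol=tol)
    i1 = series.index_near(t1, tol=tol)
    if i0 == i1:
        raise ValueError(
            f"t0={t0} and t1={t1} resolve to the same frame "
            f"(timestamp {series.timestamps[i0]})")
    g0 = series.frames[i0].grid.astype(np.float64)
    g1 = series.frames[i1].grid.astype(np.float64)
    mm = series.calibration.mm_per_unit
    grid = (g0 - g1) * mm / MM_PER_CM
    return HeightChangeMap(grid,
                           (float(series.timestamps[i0]),
                            float(series.timestamps[i1])),
                           timescale)


def rolling_change(series: DepthSeries, window_s: float = 3600.0,
                   step_s: float = 300.0) -> list[HeightChangeMap]:
    """Rolling change maps [t - window, t] stepped by ``step_s``.

    Only windows lying entirely inside a lights-on interval (and inside the
    recorded span) are emitted.
    """
    ts = series.timestamps
    maps: list[HeightChangeMap] = []
    for lo, hi in series.lights_on:
        start = max(lo, float(ts[0]))
        end = min(hi, float(ts[-1]))
        if end - start < window_s:
            continue
        for t1 in np.arange(start + window_s, end + 1e-9, step_s):
            m = height_change(series, t1 - window_s, t1, timescale="rolling")
            maps.append(m)
    return maps


def volume_of(cmap: HeightChangeMap,
              calibration: GridCalibration | None = None,
              mask: np.ndarray | None = None,
              signed: bool = True) -> float:
    """Volume (cm^3) of a change map over ``mask`` (default: whole grid).

    ``signed=True`` sums signed height change (pits and castles cancel);
    ``signed=False`` sums absolute change.  NaN pixels are skipped; an empty
    mask yields 0.
    """
    cal = calibration or GridCalibration()
    vals = cmap.grid if mask is None else cmap.grid[mask]
    if vals.size == 0:
        return 0.0
    if not signed:
        vals = np.abs(vals)
    total = np.nansum(vals)
    return float(total * cal.pixel_footprint_cm2)
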