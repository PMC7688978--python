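"""Video-to-depth registration and event linking.

Behaviour events are detected in video pixel coordinates; the depth sensor
has its own grid.  A least-squares affine transform estimated from point
correspondences maps event centers into depth coordinates, after which each
event can be linked to the sand surface height at the nearest depth frame
and pixel.  Events that fall off the depth grid or over missing pixels stay
in the output, flagged with an ``unlinked_reason``.

Events travel as pandas DataFrames with the columns
``trial_id, timestamp_s, category, video_x, video_y, radius_px`` (x = column,
y = row, 0-based); mapping adds ``depth_x, depth_y, radius_depth_px`` and
linking adds ``surface_mm`` and ``unlinked_reason`` ('' when linked).
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .depth import DepthSeries

#: the ten behaviour categories assigned by the upstream action classifier
CATEGORIES = ("bower_scoop", "bower_spit", "bower_multiple",
              "feed_scoop", "feed_spit", "feed_multiple",
              "quiver", "spawn", "shadow_reflection", "other")

EVENT_COLUMNS = ("trial_id", "timestamp_s", "category",
                 "video_x", "video_y", "radius_px")


@dataclass
class AffineTransform:
    """2x3 affine matrix mapping video (col, row, 1) -> depth (col, row)."""
    matrix: np.ndarray
    rms_residual: float = 0.0

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (2, 3):
            raise ValueError(f"matrix must be 2x3, got {self.matrix.shape}")
        if abs(np.linalg.det(self.matrix[:, :2])) < 1e-12:
            raise ValueError("linear part of affine transform is singular")

    def apply(self, xy: np.ndarray) -> np.ndarray:
        xy = np.atleast_2d(np.asarray(xy, dtype=float))
        return xy @ self.matrix[:, :2].T + self.matrix[:, 2]

    @property
    def scale(self) -> float:
        """Mean singular value of the linear part (isotropic length scale)."""
        return float(np.linalg.svd(self.matrix[:, :2],
                                   compute_uv=False).mean())


def estimate_affine(video_xy: np.ndarray,
                    depth_xy: np.ndarray) -> AffineTransform:
    """Least-squares affine fit from >= 3 non-collinear correspondences."""
    video_xy = np.atleast_2d(np.asarray(video_xy, dtype=float))
    depth_xy = np.atleast_2d(np.asarray(depth_xy, dtype=float))
    if video_xy.shape != depth_xy.shape or video_xy.shape[1] != 2:
        raise ValueError("correspondence arrays must both be (n, 2)")
    n = len(video_xy)
    if n < 3:
        raise ValueError(
            f"at least 3 point correspondences are required, got {n}")
    design = np.column_stack([video_xy, np.ones(n)])
    if np.linalg.matrix_rank(design) < 3:
        raise ValueError(
            "degenerate configuration: correspondence points are collinear")
    sol, *_ = np.linalg.lstsq(design, depth_xy, rcond=None)
    matrix = sol.T
    resid = design @ sol - depth_xy
    rms = float(np.sqrt(np.mean(np.sum(resid ** 2, axis=1))))
    return AffineTransform(matrix=matrix, rms_residual=rms)


def read_correspondences(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read a correspondences CSV (video_x, video_y, depth_x, depth_y)."""
    df = pd.read_csv(path)
    need = {"video_x", "video_y", "depth_x", "depth_y"}
    if not need.issubset(df.columns):
        raise ValueError(f"{path}: missing columns {need - set(df.columns)}")
    return (df[["video_x", "video_y"]].to_numpy(float),
            df[["depth_x", "depth_y"]].to_numpy(float))


def read_events(path: str | Path,
                categories: tuple[str, ...] = CATEGORIES) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(EVENT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing event columns {sorted(missing)}")
    if (df["radius_px"] <= 0).any():
        raise ValueError(f"{path}: event radius_px must be > 0")
    unknown = set(df["category"]) - set(categories)
    if unknown:
        raise ValueError(
            f"{path}: unknown behaviour categories {sorted(unknown)}")
    return df


def map_events(events: pd.DataFrame, A: AffineTransform) -> pd.DataFrame:
    """Map event centers and radii from video to depth coordinates.

    Radii are scaled by the mean singular value of the linear part; events
    mapping outside the grid are retained and flagged downstream.
    """
    out = events.copy()
    depth = A.apply(out[["video_x", "video_y"]].to_numpy(float))
    out["depth_x"] = depth[:, 0]
    out["depth_y"] = depth[:, 1]
    out["radius_depth_px"] = out["radius_px"].to_numpy(float) * A.scale
    return out


def link_events(events: pd.DataFrame, series: DepthSeries,
                max_gap_s: float | None = None) -> pd.DataFrame:
    """Attach surface height to each mapped event (nearest frame and pixel).

    Every input event appears exactly once in the output.  Events outside
    the depth grid get ``unlinked_reason='outside_grid'``; events over a
    missing pixel, or with no frame within ``max_gap_s`` (default: one
    cadence), get ``'missing_depth'``.
    """
    if not len(series.frames):
        raise ValueError("cannot link events against an empty depth series")
    if "depth_x" not in events.columns:
        raise ValueError("events must be mapped to depth coordinates first "
                         "(run map_events)")
    if max_gap_s is None:
        cad = series.cadence
        max_gap_s = cad if np.isfinite(cad) else np.inf
    nrow, ncol = series.shape
    ts = series.timestamps
    out = events.copy()
    surface = np.full(len(out), np.nan)
    reason = np.full(len(out), "", dtype=object)
    ev_t = out["timestamp_s"].to_numpy(float)
    idx = np.clip(np.searchsorted(ts, ev_t), 0, len(ts) - 1)
    idx_prev = np.clip(idx - 1, 0, len(ts) - 1)
    use_prev = np.abs(ts[idx_prev] - ev_t) < np.abs(ts[idx] - ev_t)
    idx = np.where(use_prev, idx_prev, idx)
    gap = np.abs(ts[idx] - ev_t)
    rows = np.rint(out["depth_y"].to_numpy(float)).astype(int)
    cols = np.rint(out["depth_x"].to_numpy(float)).astype(int)
    outside = (rows < 0) | (rows >= nrow) | (cols < 0) | (cols >= ncol)
    reason[outside] = "outside_grid"
    for i in np.nonzero(~outside)[0]:
        if gap[i] > max_gap_s:
            reason[i] = "missing_depth"
            continue
        val = series.frames[idx[i]].grid[rows[i], cols[i]]
        if np.isnan(val):
            reason[i] = "missing_depth"
        else:
            surface[i] = float(val)
    out["surface_mm"] = surface
    out["unlinked_reason"] = reason
    return out


def unlinked_summary(linked: pd.DataFrame) -> pd.Series:
    """Per-category fraction of unlinked events, descending; sums to 1."""
    unlinked = linked[linked["unlinked_reason"] != ""]
    if unlinked.empty:
        return pd.Series(dtype=float, name="fraction")
    frac = unlinked["category"].value_counts(normalize=True)
    frac.name = "fraction"
    return frac
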