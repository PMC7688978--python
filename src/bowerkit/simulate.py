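"""Synthetic bower-construction trials with full ground truth.

The simulator produces everything a real recording rig would: a depth-frame
series (noisy, gappy, averaged per 5-min window), a behaviour-event table in
video coordinates, a fish-count stream and a correspondence table — plus the
noiseless surface history and true event log, so every downstream operation
can be tested for parameter recovery without hardware.

Construction model
------------------
A male of a pit-digging species scoops sand from a Gaussian-distributed
neighbourhood of the bower center and spits it at dispersed locations
outside an exclusion disk around the bower (fish do not spit into their own
pit); a castle-builder does the reverse.  Each scoop/spit transfers a fixed
volume between locations as a smooth truncated-Gaussian bump, so total sand
is conserved exactly.  Construction happens in bursts: on a building day
(probability ``build_day_prob``) a small number of sub-hour bouts are placed
in random lights-on hours.  Feeding events cluster in a ring near the tray
edge during non-burst hours; quivering and spawning sit on the bower;
"shadow/reflection" and "other" events are scattered over the full video
field of view, including off the tray.  Fish counts are lowest during
construction, higher during feeding, and highest during quivering/spawning.

Sensing model
-------------
Each 5-min window renders ``frames_per_window`` raw frames: distance =
base - 10*height(cm) + N(0, noise_sd_mm), masked by spatially correlated
dropout.  Dropout has a persistent per-window component (small islands plus
larger blobs, which survive frame averaging and give the island
interpolator realistic work) and a transient per-frame component that
averaging removes.  Raw frames are immediately collapsed with the same
NaN-ignoring mean the real pipeline uses.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .depth import (DepthFrame, DepthSeries, GridCalibration, write_grid)

_FEED_CATS = ("feed_scoop", "feed_spit", "feed_multiple")
_FEED_PROBS = (0.4, 0.4, 0.2)
_MISC_CATS = ("shadow_reflection", "other")


@dataclass
class TrialSpec:
    """Generative parameters of one synthetic trial.

    Defaults describe a desk-scale trial: a 120x160 grid standing in for the
    sensor's 480x640, 10 raw frames per 5-min window, 3 mm sensor noise and
    ~40% raw dropout, with two sub-hour construction bursts of ~30
    scoop-spit pairs (0.2 cm^3 each) on ~60% of days.
    """
    species_policy: str = "pit"      # pit | castle | control | empty
    days: int = 10
    frames_per_window: int = 10
    grid_shape: tuple[int, int] = (120, 160)
    noise_sd_mm: float = 3.0
    dropout_rate: float = 0.4        # total raw missing-pixel fraction
    window_s: float = 300.0
    lights_on_hours: tuple[float, float] = (0.0, 10.0)  # from day start
    base_distance_mm: float = 580.0
    sand_depth_cm: float = 6.4
    pixel_footprint_cm2: float = 0.01
    bower_center: tuple[float, float] | None = None     # (row, col)
    bower_radius_px: float = 36.0
    spit_exclusion_px: float | None = None  # default 1.25 * bower_radius
    per_event_volume_cm3: float = 0.2
    event_sigma_px: float = 4.0      # spatial sd of one scoop/spit bump
    build_day_prob: float = 0.6
    bursts_per_day: int = 2
    burst_offset_s: float = 300.0
    burst_duration_s: float = 3000.0
    pairs_per_burst: float = 30.0    # Poisson mean of scoop-spit pairs
    feed_events_per_day: float = 80.0
    quiver_events_per_day: float = 20.0
    spawn_events_per_day: float = 1.0
    misc_events_per_day: float = 20.0
    off_tray_fraction_hint: float = 0.0  # misc events already cover off-tray
    fish_count_means: dict = field(default_factory=lambda: {
        "build": 1.0, "feed": 2.0, "quiver": 3.0, "spawn": 3.5,
        "misc": 1.5, "baseline": 1.5})
    fish_baseline_cadence_s: float = 60.0
    video_shape: tuple[int, int] = (240, 320)  # (rows, cols)
    volume_conserving: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.species_policy not in ("pit", "castle", "control", "empty"):
            raise ValueError(f"unknown policy {self.species_policy!r}")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.days < 1 or self.frames_per_window < 1:
            raise ValueError("days and frames_per_window must be >= 1")
        if self.per_event_volume_cm3 < 0:
            raise ValueError("per_event_volume_cm3 must be >= 0")
        if self.bower_center is None:
            self.bower_center = (self.grid_shape[0] / 2,
                                 self.grid_shape[1] / 2)
        if self.spit_exclusion_px is None:
            self.spit_exclusion_px = 1.25 * self.bower_radius_px

    @property
    def lights_on(self) -> list[tuple[float, float]]:
        h0, h1 = self.lights_on_hours
        return [(d * 86400.0 + h0 * 3600.0, d * 86400.0 + h1 * 3600.0)
                for d in range(self.days)]


@dataclass
class TrialGroundTruth:
    """Noiseless surface history and true event log of a simulated trial."""
    surface: np.ndarray            # (n_windows, rows, cols) height in cm
    window_times: np.ndarray       # frame timestamps (window midpoints)
    events: pd.DataFrame           # true depth coords, volumes, categories
    per_window_volume: np.ndarray  # |moved volume| per window (cm^3)
    affine: np.ndarray             # true 2x3 video->depth matrix
    bower_center: tuple[float, float]
    bower_radius_px: float
    fish_means: dict


@dataclass
class SimulatedTrial:
    series: DepthSeries
    events: pd.DataFrame           # video-coordinate event table
    fish_counts: pd.DataFrame
    correspondences: pd.DataFrame
    truth: TrialGroundTruth
    spec: TrialSpec


def _true_affine(spec: TrialSpec) -> np.ndarray:
    """Video->depth affine: isotropic scale, slight rotation, translation."""
    s, phi = 0.55, 0.03
    lin = s * np.array([[np.cos(phi), -np.sin(phi)],
                        [np.sin(phi), np.cos(phi)]])
    t = np.array([-14.0, -10.0])  # (x, y) translation in depth pixels
    return np.column_stack([lin, t])


def _add_bump(height: np.ndarray, row: float, col: float, sigma: float,
              volume_cm3: float, footprint_cm2: float) -> None:
    """Add a truncated-Gaussian bump of exactly ``volume_cm3`` in place.

    The kernel is renormalised over its in-grid support, so volume is
    conserved even when the bump is clipped by the tray edge.
    """
    nrow, ncol = height.shape
    rad = int(np.ceil(3.5 * sigma))
    r0, r1 = max(0, int(row) - rad), min(nrow, int(row) + rad + 1)
    c0, c1 = max(0, int(col) - rad), min(ncol, int(col) + rad + 1)
    rr, cc = np.meshgrid(np.arange(r0, r1), np.arange(c0, c1), indexing="ij")
    kern = np.exp(-((rr - row) ** 2 + (cc - col) ** 2) / (2 * sigma ** 2))
    total = kern.sum()
    if total <= 0:
        return
    height[r0:r1, c0:c1] += (volume_cm3 / footprint_cm2) * kern / total


def _blotch_mask(rng: np.random.Generator, shape: tuple[int, int],
                 frac: float, sigma: float) -> np.ndarray:
    """Spatially correlated boolean mask covering ~``frac`` of the grid."""
    if frac <= 0:
        return np.zeros(shape, dtype=bool)
    fld = ndimage.gaussian_filter(rng.standard_normal(shape), sigma)
    return fld < np.quantile(fld, frac)


def _sample_near(rng, center, sd, shape):
    """Gaussian-scattered (row, col), clipped inside the grid."""
    r = np.clip(rng.normal(center[0], sd), 1.0, shape[0] - 2.0)
    c = np.clip(rng.normal(center[1], sd), 1.0, shape[1] - 2.0)
    return r, c


def _sample_dispersed(rng, center, exclusion_px, shape):
    """Uniform (row, col) on the tray, outside the bower exclusion disk."""
    for _ in range(1000):
        r = rng.uniform(1.0, shape[0] - 2.0)
        c = rng.uniform(1.0, shape[1] - 2.0)
        if np.hypot(r - center[0], c - center[1]) > exclusion_px:
            return r, c
    raise RuntimeError("could not sample a dispersed location; exclusion "
                       "disk covers the tray")


def _sample_edge(rng, shape, ring_sd: float = 5.0):
    """Feeding location in a ring near the tray edge."""
    cr, cc = shape[0] / 2, shape[1] / 2
    ring = 0.45 * min(shape)
    theta = rng.uniform(0, 2 * np.pi)
    rad = max(0.0, ring - abs(rng.normal(0, ring_sd)))
    r = np.clip(cr + rad * np.sin(theta), 1.0, shape[0] - 2.0)
    c = np.clip(cc + rad * np.cos(theta), 1.0, shape[1] - 2.0)
    return r, c


def _fish_group(category: str) -> str:
    if category.startswith("bower"):
        return "build"
    if category.startswith("feed"):
        return "feed"
    if category == "quiver":
        return "quiver"
    if category == "spawn":
        return "spawn"
    return "misc"


def _generate_events(spec: TrialSpec, rng: np.random.Generator) -> list[dict]:
    """True event log entries: t, category, depth row/col, volume, radius."""
    shape = spec.grid_shape
    center = spec.bower_center
    scatter_sd = spec.bower_radius_px / 2
    vol = spec.per_event_volume_cm3
    radius_depth = 2.0 * spec.event_sigma_px
    builds = spec.species_policy in ("pit", "castle")
    events: list[dict] = []

    def add(t, cat, r, c, v=0.0, rad=None):
        events.append({"timestamp_s": float(t), "category": cat,
                       "depth_row": float(r), "depth_col": float(c),
                       "volume_cm3": float(v),
                       "radius_depth_px":
                           float(rad if rad is not None else radius_depth)})

    n_hours = int(spec.lights_on_hours[1] - spec.lights_on_hours[0])
    for day, (lo, hi) in enumerate(spec.lights_on):
        burst_windows: list[tuple[float, float]] = []
        if builds and rng.random() < spec.build_day_prob:
            hours = rng.choice(n_hours, size=min(spec.bursts_per_day,
                                                 n_hours), replace=False)
            for h in hours:
                b0 = lo + h * 3600.0 + spec.burst_offset_s
                b1 = min(b0 + spec.burst_duration_s, hi)
                burst_windows.append((b0, b1))
                for _ in range(rng.poisson(spec.pairs_per_burst)):
                    t_scoop = rng.uniform(b0, b1 - 30.0)
                    t_spit = t_scoop + rng.uniform(2.0, 20.0)
                    conc = _sample_near(rng, center, scatter_sd, shape)
                    disp = _sample_dispersed(rng, center,
                                             spec.spit_exclusion_px, shape)
                    if spec.species_policy == "pit":
                        scoop_loc, spit_loc = conc, disp
                    else:
                        scoop_loc, spit_loc = disp, conc
                    add(t_scoop, "bower_scoop", *scoop_loc, v=-vol)
                    add(t_spit, "bower_spit", *spit_loc, v=vol)
                    if rng.random() < 0.1:
                        add(rng.uniform(b0, b1), "bower_multiple",
                            *_sample_near(rng, center, scatter_sd, shape))

        def _nonburst_time():
            for _ in range(1000):
                t = rng.uniform(lo, hi)
                if not any(b0 <= t < b1 for b0, b1 in burst_windows):
                    return t
            return rng.uniform(lo, hi)

        if spec.species_policy != "empty":
            for _ in range(rng.poisson(spec.feed_events_per_day)):
                cat = rng.choice(_FEED_CATS, p=_FEED_PROBS)
                add(_nonburst_time(), str(cat), *_sample_edge(rng, shape),
                    rad=float(rng.uniform(3.0, 6.0)))
            for _ in range(rng.poisson(spec.misc_events_per_day)):
                cat = _MISC_CATS[int(rng.integers(2))]
                # sampled in video coordinates; may land off the depth grid
                events.append({"timestamp_s": float(rng.uniform(lo, hi)),
                               "category": cat, "depth_row": np.nan,
                               "depth_col": np.nan, "volume_cm3": 0.0,
                               "radius_depth_px":
                                   float(rng.uniform(3.0, 6.0)),
                               "_video_xy": (
                                   float(rng.uniform(0, spec.video_shape[1])),
                                   float(rng.uniform(0, spec.video_shape[0])))
                               })
        if builds:
            for _ in range(rng.poisson(spec.quiver_events_per_day)):
                add(rng.uniform(lo, hi), "quiver",
                    *_sample_near(rng, center, spec.bower_radius_px / 4,
                                  shape))
            for _ in range(rng.poisson(spec.spawn_events_per_day)):
                add(rng.uniform(lo, hi), "spawn",
                    *_sample_near(rng, center, spec.bower_radius_px / 4,
                                  shape))
    events.sort(key=lambda e: e["timestamp_s"])
    return events


def simulate_trial(spec: TrialSpec) -> SimulatedTrial:
    """Generate a complete synthetic trial (deterministic given the seed)."""
    rng = np.random.default_rng(spec.seed)
    nrow, ncol = spec.grid_shape
    affine = _true_affine(spec)
    lin, trans = affine[:, :2], affine[:, 2]
    lin_inv = np.linalg.inv(lin)
    events = _generate_events(spec, rng)

    # complete video/depth coordinates in both directions
    for e in events:
        if "_video_xy" in e:
            vx, vy = e.pop("_video_xy")
            dx, dy = lin @ np.array([vx, vy]) + trans
            e["depth_col"], e["depth_row"] = float(dx), float(dy)
            e["video_x"], e["video_y"] = vx, vy
        else:
            d = np.array([e["depth_col"], e["depth_row"]])
            vx, vy = lin_inv @ (d - trans)
            e["video_x"], e["video_y"] = float(vx), float(vy)
        e["on_tray"] = bool(0 <= e["depth_row"] < nrow
                            and 0 <= e["depth_col"] < ncol)

    # render windows
    ws = spec.window_s
    n_windows = int(round(spec.days * 86400.0 / ws))
    height = np.zeros((nrow, ncol))
    truth_surface = np.empty((n_windows, nrow, ncol), dtype=np.float32)
    avg_frames = np.empty((n_windows, nrow, ncol), dtype=np.float32)
    per_window_volume = np.zeros(n_windows)
    window_times = np.arange(n_windows) * ws + ws / 2
    scale = np.linalg.svd(lin, compute_uv=False).mean()
    ev_idx = 0
    pers_frac = spec.dropout_rate / 2
    trans_frac = spec.dropout_rate / 2
    noisy = spec.noise_sd_mm > 0 or spec.dropout_rate > 0
    for j in range(n_windows):
        t1 = (j + 1) * ws
        while ev_idx < len(events) and events[ev_idx]["timestamp_s"] < t1:
            e = events[ev_idx]
            if e["volume_cm3"] != 0.0 and e["on_tray"]:
                _add_bump(height, e["depth_row"], e["depth_col"],
                          spec.event_sigma_px, e["volume_cm3"],
                          spec.pixel_footprint_cm2)
                per_window_volume[j] += abs(e["volume_cm3"])
            ev_idx += 1
        if height.min() < -spec.sand_depth_cm:
            raise ValueError(
                f"pit deeper than the sand tray ({-height.min():.2f} cm > "
                f"{spec.sand_depth_cm} cm) at t={t1:.0f} s; reduce event "
                "volume or rate")
        truth_surface[j] = height
        clean = spec.base_distance_mm - 10.0 * height
        if not noisy:
            avg_frames[j] = clean
            continue
        raw = clean[None, :, :] + rng.normal(
            0.0, spec.noise_sd_mm, (spec.frames_per_window, nrow, ncol))
        if spec.dropout_rate > 0:
            pers = (_blotch_mask(rng, (nrow, ncol), pers_frac / 2, 1.5)
                    | _blotch_mask(rng, (nrow, ncol), pers_frac / 2, 8.0))
            raw[:, pers] = np.nan
            # transient blotches, one smoothed field per raw frame
            fld = ndimage.gaussian_filter(
                rng.standard_normal(raw.shape), (0, 1.5, 1.5))
            thr = np.quantile(fld, trans_frac, axis=(1, 2), keepdims=True)
            raw[fld < thr] = np.nan
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=RuntimeWarning)
            avg_frames[j] = np.nanmean(raw, axis=0)

    frames = [DepthFrame(avg_frames[j], float(window_times[j]))
              for j in range(n_windows)]
    series = DepthSeries(frames, spec.lights_on,
                         GridCalibration(spec.pixel_footprint_cm2))

    truth_events = pd.DataFrame(events) if events else pd.DataFrame(
        columns=["timestamp_s", "category", "depth_row", "depth_col",
                 "volume_cm3", "radius_depth_px", "video_x", "video_y",
                 "on_tray"])
    trial_id = f"{spec.species_policy}_sim_{spec.seed}"
    if len(truth_events):
        video_events = pd.DataFrame({
            "trial_id": trial_id,
            "timestamp_s": truth_events["timestamp_s"],
            "category": truth_events["category"],
            "video_x": truth_events["video_x"],
            "video_y": truth_events["video_y"],
            "radius_px": np.maximum(
                0.5, truth_events["radius_depth_px"] / scale
                + rng.normal(0, 0.3, len(truth_events))),
        })
    else:
        video_events = pd.DataFrame(columns=["trial_id", "timestamp_s",
                                             "category", "video_x",
                                             "video_y", "radius_px"])

    # fish counts: sparse baseline plus one record next to each event
    fish_rows = []
    means = spec.fish_count_means
    if spec.species_policy != "empty":
        for lo, hi in spec.lights_on:
            for t in np.arange(lo, hi, spec.fish_baseline_cadence_s):
                fish_rows.append((float(t),
                                  int(rng.poisson(means["baseline"]))))
        for e in events:
            t = e["timestamp_s"] + rng.uniform(-0.4, 0.4)
            fish_rows.append((float(t), int(rng.poisson(
                means[_fish_group(e["category"])]))))
    fish = pd.DataFrame(fish_rows, columns=["timestamp_s", "count"])
    fish = fish.sort_values("timestamp_s", kind="stable",
                            ignore_index=True)

    # correspondences: a 3x3 grid of exact video->depth pairs
    vx = np.linspace(40, spec.video_shape[1] - 40, 3)
    vy = np.linspace(30, spec.video_shape[0] - 30, 3)
    vpts = np.array([(x, y) for y in vy for x in vx])
    dpts = vpts @ lin.T + trans
    corr = pd.DataFrame({"video_x": vpts[:, 0], "video_y": vpts[:, 1],
                         "depth_x": dpts[:, 0], "depth_y": dpts[:, 1]})

    truth = TrialGroundTruth(
        surface=truth_surface, window_times=window_times,
        events=truth_events, per_window_volume=per_window_volume,
        affine=affine, bower_center=tuple(spec.bower_center),
        bower_radius_px=spec.bower_radius_px, fish_means=dict(means))
    return SimulatedTrial(series=series, events=video_events,
                          fish_counts=fish, correspondences=corr,
                          truth=truth, spec=spec)


def write_fixture(trial: SimulatedTrial, out_dir: str | Path,
                  frame_format: str = "npy") -> Path:
    """Write a trial to disk in the formats the pipeline consumes.

    Emits ``manifest.json`` + per-window frame files, ``events.csv``,
    ``fish_counts.csv``, ``correspondences.csv`` and ground-truth artifacts
    (``truth_events.csv``, ``truth_surface.npy``, ``ground_truth.json``).
    Returns the manifest path.
    """
    if frame_format not in ("npy", "txt.gz"):
        raise ValueError("frame_format must be 'npy' or 'txt.gz'")
    out = Path(out_dir)
    (out / "frames").mkdir(parents=True, exist_ok=True)
    entries = []
    for j, frame in enumerate(trial.series.frames):
        rel = f"frames/frame_{j:05d}.{frame_format}"
        write_grid(out / rel, frame.grid)
        entries.append({"path": rel, "timestamp_s": frame.timestamp})
    nrow, ncol = trial.series.shape
    manifest = {
        "rows": nrow, "cols": ncol, "frames": entries,
        "lights_on": [list(iv) for iv in trial.series.lights_on],
        "pixel_footprint_cm2":
            trial.series.calibration.pixel_footprint_cm2,
        "trial_id": f"{trial.spec.species_policy}_sim_{trial.spec.seed}",
        "seed": trial.spec.seed,
    }
    manifest_path = out / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2)
    trial.events.to_csv(out / "events.csv", index=False)
    trial.fish_counts.to_csv(out / "fish_counts.csv", index=False)
    trial.correspondences.to_csv(out / "correspondences.csv", index=False)
    trial.truth.events.to_csv(out / "truth_events.csv", index=False)
    np.save(out / "truth_surface.npy", trial.truth.surface)
    with open(out / "ground_truth.json", "w") as fh:
        json.dump({
            "affine": trial.truth.affine.tolist(),
            "bower_center": list(trial.truth.bower_center),
            "bower_radius_px": trial.truth.bower_radius_px,
            "per_window_volume": trial.truth.per_window_volume.tolist(),
            "window_times": trial.truth.window_times.tolist(),
            "fish_means": trial.truth.fish_means,
            "per_event_volume_cm3": trial.spec.per_event_volume_cm3,
        }, fh, indent=2)
    return manifest_path
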