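"""Temporal, spatial, ROI, regression and social analyses of linked events.

These operations relate the behaviour-event stream to the structural record:

* ``bin_temporal``            - hourly event counts per category plus the
                                absolute depth-change volume of each bin;
* ``correlate``               - pairwise Pearson R/p with a UPGMA leaf order
                                (Euclidean distance), as used for clustered
                                correlation heatmaps;
* ``kde_spatial``             - Gaussian KDE of event centers on the depth
                                lattice, bandwidth = half the mean radius;
* ``spatial_correlation``     - pixelwise correlation of per-category
                                densities with absolute depth change;
* ``roi_event_counts``        - scoop/spit contingency inside vs outside
                                daily bower ROIs with Pearson chi-square;
* ``hourly_regression``       - OLS of hourly change volume on hourly event
                                counts (slope estimates per-event volume);
* ``fish_counts_by_behavior`` - join events to nearest fish-count records
                                and summarise counts per category.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import leaves_list, linkage
from sklearn.neighbors import KernelDensity

from .depth import (DepthSeries, GridCalibration, HeightChangeMap,
                    height_change, volume_of)
from .metrics import BowerROI
from .register import CATEGORIES


@dataclass
class CorrelationResult:
    """Symmetric Pearson R and p matrices with a UPGMA leaf order."""
    r: pd.DataFrame
    p: pd.DataFrame
    leaf_order: list[str]


@dataclass
class DensityMap:
    """Gaussian KDE of one behaviour category on the depth lattice."""
    grid: np.ndarray
    bandwidth: float
    n_events: int
    category: str = ""


@dataclass
class RoiContingency:
    """Scoops/spits inside vs outside daily bower ROIs for one subject."""
    scoops_in: int
    spits_in: int
    scoops_out: int
    spits_out: int
    ratio: float              # max-direction in-ROI scoop:spit ratio
    ratio_direction: str      # 'scoop_over_spit' or 'spit_over_scoop'
    chi2: float
    p: float
    subject: str = ""
    days: list[dict] = field(default_factory=list)


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r2: float
    p: float
    n: int


@dataclass
class FishCountSummary:
    stats: pd.DataFrame       # per-category n, mean, sd
    joined: pd.DataFrame      # per-event table for external model fitting
    coverage: float           # fraction of events with a count within gap


def bin_temporal(events: pd.DataFrame, series: DepthSeries,
                 bin_s: float = 3600.0,
                 categories: tuple[str, ...] = CATEGORIES) -> pd.DataFrame:
    """Event counts per category and |depth change| volume per time bin.

    Bins are consecutive ``bin_s`` windows anchored at t=0.  Bins with zero
    observations of any behaviour are excluded (this drops lights-off bins
    and prevents them from inflating correlations).  The ``depth_change``
    column is the absolute change volume (cm^3) between the frames nearest
    the bin edges, NaN when no frames bracket the bin.
    """
    ev = events.copy()
    ev["_bin"] = np.floor(ev["timestamp_s"].to_numpy(float) / bin_s).astype(int)
    rows = []
    for b, grp in ev.groupby("_bin"):
        counts = grp["category"].value_counts()
        rec = {c: int(counts.get(c, 0)) for c in categories}
        t0, t1 = b * bin_s, (b + 1) * bin_s
        try:
            cmap = height_change(series, t0, t1, timescale="hourly")
            rec["depth_change"] = volume_of(cmap, series.calibration,
                                            signed=False)
        except ValueError:
            rec["depth_change"] = float("nan")
        rec["bin_start_s"] = t0
        rows.append(rec)
    cols = list(categories) + ["depth_change", "bin_start_s"]
    return pd.DataFrame(rows, columns=cols)


def correlate(table: pd.DataFrame, min_rows: int = 3) -> CorrelationResult:
    """Pairwise Pearson R/p over the columns of ``table``.

    Constant columns are dropped with a warning; fewer than ``min_rows``
    rows is an error.  Leaf order comes from UPGMA (average-linkage)
    clustering of the correlation-matrix rows under Euclidean distance,
    matching the default behaviour of clustered heatmap tools.
    """
    df = table.select_dtypes(include=[np.number]).dropna()
    if len(df) < min_rows:
        raise ValueError(
            f"correlation requires >= {min_rows} complete rows, "
            f"got {len(df)}")
    const = [c for c in df.columns if df[c].nunique() <= 1]
    if const:
        warnings.warn(f"dropping constant columns: {const}")
        df = df.drop(columns=const)
    cols = list(df.columns)
    k = len(cols)
    if k < 2:
        raise ValueError("need at least 2 non-constant columns")
    rmat = np.eye(k)
    pmat = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            r, p = stats.pearsonr(df[cols[i]], df[cols[j]])
            rmat[i, j] = rmat[j, i] = r
            pmat[i, j] = pmat[j, i] = p
    order = leaves_list(linkage(rmat, method="average", metric="euclidean"))
    return CorrelationResult(
        r=pd.DataFrame(rmat, index=cols, columns=cols),
        p=pd.DataFrame(pmat, index=cols, columns=cols),
        leaf_order=[cols[i] for i in order])


def kde_spatial(xy: np.ndarray, radii: np.ndarray,
                grid_shape: tuple[int, int],
                bandwidth: float | None = None,
                category: str = "") -> DensityMap:
    """Gaussian KDE of event centers evaluated at every grid pixel.

    ``xy`` holds (depth_x, depth_y) = (col, row) centers.  The bandwidth
    defaults to half the mean estimated event radius, so each category's
    density reflects the physical footprint of its sand-change events.
    """
    xy = np.atleast_2d(np.asarray(xy, dtype=float))
    if len(xy) == 0:
        raise ValueError("kde_spatial requires at least one event")
    if bandwidth is None:
        bandwidth = float(np.mean(np.asarray(radii, dtype=float))) / 2.0
    if not bandwidth > 0:
        raise ValueError("bandwidth must be > 0")
    kde = KernelDensity(kernel="gaussian", bandwidth=bandwidth).fit(xy)
    nrow, ncol = grid_shape
    cc, rr = np.meshgrid(np.arange(ncol), np.arange(nrow))
    pts = np.column_stack([cc.ravel(), rr.ravel()]).astype(float)
    dens = np.exp(kde.score_samples(pts)).reshape(nrow, ncol)
    return DensityMap(grid=dens, bandwidth=bandwidth, n_events=len(xy),
                      category=category)


def spatial_correlation(density_maps, abs_change) -> CorrelationResult:
    """Pixelwise Pearson correlation of event densities and |depth change|.

    ``density_maps`` is a dict of category -> DensityMap (or a list of such
    dicts, one per trial) and ``abs_change`` the matching HeightChangeMap(s).
    Pixel vectors are concatenated across trials; NaN-change pixels are
    excluded.  Categories absent from a trial contribute zero density there.
    """
    if isinstance(density_maps, dict):
        density_maps = [density_maps]
        abs_change = [abs_change]
    if len(density_maps) != len(abs_change):
        raise ValueError("density_maps and abs_change must align per trial")
    cats: list[str] = []
    for dm in density_maps:
        cats.extend(c for c in dm if c not in cats)
    frames = []
    for dm, cmap in zip(density_maps, abs_change):
        grid = cmap.grid
        valid = np.isfinite(grid)
        if not valid.any():
            raise ValueError("change map has no valid pixels")
        cols = {}
        for c in cats:
            if c in dm:
                cols[c] = dm[c].grid[valid]
            else:
                cols[c] = np.zeros(int(valid.sum()))
        cols["depth_change"] = np.abs(grid[valid])
        frames.append(pd.DataFrame(cols))
    return correlate(pd.concat(frames, ignore_index=True))


def roi_event_counts(linked: pd.DataFrame,
                     daily_rois: dict[int, BowerROI],
                     subject: str = "",
                     scoop_category: str = "bower_scoop",
                     spit_category: str = "bower_spit",
                     day_s: float = 86400.0) -> RoiContingency:
    """Count scoops and spits inside vs outside the daily bower ROIs.

    Linked construction events are assigned to the ROI of their day; days
    without an ROI (no above-threshold change) count every event as
    outside.  The chi-square statistic is the 2x2 Pearson test without
    continuity correction on (in/out x scoop/spit); the ratio is the
    in-ROI count ratio taken in its larger direction.
    """
    ev = linked[(linked["unlinked_reason"] == "") &
                linked["category"].isin([scoop_category, spit_category])]
    counts = {("in", scoop_category): 0, ("in", spit_category): 0,
              ("out", scoop_category): 0, ("out", spit_category): 0}
    days: list[dict] = []
    for day, grp in ev.groupby(
            (ev["timestamp_s"] // day_s).astype(int)):
        roi = daily_rois.get(int(day))
        rows = np.rint(grp["depth_y"].to_numpy(float)).astype(int)
        cols = np.rint(grp["depth_x"].to_numpy(float)).astype(int)
        inside = (roi.mask[rows, cols] if roi is not None
                  else np.zeros(len(grp), dtype=bool))
        rec = {"day": int(day), "has_roi": roi is not None}
        for cat in (scoop_category, spit_category):
            sel = (grp["category"] == cat).to_numpy()
            rec[f"{cat}_in"] = int((sel & inside).sum())
            rec[f"{cat}_out"] = int((sel & ~inside).sum())
            counts[("in", cat)] += rec[f"{cat}_in"]
            counts[("out", cat)] += rec[f"{cat}_out"]
        days.append(rec)
    si, pi = counts[("in", scoop_category)], counts[("in", spit_category)]
    so, po = counts[("out", scoop_category)], counts[("out", spit_category)]
    if si >= pi:
        direction = "scoop_over_spit"
        ratio = si / pi if pi > 0 else math.inf
    else:
        direction = "spit_over_scoop"
        ratio = pi / si if si > 0 else math.inf
    tbl = np.array([[si, pi], [so, po]])
    if (tbl.sum(axis=0) > 0).all() and (tbl.sum(axis=1) > 0).all():
        chi2, p, _, _ = stats.chi2_contingency(tbl, correction=False)
    else:
        chi2, p = float("nan"), float("nan")
    return RoiContingency(scoops_in=si, spits_in=pi, scoops_out=so,
                          spits_out=po, ratio=float(ratio),
                          ratio_direction=direction, chi2=float(chi2),
                          p=float(p), subject=subject, days=days)


def scoop_spit_ratio_summary(contingencies,
                             direction: str = "scoop_over_spit") -> float:
    """Mean per-subject in-ROI count ratio in the stated direction.

    Accepts RoiContingency objects or plain (scoops_in, spits_in) pairs.
    Subjects with a zero denominator are excluded with a warning.
    """
    if direction not in ("scoop_over_spit", "spit_over_scoop"):
        raise ValueError(f"unknown direction {direction!r}")
    ratios = []
    for c in contingencies:
        if isinstance(c, RoiContingency):
            scoops, spits = c.scoops_in, c.spits_in
        else:
            scoops, spits = c
        num, den = ((scoops, spits) if direction == "scoop_over_spit"
                    else (spits, scoops))
        if den == 0:
            warnings.warn("subject with zero denominator excluded from "
                          "ratio summary")
            continue
        ratios.append(num / den)
    if not ratios:
        raise ValueError("no subjects with a nonzero denominator")
    return float(np.mean(ratios))


def hourly_regression(events: pd.DataFrame, series: DepthSeries,
                      category: str, region: str = "depressed",
                      bin_s: float = 3600.0, tau: float | None = None,
                      lights_on_only: bool = True) -> RegressionResult:
    """OLS of hourly change volume (in one sign's regions) on event counts.

    For scoops the natural response is the absolute volume of depressed
    (pit-like) change per hourly bin; for spits, elevated change.  With
    ``tau`` set, only pixels with |dh| >= tau contribute.  The slope
    estimates the sand volume moved per event.
    """
    if region not in ("depressed", "elevated"):
        raise ValueError("region must be 'depressed' or 'elevated'")
    ts = series.timestamps
    intervals = (series.lights_on if lights_on_only
                 else [(float(ts[0]), float(ts[-1]))])
    edges = []
    for lo, hi in intervals:
        lo, hi = max(lo, float(ts[0])), min(hi, float(ts[-1]))
        nbin = int(np.floor((hi - lo) / bin_s + 1e-9))
        edges.extend((lo + k * bin_s, lo + (k + 1) * bin_s)
                     for k in range(nbin))
    ev_t = events.loc[events["category"] == category,
                      "timestamp_s"].to_numpy(float)
    counts, volumes = [], []
    for t0, t1 in edges:
        try:
            cmap = height_change(series, t0, t1, timescale="hourly")
        except ValueError:
            continue
        grid = cmap.grid
        sel = grid < 0 if region == "depressed" else grid > 0
        if tau is not None:
            sel &= np.abs(grid) >= tau
        vol = float(np.nansum(np.abs(np.where(sel, grid, 0.0)))
                    * series.calibration.pixel_footprint_cm2)
        counts.append(int(((ev_t >= t0) & (ev_t < t1)).sum()))
        volumes.append(vol)
    if len(counts) < 3:
        raise ValueError(f"regression requires >= 3 bins, got {len(counts)}")
    counts = np.asarray(counts, dtype=float)
    volumes = np.asarray(volumes, dtype=float)
    if np.ptp(counts) == 0:
        raise ValueError("event counts are constant across bins; "
                         "regression is undefined")
    fit = stats.linregress(counts, volumes)
    return RegressionResult(slope=float(fit.slope),
                            intercept=float(fit.intercept),
                            r2=float(fit.rvalue ** 2),
                            p=float(fit.pvalue), n=len(counts))


def fish_counts_by_behavior(events: pd.DataFrame, fish_counts: pd.DataFrame,
                            max_gap_s: float = 2.0) -> FishCountSummary:
    """Join each event to the nearest fish-count record within a gap.

    Events with no count inside ``max_gap_s`` are dropped from the summary
    and reflected in ``coverage``.  The joined per-event table is the input
    for external mixed-model fitting of count on behaviour with nested
    species/subject/day random effects.
    """
    if "count" not in fish_counts.columns:
        raise ValueError("fish_counts must have a 'count' column")
    if (fish_counts["count"] < 0).any():
        raise ValueError("fish counts must be >= 0")
    ev = events.sort_values("timestamp_s").reset_index(drop=True)
    fc = fish_counts.sort_values("timestamp_s").reset_index(drop=True)
    joined = pd.merge_asof(ev, fc[["timestamp_s", "count"]],
                           on="timestamp_s", direction="nearest",
                           tolerance=max_gap_s)
    coverage = float(joined["count"].notna().mean()) if len(joined) else 0.0
    matched = joined.dropna(subset=["count"]).copy()
    matched["day"] = (matched["timestamp_s"] // 86400.0).astype(int)
    stats_df = (matched.groupby("category")["count"]
                .agg(n="count", mean="mean", sd="std"))
    return FishCountSummary(stats=stats_df, joined=matched,
                            coverage=coverage)
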