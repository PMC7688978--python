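# Methods

`bowerkit` quantifies sand-sculpting ("bower") construction behaviour in
cichlid fish from two data streams: a depth-sensor record of the sand
surface and a classified stream of sand-manipulation events detected in
video.  This note describes the models and numerical choices behind each
stage, what the built-in simulator does and does not emulate, and the known
limitations.

## Depth processing

A trial is a stack of dense distance grids (millimetres from a downward
sensor), nominally one averaged frame per 5-minute window.  Height is the
negative of distance: sand deposited at a pixel moves the surface toward
the sensor, so the signed height change between two times,
`dh(x, y) = (d(x, y, t0) - d(x, y, t1)) / 10` cm, is positive for
castle-like elevation and negative for pit-like depression.

Raw sensor frames carry substantial missing data.  Three steps recover a
usable surface:

1. **Window averaging.**  Raw frames inside each 5-min window are combined
   with a per-pixel NaN-ignoring mean; a pixel is missing in the averaged
   frame only when it is missing in every raw frame.  The averaged frame's
   timestamp is the window midpoint.
2. **Island interpolation.**  Connected components of missing pixels
   (4-connectivity) no larger than `max_island_px` (default 100) are filled
   by piecewise-linear (Delaunay) interpolation from the ring of valid
   pixels surrounding them; islands at the frame border that the convex
   hull cannot cover fall back to nearest-neighbour.  Larger holes are left
   missing, and valid pixels are never altered.  Planar surfaces are
   reproduced exactly.
3. **Savitzky-Golay smoothing.**  Separable polynomial smoothing along
   time, then rows, then columns (windows 5/5, order 2 by default; the
   published pipeline does not state its values, and the separable choice
   is ours — a full 2D fit differs only at higher orders).  Because the
   stacks are gappy, the filter is a masked variant: each window is fitted
   over its valid samples only, provided at least `polyorder + 1` remain,
   otherwise the output sample is missing.  Fit weights depend only on the
   window's validity pattern, so they are cached per pattern and applied
   vectorised.  Edge samples re-use the nearest full window evaluated
   off-centre, which keeps the filter exact for polynomial fields.

   Gappy windows additionally obey a no-extrapolation rule: a sparse fit
   is evaluated only at positions inside the span of its valid samples and
   is marked missing otherwise.  Without this guard, quadratic fits
   anchored on one side of a dropout blob extrapolate sensor noise into
   centimetre-scale spikes that contaminate the stepped Bower Index terms;
   with it, values next to holes are honest interpolations or honest NaNs.

Volumes convert pixel sums to cm^3 through the pixel footprint
(default 0.01 cm^2), chosen so that 1000 contiguous pixels with 1 cm of
change correspond to ~10 cm^3 of sand.

## Structure metrics

Change maps are thresholded at a per-timescale detection threshold (0.18 cm
hourly, 0.5 cm daily, 1.0 cm whole-trial — the maximum values observed in
control recordings without construction, taken as configuration constants).
Elevated and depressed pixels are labeled as separate component populations
(4-connectivity by default, so diagonal noise chains do not merge), and
components below `min_region_px` (1000 at full 480x640 resolution) are
discarded.  The single surviving region of greatest absolute volume is the
bower ROI; ties break toward larger pixel area, then lowest label.  ROI
selection by volume rather than by peak height is a design choice: volume
is the quantity the construction events conserve.

The Bower Index of a change map is `sum(dh) / sum(|dh|)`: -1 for a pure
pit, +1 for a pure castle, 0 for balanced change.  The final index averages
the unthresholded value with three values restricted to pixels above
sequentially increasing thresholds (trial 1/3/5 cm, daily 0.4/0.8/1.2 cm,
2-h 0.2/0.4/0.8 cm, units cm throughout).  Stepped terms with no qualifying
pixels are excluded from the mean rather than set to 0, which avoids
dragging weak builders toward a neutral score.  Note the daily detection
threshold (0.5 cm) sits above the first daily index step (0.4 cm); both
values are kept as published.

Activity fractions report the share of 24-h bins (whole trial) and 2-h bins
(lights-on hours only) whose change map retains at least one
above-threshold region — the quantity behind the observation that
construction is punctuated rather than continuous.

## Registration and linking

A 2x3 affine transform from video pixel coordinates to depth-grid
coordinates is estimated by least squares from user-supplied point
correspondences (>= 3, non-collinear; the fit reports its RMS residual).
Event radii scale by the mean singular value of the linear part.  Each
event links to the surface height at the nearest depth frame in time
(within one cadence, 5 min) and nearest pixel — events cover many pixels,
so sub-pixel interpolation would add only spurious precision.  Events
landing off the grid, over a missing pixel, or with no frame within the
gap stay in the output flagged `outside_grid` / `missing_depth`.

## Event analytics

* **Temporal covariance** pools 60-min bins across trials: per-category
  event counts plus the absolute change volume of each bin.  Bins with
  zero behavioural observations are excluded (they are dominated by
  lights-off time and would inflate correlations).  Pearson R and p are
  computed pairwise; the display order comes from UPGMA clustering of the
  correlation rows under Euclidean distance.
* **Spatial covariance** builds a Gaussian KDE of each category's event
  centers on the depth lattice, with bandwidth equal to half the mean
  estimated event radius (per category and trial), then correlates the
  per-pixel densities with absolute depth change, excluding missing-data
  pixels, pooling pixels across trials.
* **ROI contingency** counts scoops and spits inside vs outside the daily
  bower ROIs.  The statistic is the 2x2 Pearson chi-square without
  continuity correction (the variant is not fully determined by the
  published values; the uncorrected statistic reproduces the textbook
  value 20 for a perfectly associated 10+10 table).  Days without an ROI
  classify every event as outside.
* **Hourly regression** fits OLS of the hourly change volume in depressed
  (for scoops) or elevated (for spits) pixels on the hourly event count;
  the slope estimates the sand volume moved per event.  By default all
  pixels of the matching sign contribute (no threshold): noise pixels add
  a constant intercept but leave the slope unbiased, whereas thresholding
  discards the bump tails and systematically underestimates per-event
  volume.
* **Fish counts** join each event to the nearest count record within 2 s;
  the deliverable is the per-category descriptive table and the joined
  per-event table (with day and subject columns) for external mixed-model
  fitting of `count ~ behavior + (species/subject/day)`.

## The simulator

The simulator generates the full input bundle — depth manifest and frames,
event CSV in video coordinates, fish counts, correspondences — plus ground
truth (noiseless surface history, true event log, true affine).

Generative model, with desk-scale defaults chosen once:

* **Geometry.**  120x160 grid (a miniature of the sensor's 480x640; the
  full resolution is supported), 0.01 cm^2/pixel, sand depth 6.4 cm,
  sensor 580 mm above the surface, 10-h lights-on per day.
* **Construction.**  On a building day (probability 0.6, mirroring the
  ~60% of daily bins with above-threshold change), two sub-hour bursts of
  ~30 scoop-spit pairs occur in random lights-on hours, offset from the
  hour edges so that hourly binning captures whole bouts.  Pit policy:
  scoops Gaussian-scattered around the bower center (sd = radius/2,
  radius 36 px), spits uniform outside a 1.25-radius exclusion disk —
  fish do not spit into their own pit, and uniform-everywhere spitting
  would contaminate the depressed-region volume that the regression
  recovers.  Castle policy is the mirror image.  Each event transfers
  0.2 cm^3 (a desk-scale mouthful) as a truncated-Gaussian bump (sd 4 px)
  renormalised over its in-grid support, so total sand volume is conserved
  exactly; exceeding the tray depth raises an error.  Volume-recovery
  scenarios instead use a full-scale 1.5 cm^3 mouthful at a
  proportionally lower rate, because with 0.2 cm^3 events the bump tails
  sit below the sensor noise floor and any sign-based volume estimate
  loses them.
* **Other behaviours.**  Feeding (~80 events/day) clusters in a ring near
  the tray edge during non-burst hours, giving the temporal anti-phase and
  spatial segregation from construction seen in real trials; quivering and
  spawning sit on the bower center; "shadow/reflection" and "other" events
  scatter over the full video field of view, including off the tray, which
  produces the unlinked-event population.
* **Sensing.**  Each window renders 10 raw frames at distance =
  base - 10*height + N(0, 3 mm), masked by ~40% dropout split evenly
  between a persistent per-window component (small islands at correlation
  scale 1.5 px plus larger blobs at 8 px, which survive averaging and give
  the interpolator realistic work) and a transient per-frame component
  that averaging removes — reproducing the observed ~40% raw -> ~20%
  averaged -> ~10% interpolated progression of missing data.
* **Fish counts.**  A sparse 60-s baseline stream plus one record adjacent
  to each event, Poisson with category-dependent means (build 1.0 < feed
  2.0 < quiver 3.0 < spawn 3.5).
* **Determinism.**  One seed drives every draw; identical seeds reproduce
  byte-identical outputs.

What the simulator does **not** emulate: RGB appearance, fish trajectories
and occlusion, misclassified events (categories are exact), structured
sensor physics (dropout is noise-thresholded rather than
reflection-driven), event radius estimation error beyond small jitter, and
feeding-induced surface change (real control trials show measurable
sub-threshold churn).  Passing recovery tests therefore demonstrate that
the pipeline's estimators are consistent under the stated generative
assumptions — not that classifier noise or optical artifacts are handled.

## Problem sizes and tolerances

The test suite and acceptance script run everything at desk scale: the
minimum region size becomes 60 px (1000 scaled by the grid-area ratio),
sign-recovery sweeps use 20 single-construction-day trials per policy at
default noise, and recovery statistics come from a five-day pit trial with
50 lights-on hourly bins.  Slope recovery is asserted within 15% of the
true per-event volume, ROI centers within one true bower radius, and
correlation sign structure (construction vs feeding negative in time,
construction vs quivering positive in space) exactly.  Numerical
tolerances elsewhere are round-off level (1e-6..1e-12) because the
underlying identities are exact.

## Known limitations

* The masked Savitzky-Golay filter refuses to extrapolate next to large
  dropout blobs, so smoothed frames retain somewhat more missing data than
  an unguarded filter would produce; change maps inherit the union of
  their endpoint frames' holes.
* Detection thresholds are configuration constants taken from the
  published calibration; the helper that re-derives them from
  user-supplied control series applies the same maximum-absent-
  construction rule but cannot validate transfer to other sensors.
* The chi-square variant and the 2-h Bower Index step units are assumed
  (uncorrected Pearson; cm) where the published record is ambiguous.
* Mixed-effects fitting of fish counts is intentionally out of scope; the
  package produces the joined table such a model consumes.
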