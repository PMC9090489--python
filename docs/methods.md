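# Methods

`turtlenav` implements the trajectory-analysis chain used to study the
resolution of the navigational "map sense" of sea turtles migrating to
isolated, submerged-bank targets, together with a generative model of such
migrations so that every stage can be validated against known truth.

## The analysis chain

**Quality control.** Fastloc-GPS fixes are retained when they were computed
from at least 4 satellites with a dimensionless residual error strictly below
35 (positions then good to a few tens of metres). The residual bound is
strict: a residual of exactly 35 is rejected.

**Phase segmentation.** Three boundaries are located per track:

* *beach departure* — the last fix within a configurable radius (default
  5 km) of the nesting beach before sustained movement (>2 km net
  displacement over the following 6 h) with no later return inside the
  radius;
* *oceanic start* — the first fix in water deeper than the isobath threshold
  (default 200 m, the contour that delimits the submerged banks);
* *arrival* — the earliest time T such that every subsequent fix lies within
  `radius_km` (default 20) of the centroid of the post-T fixes and the post-T
  span is at least `min_days` (default 14). The centroid is the foraging goal.

The departure and arrival rules are operational conventions, exposed as
configuration: the underlying behaviours ("left the beach", "settled at the
foraging ground") have no unique observational definition. A consequence of
the residency rule worth knowing: when an animal spends its final days
searching within ~20 km of its goal, detected arrival can precede the actual
goal-reaching moment by those days. The goal location itself is robust
(validated to <10 km on simulations).

**Interpolation.** Tracks are linearly interpolated to 6-h nodes (matching
the temporal resolution of the modelled current fields), linear in latitude
and longitude independently; longitude is interpolated on unwrapped values so
antimeridian crossings are safe. Geodesic interpolation (nodes placed along
the Vincenty geodesic between bracketing fixes at the time fraction) is a
config option; at the <=200 km scale of these migrations near 7 degrees S the
two differ by tens of metres. Fix gaps longer than 48 h (configurable) are
not interpolated across; the track splits into segments. Interpolation never
extrapolates.

**Geodesy.** All distances and bearings use Vincenty's inverse formula on the
WGS-84 ellipsoid (iteration tolerance 1e-12 rad, 200 iterations;
near-antipodal non-convergence raises a distinct error, with a spherical
haversine fallback available). The implementation is verified in the test
suite against an independent implementation of Karney's algorithm
(`geosphere::geodesic_inverse` via Rscript) to <0.01 m and <0.01 degrees on
1000 regional pairs.

**Route metrics.** The *beeline* is the geodesic from the beach-departure
point to the foraging goal; the *path* is the summed geodesic length of the
QC-filtered fixes from departure to arrival, extended to end at the goal
itself (so the straightness index beeline/path is always in (0, 1], with 1
attained only by the geodesic route). Departure direction is the bearing from
the island-exit point (bound to the oceanic-start fix by default) to the
first fix reached after at least 5 km of cumulative travel; its deviation
from the goal bearing is wrapped to (-180, 180] with negative =
counterclockwise, so westward departures on a northward route are negative.
Circular statistics use the unit-vector mean. The short-vs-long migration
comparison (beeline below/above 200 km) uses Welch's t by default (pooled
variance optional: the original analysis does not name the variant).

**Current decomposition.** Each 6-h step is paired with the modelled current
at its start node (bilinear in space with masked-neighbour weight
renormalization; nearest 6-h slice in time, linear optional). Active
swimming is recovered by vector subtraction, `v_swim = v_ground - v_current`.
Off-course movement is the displacement component perpendicular to the
beeline (positive = left of the beeline facing the goal), evaluated in the
local east-north plane (error <0.1% at <=20 km steps). Because subtraction is
linear, per-step and summed perpendicular components obey exact closure
(ground = current + swim, to machine precision) — this is asserted, not
assumed. Sums run from the oceanic start to the first interpolated node back
in shallow water (bank entry). A turtle *compensated* for drift when
|total| < |current component| (signed sums by default; absolute-sum mode is a
flag). The total-vs-swim relationship across turtles is summarized by OLS.

**Depth-class speeds.** Per-turtle mean ground speeds over steps starting in
deep vs shallow water, compared across turtles with a paired t-test (turtles
lacking one class are excluded with a warning). The boundary convention is
strict: depth < threshold is shallow, exactly 200 m is deep; land (depth <= 0)
is shallow for segmentation purposes.

## The generative model

The simulator produces the full causal chain — behaviour, advection,
observation — on a synthetic stage shaped like the study system: an island
origin (land disc with a shallow skirt) and a large elliptical bank whose
200 m isobath falls exactly on the specified ellipse, in a 3000 m basin
(~440 x 440 km domain, 0.02-degree bathymetry grid).

**Currents** are a mean vector (default 0.29 m/s toward 227.8 degrees, the
southwest flow observed during the crossings) plus Gaussian-filtered
space-time noise (default s.d. 0.05 m/s per component, correlation scales
~0.5 degrees and ~1 day) on a 0.08-degree, 6-hourly grid. Velocities are
attenuated over shallow water (factor depth/200 m, floored at 0.15):
open-ocean flow does not extend unchanged onto a bank, and without this a
shallow-water swimmer at 0.25 m/s could never cross against a 0.29 m/s
current — the observed 0.22 m/s shallow ground speeds require weak bank
currents.

**Behaviour** integrates at a 6-min internal step (far below the 6-h
analysis interval, so discretization does not alias the decomposition):

1. *Coastal*: from the nesting beach to an island exit point at 0.25 m/s,
   then a full-speed push off the shallow skirt.
2. *Crossing*: on first entering deep water the turtle draws a persistent
   perceived-bearing error from a von Mises distribution (default mean
   -27.1 degrees — the observed westward departure bias — concentration 4)
   and swims at 0.73 m/s along goal-bearing + error. The departure bearing is
   committed for 12 h; thereafter the error relaxes smoothly toward zero
   (retention 0.92 per 6 h) with small smooth jitter (s.d. ~2 degrees per
   6 h, integrated per internal step as an Ornstein-Uhlenbeck process).
   Smooth relaxation, rather than discrete 6-h turns, reflects the
   near-straight observed ocean legs (leg straightness ~0.91) and keeps the
   path's fine structure resolvable at ~7 fixes/day; it is what gradual
   mid-ocean course corrections look like.
3. *Bank*: on first encountering shallow water the bearing error shrinks
   (residual 0.2 — the observed reorientation toward the target) and speed
   drops by the shallow factor 0.34 (= 0.22/0.64, the observed speed ratio).
4. *Search*: within `map_resolution_km` of the goal (default 50 km) the
   map sense can no longer refine position and the turtle switches to a
   correlated random walk (heading persistence 3 km; turn concentration 3)
   — unbiased in deep water, weakly goal-biased (concentration 1,
   representing local familiarity with the shallow foraging area) on the
   bank. Straying outside the resolution disc re-engages the crude map.
   The goal is "found" within a 2 km capture radius. Search kinematics are
   unconstrained by observation and are documented free parameters; a fully
   unbiased disc search would imply months-long searches, inconsistent with
   observed path lengths (~2x beeline on average).
5. *Residency*: ~16 days of localized wandering (<3 km) at the goal, enough
   to trigger the arrival rule.

Position updates use the WGS-84 meridional/parallel metres-per-degree at the
current latitude, so the integrator is consistent with Vincenty measurement
to <0.01%. All randomness flows from one `numpy` Generator seeded per track.

**Observation** subsamples the truth at Poisson times (default 7.05
fixes/day) with one fix pinned at deployment, adds isotropic Gaussian
position noise (default s.d. 30 m), and synthesizes satellite counts and
residual errors so a configurable fraction (default 0.1) fails quality
control.

### What the generator does and does not emulate

It reproduces the study's sampling statistics, speeds, current regime,
phase structure and the crude-map/search phenomenology. It does not emulate
Argos (non-GPS) positions, tag duty cycling or transmission dropout beyond
Poisson gaps, depth-resolved currents, tides, geomagnetic cues, or any
ecological drivers of behaviour. Passing recovery tests therefore shows the
*analysis chain* is correct and self-consistent under realistic sampling —
not that the behavioural model is the true model of turtle navigation.

## Validation experiments

**Parameter recovery** (`turtlenav.experiments.recovery_experiment`): 100
single-turtle simulations, each with an independent current-field
realization (a shared field would correlate recovery errors and invalidate
the standard error). The pipeline runs on the observed fixes alone; recovered
per-step swimming vectors are then compared with the generator settings over
the oceanic crossing:

* *swim speed* — per-simulation mean of |recovered swim vector| over interior
  crossing steps whose covering fix gaps are all <=4.5 h. Interpolating
  across longer transmission gaps cuts corners and shortens the measured
  displacement by ~0.5-1%; excluding under-sampled steps is a data-quality
  rule, not a tuning knob. A residual ~0.2% deficit remains because the 6-h
  mean of a curving velocity vector is shorter than the instantaneous speed;
  recovery converges to the configured value as the fix rate grows.
* *departure deviation* — the recovered swim-vector bearing of the first 6-h
  step after the oceanic start (while the departure bearing is still held),
  relative to the goal bearing. The *ground* departure bearing is rotated
  ~20 degrees further west by the current, which is exactly why the
  decomposition is needed to talk about the animal's own heading.

**Map-resolution response** (`map_resolution_experiment`): truth-track
straightness across map resolutions {0, 25, 50, 100} km, 50 seeds each with
matched behaviour seeds. Mean straightness decreases monotonically with
resolution (Spearman rank test), the signature that distinguishes a crude
map with terminal search from pinpoint navigation.

## Numerical choices and degenerate inputs

* Bearings in [0, 360); signed differences in (-180, 180] with the -180 wrap
  mapped to +180.
* Coincident points: distance 0; bearing raises a distinct error.
* Vincenty non-convergence (near-antipodal) raises; callers may fall back to
  haversine explicitly.
* Bilinear samplers raise on points outside grid coverage; current sampling
  tolerates half a slice spacing beyond the time axis (snapping to the end
  slice) and renormalizes around masked (land) neighbours, raising only when
  all four neighbours are masked.
* The drift-compensation flag uses a 1e-6 km tolerance so float fuzz in the
  closure arithmetic cannot flip it.
* Isobath crossing points are interpolated linearly in depth between the
  bracketing fixes, clipped to the segment.
* Zero-length analysis windows, empty depth classes, degenerate (constant-x)
  regressions and cancelling circular means all raise informative errors
  rather than returning NaN silently.

## Problem sizes

The shipped validation suite simulates ~20-40 day migrations at 6-min
internal steps (a few thousand steps per track), 100 tracks for recovery and
200 for the map-resolution curve; the full suite and the reporting script
each run in a few minutes on a single core. All sizes are arguments, not
constants.

## Known limitations

* The arrival rule cannot separate terminal search from residency when the
  search already happens inside the residency radius (see above).
* Swim-speed recovery is measured on well-sampled steps; with ~7 fixes/day,
  roughly half the simulated crossings contribute, and tracks with long
  transmission gaps are measured less precisely — exactly as with real tags.
* The real-data reproduction path (CSV of the original per-fix table) is
  implemented and tested structurally, but the original raw table is not
  redistributed here; the corresponding acceptance test reports that absence
  as a failure rather than silently passing.
* Alternative tortuosity measures (fractal dimension, first-passage time)
  are out of scope.
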