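# Methods

This note documents the models, conventions, and numerical choices
behind `zebraswim`, what the synthetic-data generator does and does not
emulate, and the known limitations.

## Coordinates, arenas, and protocols

All geometry is 2-D top-view in millimetres. Circular arenas (well,
dish) are centred on the origin; rectangular tanks have the lower-left
corner at the origin, x right, y up. Tank depth is ignored because
centroid tracking is planar. Four presets cover the standard assays: a
24-well plate well (18 mm inner diameter, 7-dpf larvae), a 35-mm dish
(15-dpf), a 300 × 300 mm open-field/novel tank, and a 210 × 100 mm
mating tank whose third nearest the divider is the "social" region (the
published schematic is not dimensioned; the one-third strip is a fixed,
configurable default). Each arena carries an `edge_band_mm` — the
distance-from-wall band that operationalises "along the edges" —
defaulting to 30 mm for the open tank, 25 mm for the mating tank, and
20 % of the radius for wells.

Region membership is boundary-inclusive, a deterministic tie-break.
Point-in-region queries are validated against a rasterised brute-force
oracle on a 0.1 mm grid.

The larval photomotor protocol exists in two published timings that
disagree: 55 min baseline light plus two 5-light/5-dark cycles (75 min
total), or 20 min adaptation + 40 min baseline + the same cycles
(80 min, analysis from minute 21). Both are provided
(`make_pmr_schedule("methods" | "figure")`) and neither is treated as
canonical; epochs are labelled L0, L1, D1, L2, D2.

## Trajectories and pre-processing

A `Trajectory` carries explicit timestamps (so variable-rate input
degrades gracefully), positions, and a missing-frame mask. On ingest,
points up to 0.5 mm outside the arena are clamped to the wall (tracking
slop); points further out are flagged missing. Missing runs of up to 5
frames are linearly interpolated; longer dropouts stay missing and
split downstream bout/segment analyses, so a lost fish never fabricates
motion.

Tracker jitter is removed with a displacement deadband: a position is
updated only once it moves at least `min_step_mm` (default 0.2 mm,
suitable for larvae) from the last accepted position. The commercial
tracker's unit-less detection threshold is an instrument setting that
cannot be reproduced physically, so it is re-expressed as this
configurable deadband. The operation is idempotent and can only shorten
the path (triangle inequality); the pipeline applies it at ingest so
all distances are computed on deadbanded tracks.

## Kinematics and binning

Distance is the chord sum between consecutive non-missing frames; a
step straddling an analysis-window edge contributes proportionally to
its time overlap (constant speed within a frame interval). Bins are
left-closed right-open and each bin takes the epoch label at its
midpoint — the convention for bins that straddle a light/dark
transition; binning refuses bin widths longer than the shortest epoch,
where labels would be ambiguous. Conservation (Σ bins = whole-window
distance) and rigid-motion invariance are property-tested. A cycle's
photomotor ratio with a zero light-phase mean is returned as NaN with
an `undefined` flag rather than raising, since a fish that freezes
through a light phase is data, not an error.

## Zone occupancy

Dwell time is frame-weighted with symmetric trapezoidal shares
(frame *i* owns the interval from the midpoint of its preceding step to
the midpoint of its following one), which makes occupancy exactly
invariant under time reversal and sums to the analysed duration. Path
length is assigned by the midpoint of each step — a step half in, half
out is not split; the error is bounded by one step length. With these
rules a partition of the arena yields fractions that sum to one
exactly. "Distance away from the social area" is reported as the
complement of the in-region distance fraction; the alternative reading
(mean distance *from* the region) is not used. Heatmaps deposit the
same frame weights on a regular grid (default 5 mm cells for tanks,
0.5 mm recommended for wells), so total mass equals analysed duration.

## Repetitive-behaviour classifiers

**Stereotypic movement.** "Maximum movement distance" is interpreted as
the spatial span — the maximum pairwise distance among window positions
— not net start-to-end displacement, which would label a full lap of
the tank as confined. Within each continuous-swimming interval
(smoothed speed ≥ 1 mm/s, pauses < 0.2 s bridged), a greedy
left-to-right two-pointer scan emits maximal windows with span strictly
below 30 mm and duration strictly above 5 s. The scan relies on one
fact: a span-valid window stays valid when shrunk from the left, so
admitting a frame only requires its maximum distance to the current
window. Emitted windows are verified against an O(n²) all-pairs oracle.

**Large circular movement.** While the fish is inside the edge band,
per-frame increments of the angle about the arena centre (wrapped to
(−π, π]) are accumulated; each accumulation reaching 2π emits one loop,
labelled ccw for positive winding. The accumulator resets when the fish
backtracks more than π/2 from its winding extremum or stays out of the
band longer than 0.5 s (both configurable smoothing parameters; the
band gate can be disabled for sensitivity analyses). On monotone
wall-following paths the loop count equals ⌊|Σ signed angle| / 2π⌋,
and time reversal maps cw loops to ccw loops one-for-one.

**Back-and-forth motion.** In-band positions of a rectangular tank are
projected onto a perimeter arc-length coordinate (ccw from the origin
corner, by nearest-wall projection; per-frame increments are bounded by
the 2-D step length because the projection is discontinuous across
corner diagonals). Turn-around pivots of this 1-D series are extracted
with a hysteresis equal to the 15 mm return radius; an event is a
pivot-to-pivot swing of at least 50 mm whose back-swing re-enters the
return radius of the outbound pivot, restricted to one wall or two
adjacent walls (opposite-wall traversals are excluded). The 50 mm leg
floor is an invented guard against counting millimetre-scale
oscillation; the rule itself gives no length.

## The synthetic swim simulator

Each fish is a discrete-time correlated random walk at the frame rate:
per-frame speed is gamma(shape = 3, mean = `mean_speed_mm_s`); heading
receives wrapped-normal noise (`turn_sd_rad` per frame) and is then
blended, as a weighted vector sum, with steering terms: toward the
nearest wall when beyond the edge band and along it when inside
(`wall_bias`), toward the social-region centre (`social_weight`),
toward the shoal centroid (`cohesion`), and — always — a collision
avoidance term that engages within 10 mm of a wall when the heading
closes on it, veering the fish tangentially with a persistent turning
sense so corners are rounded. Avoidance was added because pure specular
reflection retro-reflects at corners (a double bounce off adjacent
walls turns the fish ~180°), a billiard artifact real fish do not show;
reflection remains as the backstop boundary rule so that unbiased walks
still explore the interior rather than sticking to walls. Speed is
multiplied by `dark_multiplier` during dark epochs.

Defaults represent the study conditions per assay: larvae at 2.5 mm/s
cruise with a dark multiplier of 2; juveniles at 25–35 mm/s; wild-type
versus mutant groups differ in speed, wall bias, social weight,
cohesion, or injected bout rates, matching the phenotype contrast under
study (hypoactive larvae; hyperactive, socially indifferent, loosely
shoaling, stereotypy-prone juveniles).

Injected bouts override the walk with archetypal kinematics and are
logged as ground truth: confined jitter inside a 6 mm disk for 10–14 s
(stereotypic; twice clear of the 30 mm / 5 s rule), 1.25 wall-following
revolutions (circling), and a 100 mm out-and-back along the wall
returning within 7 mm (back-and-forth; twice clear of the 50 mm /
15 mm rule). The out-leg sets off against the arrival drift so the bout
origin is a genuine turn-around, as "returning to the origin"
presupposes. A `hard` mode generates near-threshold bouts for
sensitivity analysis. A single integer seed determines everything;
cohort members get streams split deterministically from it.

Classifier validation uses per-label cohorts of 900-s sessions with a
quiet ballistic background (30 mm/s, no wall bias, heading noise
0.12 rad/frame) and bouts injected at 1/45 s⁻¹. The background rate of
*spontaneous* rule-satisfying events is not zero — a correlated walk
performs a genuine chance out-and-back along a wall roughly once per
15 min — and such unlabelled events bound the measurable precision of
the back-and-forth detector near 0.9; the other two detectors sit at
≈ 1.0. Detections are matched to truth when their overlap exceeds 0.3
of the shorter interval, tolerating the systematic boundary offset
between the detector's 15 mm trigger and the bout's 7 mm return.

What the generator does *not* emulate: burst-and-glide microstructure,
tail-beat kinematics, body posture, occlusion-driven identity swaps in
shoals, arena illumination artefacts, or habituation over a session.
Passing validation therefore shows the analysis code is correct with
respect to its definitions on plausible trajectories — not that the
rules themselves capture everything a human scorer would call
repetitive behaviour in real video.

## Statistics

Groups are compared with the unpaired Student's (pooled-variance)
two-sided *t* test, reported as mean ± SEM with the star convention
(\* < 0.05 down to \*\*\*\* < 0.0001); Welch's test is available by
flag. Two identical constant groups return t = 0, p = 1. No
multiple-testing correction is applied across behavioural panels, and
the report notes this. The per-fish summary (not the per-bin value) is
the unit of analysis. Null calibration over seeded replicates keeps the
empirical type-I rate within binomial noise of α.

## Problem sizes and determinism

The shipped validation runs use desk-scale sizes chosen as the
package's own defaults: 200 random-walk windows (≤ 500 frames) and 100
wall-following paths for oracle equivalence; 100 seeded 900-s sessions
per label for classifier recovery; 200 simulated larvae on a compact
25-min light/dark protocol (5-min baseline plus two 5/5 cycles) for
dark-multiplier recovery; 50 paired seeds for the social and cohesion
orderings; 1000 replicates for null calibration. All randomness flows
from explicit integer seeds; reruns with the same seed produce
byte-identical tracking files and report tables (number formatting is
fixed at six decimals).

## Known limitations

- The perimeter projection underlying back-and-forth detection is
  ambiguous in the corner-diagonal wedges of the band; increments are
  clipped rather than modelled.
- Step-midpoint distance assignment biases zone distance fractions by
  at most one step length per crossing; at 25 fps this is negligible
  for larvae but grows with swim speed.
- The thigmotaxis inner/outer geometry of the published well assay is
  not dimensioned; the default half-radius disk (25 % of area) is a
  convention, and conclusions should be checked against other
  `inner_fraction` settings.
- `simulate_group` batches many independent fish through one random
  stream for speed; per-fish reproducibility independent of cohort size
  holds for `make_cohort`, which splits seeds per fish.
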