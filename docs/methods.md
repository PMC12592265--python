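# Methods

This note documents the models, estimators, detection rules and design
choices behind `antnav`, and what the synthetic validation does and does
not establish about real tracking data.

## Data model

A trajectory is a strictly increasing time vector (seconds) with head-tip
and thorax-centre positions (millimetres, arena frame, +y up the trunk)
per video frame, nominally at 25 frames/s. Coordinates are assumed
already calibrated to millimetres; the reader offers a single scale
factor, but pixel-to-millimetre calibration is the caller's
responsibility. No smoothing is applied by default: metrics are computed
from raw digitised points, and any pre-filtering is left to the caller so
that the estimators stay transparent.

## Kinematics

Steps are thorax displacements between consecutive frames; headings are
step directions; turning angles are heading differences wrapped to
(−180°, 180°]. Zero-length steps have no defined heading, and turning
angles involving them are skipped and counted rather than set to 0 —
fabricating a direction while the animal is stationary would bias the
mean turning-angle cosine upward. Angles are degrees externally and
radians internally.

Speed uses per-step values (step length × frame rate). A step is
*stopped* when its speed falls below `v_stop`; stopped steps are excluded
from both the numerator (distance) and denominator (time) of mean speed.
The default `v_stop` = 0.01 mm/s is kept deliberately conservative — at
25 fps it corresponds to 0.4 µm per frame, far below tracking jitter on
real video, so on real data a larger threshold will usually be
appropriate; it is configurable everywhere and logged with every run.

Body orientation is the direction of the thorax→head axis; frames where
the two points coincide yield an undefined orientation (counted, never
interpolated). Orientation angular velocity is the wrapped orientation
change over the frame interval; the headline summary is the mean
magnitude, with the signed mean also reported.

## Straightness indices

Sinuosity S = 2 [ p ( (1+c)/(1−c) + b² ) ]^(−1/2) with p the mean step
length, c the mean turning-angle cosine and b the step-length CV. b uses
the population-style standard deviation (denominator n); the choice is
recorded and switchable. S carries units of length^(−1/2); no
rediscretisation to constant step length is performed (steps are defined
at consecutive frames), though that option exists for robustness work.

E^a_max = β/(1−β) with β = c, the same sample quantity computed once. We
report the asymptotic value only; a finite-n variant (displacement
expressed as a function of the number of steps) would interpolate toward
it from below, and the asymptotic form is the one that orders paths by
straightness. Degenerate inputs return flagged sentinels instead of
raising: c → 1 yields S = 0 / E^a_max = +inf with a `straight` flag, and
c → −1 yields a `reversal` flag, so batch tables never abort.

Trip duration is the time between the first and last frame inside the
recording area, stops included — distinct from the moving time used for
mean speed.

## Scanning-bout detection

A bout is a maximal interval of stopped steps (after merging intervals
separated by less than `gap_merge` = 0.2 s) that (i) lasts at least
`min_dur` = 0.4 s, (ii) keeps the thorax within `r_max` = 5 mm of the
interval centroid, and (iii) accumulates at least `theta_min` = 45° of
absolute orientation change. Candidate intervals where more than 20% of
orientations are undefined are skipped with a warning. Head-sweep
direction reversals are counted as fixations (+1) and reported, but not
used in any statistic.

No published numeric criteria exist for these thresholds; the defaults
are package choices tuned for 25 fps two-point tracks, surfaced
prominently, configurable, and logged. The detector is deterministic and
monotone in its thresholds (raising `theta_min` or `min_dur` can only
remove bouts), which the property tests enforce.

## Route-outcome classification

The odour band is a rectangle inside the recording area (defaults: arena
700 × 1000 mm; band 500 × 50 mm centred, i.e. x ∈ [100, 600],
y ∈ [475, 525] — the band is narrower than the arena, so in-frame detours
are geometrically possible). A *bottom-to-top passage* is a contiguous
segment rising from below the band bottom to above its top without
dropping back below. A trip is:

- **walked_over** if any passage stays horizontally inside the band's
  x-extent for ≥ 50% of the frames in the vertical span (the 50% rule is
  the tie-break for edge-straddling passages and is recorded in output);
- **detour** if the trip reaches above the band top but every passage is
  horizontally outside the band;
- **u_turn** if the trip approaches within `d_app` = 100 mm below the
  band, never reaches above it, and ends at or below both its entry
  height and the approach line (a net return down and out);
- **incomplete** otherwise (e.g. the recording ends mid-ascent).

Incomplete trips are excluded from frequency denominators. Frequencies
carry exact Clopper–Pearson intervals. The `d_app` default is a package
choice (no published value); classification is symmetric under mirror
reflection about the band centre.

## Statistics

Control-vs-test comparisons use the unequal-variance (Welch) t-test with
Satterthwaite degrees of freedom — the appropriate default when group
variances differ, and consistent with fractional dfs in field reports —
one test per metric with no multiplicity correction by default (an
optional Holm flag exists). A pooled-variance form is available by flag.

The repeated-exposure design uses the one-way within-subject ANOVA:
F = MS_condition / MS_(condition × subject) with df (k−1) and
(k−1)(n−1) — for n = 16 subjects and k = 4 conditions, df = 3, 45. The
Greenhouse–Geisser epsilon and corrected p-value are computed and
reported but not applied to the headline F. The three a priori Helmert
contrasts use coefficient vectors (3,−1,−1,−1), (0,2,−1,−1), (0,0,1,−1),
each scaled to unit sum of squares (orthonormal); per-subject contrast
scores are tested against zero with an exact one-sample t (df = n−1),
and a normal-approximation z is printed alongside for comparability with
reports that quote contrast Z values. Contrast estimates are invariant
to per-subject additive shifts, as within-subject contrasts must be.

## Synthetic data

The generator emulates the statistical structure the estimators assume,
with every population value recorded as ground truth:

- **Steps**: gamma-distributed with mean p* and CV b* (constant when
  b* = 0).
- **Turning angles**: wrapped normal, parameterised by the target mean
  cosine c* via sigma = sqrt(−2 ln c*); c* = 0 uses uniform turns.
- **Head point**: thorax + `head_offset` (2.5 mm) along the body axis,
  which oscillates sinusoidally (±15°, 0.5 s period) about the walking
  direction like a walking ant's head sweep.
- **Foragers**: the heading update blends goal attraction toward the
  current waypoint with the CRW turn (weight 0.35 by default). Waypoint
  sequences implement the three band responses: cross (straight up
  through the band interior), detour (lateral corridor beyond the band's
  x-extent, then up and back), u_turn (approach to 60 mm below the band,
  then down and out the bottom). Goal attraction inflates the sample
  turning-angle cosine relative to c*, so the drift weight is recorded in
  ground truth and parameter-recovery checks use pure (drift-free) CRWs.
- **Implanted events**: stop episodes freeze the thorax with constant
  orientation; scanning episodes freeze the thorax while the body axis
  sweeps sinusoidally with the scripted amplitude (≥ 60°) and ≥ 1 cycle,
  guaranteeing the detector's sweep criterion with margin. Episode times
  refer to the final timeline, so ground-truth boundaries are exact to
  the frame.
- **Arena edges**: the top and bottom edges terminate the trajectory
  (recording-area windowing); the lateral walls reflect. Reflection
  keeps the scripted response mode geometrically unambiguous — a forager
  mid-detour cannot wander out of frame sideways and produce an
  unlabeled truncation — which the ground-truth validation relies on.

Experiment-level generation adds per-ant (paired design) or per-subject
(repeated design, shared across conditions) lognormal intercepts on mean
step length (sd 0.06 on the log) and Gaussian intercepts on c*
(sd 0.012). The built-in condition profiles encode the study conditions
the pipeline is validated under: control c* = 0.95, p* = 1.6 mm,
~0.5 scans/trip, all crossings; odour test c* = 0.85, p* = 1.1 mm,
~4 scans/trip, mixture 35/55/10% cross/detour/U-turn; habituation day 1
c* = 0.82 recovering through 0.89 (day 2) to 0.94 (day 3). These are
package choices of realistic magnitudes — paths that roughly double in
sinuosity and a ~30% speed drop under odour, relaxing monotonically over
repeated exposure.

### What the synthetic validation does and does not show

Passing tests establish that the estimators, detector, classifier and
inference layer are correct for data with exactly the assumed structure
(gamma steps, wrapped-normal turns, motionless scanning, noiseless
digitisation). Real tracking data add digitisation jitter, occasional
mislabelled points, body-length-scale wobble during scanning, and
responses that blur the three route categories; the thresholds
(`v_stop`, scan criteria, `d_app`) would need tuning against such data,
and perfect detector precision/recall on synthetic implants should not
be read as a field-performance claim.

## Problem sizes and numerical choices

Parameter-recovery checks use 10,000-step walks (3-standard-error
bands); detector recovery uses 50 foragers with implants at twice the
detection thresholds; type-I calibration uses 2,000 null replicates at
n = 15 vs 15; the power checks use 100 seeded replicates of the full
pipeline at the study's cell sizes (15 per condition; 16 subjects). The
acceptance script uses 60 replicates for the two power checks. Angle
wrapping uses the convention (−180°, 180°]; oracle comparisons are made
at 1e-12 (algebraic identities) or 1e-9 (trigonometric round trips).
All generators are pure functions of (parameters, seed).

## Known limitations

- 2-D kinematics only; the bark surface's curvature is ignored.
- The asymptotic E^a_max is reported without a finite-n correction.
- Scanning fixation counts are heuristic (sign reversals of the sweep).
- The U-turn rule requires the trip to end below its entry height;
  an ant that aborts its ascent but lingers in frame is `incomplete`.
- The generator does not model sensory mechanisms — response modes are
  scripted, not emergent, so it cannot be used to study *why* ants
  detour, only to validate the measurement pipeline.
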