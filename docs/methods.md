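# Methods

`gazewalk` analyzes where a person looks while walking into a room to
grasp and manipulate an object on a table, with obstacles on the floor
along the way and one more next to the target. The concrete task it
models: walk ~3 m from a hallway through a door, cross a 296 × 480 cm
room past two cups standing on the floor (at 140 and 205 cm from the
door, each on one of two sides 55 cm apart), and pour water from a target
cup on a table (near edge 280 cm from the door) into a destination cup,
without knocking over a third cup placed right next to the target. All
five cups have distinct colors; the analysis identifies them in the scene
camera of a head-mounted eye tracker, uses them as landmarks to localize
the walker, and categorizes gaze frame by frame.

Because no human recordings are bundled, every stage runs against a
synthetic walking-and-gazing simulator whose defaults mirror the study
conditions. The simulator is first-class, tested code: it is what makes
the claims about the analysis chain checkable.

## Coordinate conventions

World frame: origin at the doorway center on the floor, +y into the room,
+x to the walker's right, +z up, lengths in cm. The published layout only
gives distances, so this frame is our choice. The two floor obstacles are
placed symmetrically about the midline at ±27.5 cm (their separation,
55 cm, is given; the midline offset is not, and the scale drawing shows
near-symmetry). A cup's reference point for projection, detection, and
angular gaze distance is its axis at half height ("center of the cup" is
not defined more precisely in the source description).

Camera rays are angular image coordinates (azimuth, elevation) of the 3-D
ray in the head frame, azimuth positive rightward, elevation positive
upward; yaw is applied before pitch and roll is fixed at zero. The scene
camera has an 82° × 82° field of view at ~26 Hz; gaze samples arrive at
~200 Hz. Pixels exist only in image mode via a pinhole tangent mapping
(default 1088 × 1088).

## Synthetic walker

`simulate.WalkerProfile` fixes a participant's eye height (drawn from the
cohort's 149–182 cm range; default 158 cm, the median), walking speed
(95–130 cm/s), start depth (−300 cm, i.e. ~3 m outside the door), and a
path policy: around_left / around_right / between / step_over, or `auto`,
which passes on the free side when both floor cups share a side and
mostly between them otherwise — the behaviors the study reports. The
ground path is a cubic spline through policy-dependent waypoints, walked
at constant speed to a standing point 50 cm before the target cup, then a
4 s standing phase.

Head orientation leads gaze: yaw is the path tangent blended halfway
toward the current gaze target's azimuth, with gaze eccentricity in the
head capped at ±40°; pitch is a 1 Hz low-pass of 0.6 × target elevation.
No head-model parameters are published for this task; these are plausible
values, and nothing downstream depends on them beyond cups staying in
view at sensible times.

`simulate.GazeScript` scripts gaze targets as trial fractions. The
default follows the reported pattern: the target cup from the start,
the floor near each obstacle while entering the room and approaching the
obstacles, then the table obstacle, the target cup, and finally the
destination cup. Blinks are a Poisson process (0.25/s, 100–300 ms,
uniform) that invalidates gaze samples.

`simulate.NoiseModel` is the measurement model. Gaze error is a fixed
offset plus independent per-axis Gaussian noise with the study's reported
figures: offsets −0.5° (horizontal) and +3.9° (vertical), SDs 1.8° and
4.0°. Only means and SDs are reported, so Gaussian is our distribution
choice. Detections drop out with probability 0.02 per cup per frame,
false positives ("light on the floor mistaken for the yellow cup") are
injected at 0.05/frame at random floor points, and detected cup centers
jitter by 0.2° SD per axis — the last is our own addition reflecting that
the reported precision explicitly combines eye tracking with cup
localization error; it also lets tests probe how localization degrades
with detection noise.

What the simulator does **not** emulate: vertical head bob, head roll,
camera rolling shutter or exposure transients, parallax between eye and
scene camera (the reported −0.5° horizontal offset is applied as a
constant instead), the carried cup during pouring within walking trials,
and any gait or hand kinematics. Passing tests therefore show the
analysis chain is internally correct under realistic noise magnitudes,
not that it is robust to every artifact of real recordings.

## Cup detection

In image mode, frames are segmented by circular hue distance
(saturation-gated) to the five nominal cup colors; connected components
≥ 6 px become candidates with centroids converted to rays. In symbolic
mode — the default analysis path — the simulator's detection stream is
used directly as candidates.

The plausibility filter then enforces: (a) a candidate for a cup seen
recently must lie within 8° of its last accepted ray (the largest
inter-frame cup displacement at walking speed stays well below this; ties
go to the nearest ray, then the largest blob); (b) floor-cup rays must
lie below every table-cup ray in elevation, which holds for all reachable
poses in this room (verified by sweeping simulated poses) and is what
rejects sky-high "yellow cups"; (c) when the two floor cups are
configured on opposite sides, their apparent left/right order must match
the configuration. The gating history persists per cup for up to 5 frames
so that one missed frame does not reset the gate; this also makes the
filter idempotent. The very first frame has no history and is resolved by
the geometry rules plus blob size alone, so it is the least reliable.

## Observer localization

Per frame, the walker's (x, y, yaw, pitch) are estimated by minimizing
the sum of squared angular distances between observed cup rays and the
forward model's predictions, with eye height known and roll zero. The
residual is the difference of unit rays (equivalent to angular distance
to second order), minimized by damped Gauss–Newton with finite-difference
Jacobians; convergence at a normalized step < 1e-6 or 100 iterations.
Each frame warm-starts from the previous estimate; otherwise a coarse
grid over the room (orientation pointed at the cup centroid) initializes.

A reliable ("ok") fix requires the three table cups plus at least one
floor cup. The three table cups alone are nearly collinear: a change in
their image separation cannot distinguish viewing distance from viewing
angle, so the lateral position is unobservable. Rather than dropping such
frames we freeze the lateral coordinate (at the last reliable value via
the warm start) and fit only depth, yaw, and pitch, flagging the result
`degenerate`. This keeps the distance-to-target axis defined all the way
to the table — which the occupancy analysis needs — while the lateral
value on those frames is explicitly not to be trusted. Fewer cups than
the three table cups is `insufficient_cups`; a fit that cannot converge
is `diverged`.

The estimated depth and lateral tracks are smoothed with a
Savitzky–Golay filter (40-frame window, order 2, applied per contiguous
valid run; interior gaps ≤ 12 frames are bridged linearly first, longer
gaps stay invalid). Yaw and pitch are not smoothed. Gaze is resampled at
frame times by a local order-2 polynomial fit over a 100 ms window;
frames whose window is more than half invalid are marked invalid, which
propagates blinks to the frame level.

## Gaze categorization

Eleven mutually exclusive categories per frame: the five cups,
cups_on_table, table, floor, elsewhere, blink, none. Cup-center rays come
from the filtered detections when present, else from the pose prediction.
Thresholds are visual angles. A cup "hit" is a gaze–center distance
strictly below 4° — about two horizontal SDs of the combined measurement
noise (2 × 1.8° = 3.6°), rounded up because cups beyond ~1.3 m subtend
less than 4°. Two or more table-cup hits give cups_on_table (the target
and its neighboring obstacle are often both within 4°); exactly one hit
gives that cup; mixed hits go to the angularly nearest. With no hits,
gaze at or above 5° below the target cup's elevation and angularly closer
to the target than the destination cup (or within 20° of the target when
the destination is out of view) is table; strictly below that line is
floor; anything else is elsewhere. Invalid-gaze runs up to 500 ms are
blink, longer ones (or frames without a usable target-cup reference) are
none. The boundaries are deliberate: exactly 4° is not a hit; exactly on
the 5°-below line is table.

"Closer to the blue cup than the purple cup" is evaluated as angular
image distance (the lateral-separation reading is also defensible but
not used). An independent brute-force re-evaluation of these rules,
sharing no code, agrees with the classifier on 10,000 randomized
geometries in the test suite.

## Precision from pouring periods

While pouring, gaze can be assumed locked on the destination cup. Pouring
periods are maximal runs of ≥ 10 frames (~333 ms), starting after the
walker reaches the table (smoothed distance to target ≤ 60 cm; no number
is published for "reached the table"), during which target and
destination cups are < 5° apart in the image — which only happens when
one is held over the other. Per period, the mean and SD of the
gaze-minus-destination azimuth and elevation ("horizontal/vertical
distances" read as camera-frame azimuth/elevation differences); per
participant, the median over periods (robust to periods where the
participant glanced away); finally the mean of those medians across
participants. On synthetic pouring data this recovers the generator's
horizontal offset and SD to well under 0.1° bias.

## Floor mapping and occupancy

Frames categorized floor/turquoise/yellow are mapped to the ground by
exact ray–plane intersection of the world-frame gaze ray from the
smoothed pose; non-descending rays are dropped. A cup-relative
triangulation variant (gaze placed relative to the floor cups' known
positions via their image rays) exists as a cross-check and agrees within
10 cm on noiseless data.

Occupancy curves bin frames by smoothed distance to the target cup
(10 cm bins, analysis range 50–450 cm: from roughly 1.5 m outside the
door, beyond which too few cups are in view to localize, down to
"at the table"). Fractions are pooled unweighted over frames within a
participant, then averaged unweighted across participants; both the
per-participant matrices and the grand mean are computed from counts, so
per-bin fractions sum to one wherever there is data.

## Floor-looking time and ANOVA

The behavioral window runs from smoothed depth y = −100 cm (1 m before
the door) until the smoothed depth first exceeds 140 cm (crossing the
near obstacle's depth; crossing is defined on depth alone, not laterally).
The dependent variable is the fraction of in-window frames in the floor
group; blink/none frames count in the denominator by default (a
total-time reading), with a switch to exclude them.

Cells are per-configuration means over trials, one per participant per
configuration; missing cells are imputed with the participant's mean,
with a warning. With four two-level within factors every one of the 15
effects is a single ±1 contrast per participant, so
F = n·(mean contrast)²/var(contrast) on (1, n−1) df, identical to the
squared paired t; p-values come from the F survival function and no
sphericity correction is needed (or possible) at two levels. The
factorial treats the table-obstacle side as an independent factor (16
cells); geometrically the table obstacle is aligned with the destination
cup, and `place_cups(constrained=True)` reproduces that physically
coupled 8-layout variant.

## Problem sizes and numerics

The bundled analysis drivers use 3 participants × 16 trials to keep the
demo light; the test suite exercises the full 10 × 80 design (symbolic
detection mode) and the ANOVA's type-I calibration with 2000 null
replicates. All randomness flows from integer seeds through
`numpy.random.SeedSequence`, so every simulated artifact is bit-for-bit
reproducible. Degenerate inputs are handled explicitly: tracks shorter
than the smoothing window pass through with a warning, empty detection
streams classify every frame as none, zero-variance ANOVA contrasts
report F = 0 with a warning rather than 0/0.

## Known limitations

- The localization parameterization (joint fit of position and
  orientation with fixed eye height) is one concrete reading of a
  briefly described procedure; it is validated by simulation, not by
  fidelity to the original implementation.
- The simulator's head model and gaze scripts are stylized; between-
  participant variability in gaze policy is limited to timing, path, and
  noise draws.
- Image mode assumes rendered-disk-like color blobs; real video
  (specularities, occlusion, exposure) is out of scope.
- Floor-looking fractions produced by the simulator depend on the script
  and are not calibrated to reproduce any particular observed percentage;
  only the measurement-model figures are.
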