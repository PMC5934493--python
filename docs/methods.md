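# Methods

## The estimation problem

A lower-limb exoskeleton is strapped to a person's pelvis, thigh, shank
and foot.  Because skin, soft tissue and straps are compliant, the
device frame and the skeleton move relative to each other, so the
exoskeleton's joint angles are not the person's joint angles.  The
package implements a purely geometric estimator of the human sagittal
joint angles (hip, knee, ankle flexion-extension) from the exoskeleton
joint angles: the human limb and the device are modeled as one parallel
kinematic chain closed through the physical fixations, and for each
instant the human angles are those that best satisfy the fixation
constraints given the known exoskeleton configuration.  The baseline it
is compared against is the traditional rigid assumption, which copies
the exoskeleton angles over unchanged.

## Kinematic models

Both chains are trees of rigid segments.  Frames follow one convention:
X anterior, Y up (the longitudinal axis, distal to proximal), Z to the
subject's right; a segment's origin is its proximal joint and its
distal joint sits at local (0, −L, 0).  All articulations are revolute
about local Z, positive by the right-hand rule, so flexion is positive
for the right leg; the neutral angle is the posture in which adjacent Y
axes are parallel.  Angles are degrees at every interface; the wrap
convention is (−180, 180] with +180 at the cut.  Knee flexion is
positive here; models exported from conventions with negative knee
flexion need a sign flip.

The human model has a 6-DOF pelvis base, three estimable flexion DOFs,
and two frozen hip parameters (internal/external rotation and
ab-adduction) that are solved once at the static calibration and then
enter the forward kinematics as constants.  Only those five rotational
quantities are modeled because they are the only ones the estimator and
its evaluation ever touch; a fuller generic model would carry the extra
coordinates as dead weight.  The exoskeleton model is a corset (trunk
attachment), thigh bar, shank bar and sole with three parallel-axis
revolute joints and extensible links.  Default anthropometry (pelvis
0.20 m, femur 0.40 m, tibia 0.38 m, foot 0.25 m) are round mid-range
adult values; everything is overridable.

Twelve skin markers are attached in segment-local coordinates: three
on the foot (calcaneus Mk0, fifth metatarsal Mk1, first metatarsal
Mk2), the lateral malleolus Mk3, a shank cluster Mk4–6, the lateral
knee Mk7, a thigh cluster Mk8–10 and the greater trochanter Mk11.  The
published protocol names only Mk0–Mk3, Mk7, Mk11 and the virtual Mk14;
the cluster numbering and exact local coordinates here are the
package's own layout, chosen so each scaling pair (Mk11–Mk7, Mk7–Mk3,
Mk2–Mk1) spans exactly the longitudinal axis of its segment.  That
choice makes marker-pair scaling an exact inverse of the generator (a
pair with an off-axis component would recover a slightly biased
factor).  The exoskeleton carries five markers: hip/knee/ankle motor
centers and the thigh/shank bar midpoints.

## Subject personalization

Scaling factors are measured-to-model distance ratios of the three
marker pairs from a static upright trial without the device: femur from
trochanter–knee, tibia from knee–malleolus, foot from the metatarsal
pair.  Applying a factor scales the segment length, the longitudinal
component of its marker offsets and of its child-joint attachment;
transverse offsets are untouched.  Manual per-segment overrides take
precedence, replacing the interactive visual-inspection step of a
laboratory workflow; a static-calibration residual above 5 mm RMS is
flagged instead of prompting.

The exoskeleton's extensible links are set from the static trial worn
with the device: thigh link = height(Mk11) − height(Mk7), shank link =
height(Mk7) − height(Mk3), "height" being world Y in the upright trial.

## Coupling and calibration

The pelvis is welded to the corset.  The weld translation aligns the
hip rotation centers of the two chains in the anterior-posterior
direction, and — an assumption the source protocol leaves open — in
height as well; the lateral offset is configurable.  The static
(device worn) capture is then solved by marker IK over the base
translation, the three human flexion angles, the exoskeleton hip/knee
angles, and the frozen hip rotation/ab-adduction.  Two quantities are
deliberately not solved there:

* the base rotation is pinned to zero.  The protocol has no pelvis or
  corset markers, so a common rotation of the base about the (aligned)
  hip axes is exactly compensated by shifting both hip angles — a true
  gauge freedom of the data.  Pinning the base rotation (upright stand,
  laboratory-aligned capture volume) removes it.
* the exoskeleton ankle is unobservable at this stage (the sole carries
  no marker) and stays at zero; the sole anchor calibration below
  absorbs the true donning angle consistently.

The fixation constraint set is: a structural pelvis–corset weld (zero
residual rows, equivalent to a 6-DOF constraint), a 2-DOF
point-on-line constraint between a mid-shank tibia point and the shank
bar axis, and three 3-DOF point-to-point constraints between foot sole
points (heel cup, medial and lateral forefoot) and the sole — 11
residual rows in total.  Anchor counterparts on the device are the
static-posture world positions expressed in the device body frames, so
every residual vanishes exactly at the calibration posture.  The
point-on-line basis vectors are fixed at construction to keep the two
residual components continuous over the gait cycle.  Constraint weights
default to shank cuff 4, heel cup 3, forefoot straps 1, reflecting the
relative stiffness of the physical fixations; weighting the heel up
also moves the weighted anchor centroid toward the ankle axis, which
reduces how much unresolvable strap-translation mismatch leaks into the
estimated ankle rotation.  Anchors and weights are configurable because
the physical brace coordinates are not published.

## Ground-truth angles

Ground truth is computed by marker IK: per frame, minimize the weighted
sum of squared model-marker-to-measured-marker distances over the free
coordinates, warm-starting from the previous frame.  During walking the
base pose is frozen at its static value: treadmill walking keeps the
pelvis quasi-stationary, and joint angles are invariant to a common
rigid motion in any case.  During device-worn trials the trochanter,
knee and malleolus markers are occluded and dropped; hip
rotation/ab-adduction stay frozen at their static values.

The exoskeleton ankle needs special handling.  The sole has no marker
of its own; the strapped foot's markers are its only tracer.  A
positional fit of foot-riding points against the device chain amplifies
the centimeter-scale proximal chain slip through a 7–8 cm lever arm and
produces garbage (tens of degrees).  Instead the package uses the
direction from the calcaneus marker to the virtual mid-foot marker
(midpoint of calcaneus and fifth metatarsal, the Mk14 construction):
both points ride the foot, so chain slip cancels in their difference,
and the sagittal rotation taking the statically calibrated sole-local
direction onto the measured direction — expressed in the shank frame
posed at the known hip/knee angles — is the ankle angle in closed form.

## The closure solver

Per frame, the exoskeleton coordinates are clamped to their known
values and the three human angles minimize the stacked, weighted
constraint residuals (11 equations, 3 unknowns) by Levenberg-Marquardt
least squares with an absolute-step forward-difference Jacobian
(degrees and meters are both O(1) scales; a relative step underflows
whenever a coordinate passes through zero).  Warm starts come from the
previous frame; frame 0 starts at the static posture.  Warm starts with
magnitude below 1e-9 are snapped to exact zero because the underlying
MINPACK routine sizes its initial trust region from the start-point
norm.  Tolerances default to 1e-10 with 100 iterations; solutions are
deterministic.  A nested dense grid search (13-point grids refined
until the step falls below 0.005°) serves as an independent brute-force
reference for the same weighted objective in the tests.

## The synthetic laboratory

No recordings accompany the study conditions, so a generator stands in
for the motion-capture laboratory.  It emulates slow treadmill walking:
10 s at 100 Hz, one stride every 2 s (a whole number of strides, so
periodic lag shifts are exact), with per-joint Fourier series whose
default ranges are typical of 1 km/h gait (hip ≈ −8..25°, knee ≈
5..58°, ankle ≈ −11..10°).

Human-to-exoskeleton relative motion is a per-joint affine-plus-lag
surrogate: offset (donning bias), gain (amplitude attenuation through
compliant fixations), lag (transmission delay), plus band-limited noise
derived from the attachment jitter through a nominal 0.4 m lever.  The
"paper-like" preset uses offsets (−1, −3, −2)°, gains (0.97, 0.92,
0.94) and lags (20, 30, 40) ms for hip/knee/ankle, 1.5 mm attachment
jitter and 0.5 mm marker noise.  Offset magnitudes, gains and lag range
follow the documented preset; the signs are this package's choice: a
coherent extension-ward settle of the frame.  With the stated gains, a
*positive* knee offset would largely cancel the knee gain error and
make the rigid baseline anomalously accurate at the knee — the
opposite of the documented qualitative finding that the knee carries
the largest misalignment.  The negative sign is also the physically
coherent one for a frame that sags into extension under gravity.

Marker synthesis runs the human chain under the true human angles and
the device chain under the derived exoskeleton angles from a shared,
static base; human skin markers receive smooth attachment jitter, all
markers receive white measurement noise, and the device-worn walking
trial drops the occluded markers.  All randomness flows from explicit
seeds.

What the generator does not emulate — and what passing tests therefore
do not demonstrate about real data: out-of-sagittal-plane relative
motion; genuinely time-varying or load-dependent strap compliance (the
affine map is constant over a trial); pelvis excursion on the
treadmill; marker occlusion dropouts mid-trial; and any musculature or
dynamics.  Because the sole carries no marker, ankle-level slip between
foot and sole is structurally unobservable in this protocol — a limit
shared with the laboratory protocol being emulated — so the
exoskeleton-ankle "ground truth" is by construction the foot-tracking
estimate, not the unobservable device-side truth.

## Evaluation

Per subject, joint and method: RMSE between estimate and ground truth,
and ROME (range-of-motion error), the difference of the two series'
ranges.  ROME is signed per trial; aggregates use its magnitude.
Improvement percentages are computed from unrounded mean errors and
rounded last.  Method differences are tested per joint and metric with
the two-sided Wilcoxon-Mann-Whitney rank-sum test, exact by full
enumeration of rank assignments (mid-ranks for ties) for combined
sample sizes up to 16 — covering two groups of seven — and the
tie-corrected normal approximation beyond; no multiple-testing
correction is applied.  The test treats the two method error samples as
independent; a paired signed-rank test would be the natural alternative
reading and would be more powerful, but the rank-sum form matches the
test's stated name.

## Study conditions and problem sizes

The full synthetic study uses 7 subjects, each with scale factors drawn
from U(0.92, 1.08), soft-tissue parameters jittered around the
paper-like preset (offsets ×U(0.7, 1.3), gains ±0.02, lags ×U(0.8,
1.25)), and a 10 s walk at 100 Hz.  Unit tests use 1–2 s trials of the
same conditions; the acceptance checks use the full 10 s trials.

## Known limitations

* The estimator corrects the component of relative motion that is
  constant in the fixation geometry (donning offsets) and the
  chain-geometry mismatch; gain- and lag-like relative motion is
  information-theoretically outside a constant constraint model, and
  under it the closure solve trades foot-position mismatch against all
  three angles, which is the dominant residual error source.
* Left limb, torso and frontal/transverse DOFs are out of scope.
* The static calibration is a single posture; a calibration at the
  gait-average posture would reduce the shared bias both estimators
  show at the ankle, but would no longer mirror the emulated protocol.
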