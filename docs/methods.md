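# Methods

## Problem and scope

`limbkin` reconstructs upper-limb joint angles from a distributed chain of
eight inertial measurement units (sternum, shoulder, upper arm, forearm,
hand, thumb, index and middle finger), the instrumentation style used for
kinematic assessment of post-stroke motor impairment during the arm items
of the Fugl-Meyer Assessment (FMA-UE). Each IMU provides a triaxial
gyroscope at 200 Hz and a triaxial accelerometer at 100 Hz; no
magnetometers are used because of their sensitivity to indoor magnetic
disturbance. The package covers the entire processing chain —
sensor-to-segment calibration, global-frame definition, drift-corrected
orientation estimation, joint-angle extraction, target-position features
and the group statistics — together with a rigid articulated arm simulator
that replaces the hardware rig for validation.

## Frames and conventions

* **Anatomical segment frames**: `x` along the segment's longitudinal
  direction. At the neutral pose (arm hanging along the body, fingers
  extended) every segment frame coincides with the body frame: `x` up,
  `y` medio-lateral (lateral = positive; pointing right for a right arm),
  `z` anterior. Quaternions are scalar-first Hamilton; `b_R_a` maps
  coordinates from frame *a* to frame *b*.
* **Global frame**: `z` vertical (up, measured from gravity at the neutral
  pose), `y` horizontal along the hip-flexion rotation axis, `x = y × z`.
* **Joint angles** are reported in degrees, zero at the neutral pose,
  positive for flexion/abduction, negative for extension/adduction. In
  these frames, flexion of a hanging segment is a rotation about `+y`,
  abduction about `-z` and supination about `-x` (right arm); the
  abduction and supination signs mirror for the left arm.

## Sensor-to-segment calibration

Each anatomical axis is the normalized component-wise median of either the
accelerometer during a defined static posture (the gravity direction seen
by the sensor) or the gyroscope during a defined single-axis movement (the
rotation axis seen by the sensor):

    v_seg = median(a_s) / ||median(a_s)||   or   median(w_s) / ||median(w_s)||

The median runs over the whole item window; a separate kernel length is
not needed because items are single postures/movements of a few seconds.
For each sensor two axes are measured, the third is their cross product,
and one of the measured axes (configurable; by default the dynamic one) is
recomputed so the triad `s_R_seg = [x_seg y_seg z_seg]` is exactly
orthonormal and right-handed.

Which item defines which axis is a declarative `CalibrationProtocol`
(YAML-serializable) rather than a hard-coded table. The shipped default:

| item             | kind    | defines                                   |
|------------------|---------|-------------------------------------------|
| `neutral_pose`   | static  | `x` of all 8 segments (gravity), global vertical |
| `hip_flexion`    | dynamic | `y` of sternum and shoulder, global horizontal |
| `arm_flexion`    | dynamic | `y` of upper arm, forearm, hand            |
| `finger_flexion` | dynamic | `y` of thumb, index, middle                |

Dynamic items are drift-corrected with their own lead-in/lead-out static
intervals before the axis median. An oscillating movement measures its
axis only up to sign, so the estimator keeps the hemisphere of the first
above-half-peak sample and the protocol declares that every calibration
movement begins in the anatomically positive direction. Guards:
calibration axes closer than 30° (or further than 150°) apart are
rejected, static items are checked for stillness (gyro norm below 3°/s),
dynamic items for a peak rate above 30°/s, and a median accelerometer norm
below 1 m/s² (free fall / corrupt data) is a degenerate-axis error. All
thresholds are configurable defaults.

The global frame is defined per sensor from the same two reference items:
`z` is the measured gravity (up) direction, `y` the hip-flexion rotation
axis orthogonalized against `z`, `x = y × z`. The alignment reports the
spread of the aligned gravity vectors across sensors as a quality
diagnostic (noise-free simulated scenes give < 0.001°).

## Orientation estimation

Per sensor and task, in order:

1. **Static detection** — maximal runs with gyro norm < 3°/s lasting at
   least 0.25 s (half-open, 0-based sample intervals).
2. **Zero-velocity drift removal** — the bias inside each static interval
   is its mean rate; between consecutive intervals the bias is linearly
   interpolated, anchored at the interval time-centroids so a linearly
   ramping bias is removed exactly; it is held constant outside the outer
   intervals; samples inside static intervals are forced to exactly zero.
   A constant bias with two or more static intervals is removed to
   machine precision.
3. **Gradient-descent fusion** — a Madgwick-style filter: Euler
   integration of the gyro quaternion rate followed by a normalized
   gradient step (gain `beta` = 0.033 rad/s) toward the measured gravity
   direction, evaluated at the *predicted* quaternion. Evaluating the
   correction after the gyro update removes the one-sample lag a
   correct-at-previous-estimate formulation exhibits under steady
   rotation (about 0.22° at 45°/s and 200 Hz). Accelerometer samples with
   norm outside [0.5 g, 1.5 g] skip the correction (gyro-only) and are
   counted. Heading is observable only through the gyro; heading errors
   therefore cancel exclusively in *relative* (joint) quantities, which is
   what the package reports.
4. **Initial orientation** — each task is assumed to start in (or near)
   the calibration neutral posture: the initial quaternion is the
   global-frame alignment, tilt-corrected against the mean accelerometer
   of the task's initial static interval (heading kept from the
   alignment). This per-task re-anchoring bounds the drift any single
   task can accumulate and is what makes a mis-calibrated posture visible
   as a constant angle offset rather than a growing one.

The order *drift-correct, then filter* was chosen over filtering raw gyro:
the interpolated-bias correction is a deterministic preprocessing step and
keeps the filter's single gain interpretable. Segment orientation follows
by right-composition with the calibration, `g_R_seg(t) = g_R_s(t) s_R_seg`.

## Joint angles

Flexion/abduction-type channels: the distal segment's longitudinal axis,
expressed in the proximal frame, is projected onto the joint's plane,

    v_p = v - (v·n / ||n||^2) n,    theta = atan2(||v1 x v2||, v1·v2),

signed by `(v1 × v2)·sign_axis`. The elbow, wrist and finger
flexion/extension planes are normal to the proximal medio-lateral axis
(excluding ulnar/radial deviation); shoulder flexion uses the sternum's
sagittal plane (normal `y`) and shoulder abduction the frontal plane
(normal `z`). Note the sign axis is necessarily collinear with the plane
normal — `v1 × v2` lies along it — and encodes the positive rotation
direction per side.

Forearm pronation/supination has no plane-projection form; it is computed
as the twist component of the upper-arm-to-forearm relative rotation about
the forearm's longitudinal axis (swing-twist decomposition), zeroed at
neutral. This is an interpretation: the measurement protocol reports the
angle but does not define its computation.

Degenerate samples: when the distal axis is nearly normal to a projection
plane the angle is ill-conditioned (e.g. the abduction channel of an arm
flexed to exactly 90°, whose projection onto the frontal plane vanishes).
Samples with a projected norm below `sin(1°)·||v||` are marked missing
(NaN) and processing continues; the hard single-projection error threshold
is `1e-6·||v||`. Ground truth and reconstruction apply the same rule, and
round-trip comparisons use jointly defined samples.

All channels are zero-referenced to the neutral pose. With calibrated
frames the neutral angles are zero by construction; the pipeline still
subtracts the angles implied by the estimated calibration at the neutral
posture so that calibration offsets cannot masquerade as resting angles.

## Features and statistics

The target-position window of a repetition is the longest interval of at
least 0.5 s in which the task's primary channel (shoulder abduction for
tasks 1 and 3, shoulder flexion for tasks 2 and 4) stays within 10 % of
the repetition range of its extremum (the minimum for extension-type
movements); manual windows may override. The feature per channel is the
median over the window — robust to edge transients; a channel with more
than half its window samples missing yields a missing feature.

Subjects are grouped by the FMA-UE arm subscore: ≤ 22 is the more affected
group 1. Per-subject features are the mean over the three repetitions.
Within-group comparisons (non-affected vs affected arm) use the paired
Wilcoxon signed-rank test; between-group comparisons of the same arm use
the Mann-Whitney U test; all two-sided at α = 0.05 with no
multiple-testing correction, matching the clinical reporting convention.
Exact permutation null distributions are used whenever the data are
tie-free and small (n ≤ 25); zero differences are dropped and ties receive
mid-ranks under the normal approximation otherwise; identical paired
samples return p = 1 by convention.

The type-I-error check simulates both tests under the null with 12 pairs
(Wilcoxon) and 10 vs 10 (Mann-Whitney): sizes at which the discrete exact
distributions can attain a level close to 0.05 (≈ 0.042/0.043). At the
study's own sizes (6 and 4 subjects) the largest attainable level below
0.05 is 0.031, so a ±0.02 calibration band around 0.05 is structurally
out of reach — a property of exact tests at tiny n, not of the
implementation.

## The simulator

The rigid chain is a kinematic tree with per-joint intrinsic rotations in
the order flexion → abduction (shoulder) and flexion → twist (forearm).
Movement profiles are minimum-jerk rise/hold/return curves
(`s(τ) = 10τ³ − 15τ⁴ + 6τ⁵`) with analytic rates; task 4's wrist channel
is a sinusoid under a minimum-jerk envelope. Task templates follow the
four FMA-UE-derived protocol items (hand-to-ear within the flexor
synergy; shoulder flexion 90° with the elbow extended; shoulder abduction
90°; wrist flexion/extension at 70° shoulder flexion), with a `synergy`
preset that couples elbow flexion and shoulder abduction to the primary
movement to emulate the pathological flexor synergy. Timing defaults: 2 s
lead-in static, 2 s minimum-jerk rise, 2 s hold, 2 s return, 2 s tail —
slow, guided movements with clean static anchors, as in a supervised
clinical protocol.

Per sensor, gyro = mounting⁻¹ · (segment angular velocity in the segment
frame) + bias + white noise at 200 Hz, with the angular velocity computed
analytically by the recursive chain rule. The accelerometer carries the
gravity-only specific force at 100 Hz, linearly interpolated onto the gyro
timebase exactly as the ingestion path does. Gravity-only is the default
because the protocol's movements are slow and the pipeline uses the
accelerometer purely as an inclination reference; linear acceleration at
the mounting point is deliberately not modelled (stress tests can inject
out-of-range accelerometer samples instead, which the filter gates).
Mounting rotations are uniformly random per scene from the scene seed, so
calibration is always exercised nontrivially.

Default error model (the conditions of the headline validity test):
constant gyro bias of norm 0.01 rad/s in a random per-sensor direction,
gyro noise σ = 0.005 rad/s, accelerometer noise σ = 0.05 m/s², no
accelerometer bias; identical seeds reproduce identical streams.

### What the simulator does and does not show

The simulator is a *rigid* chain with perfectly repeatable movements,
ideal mounting (no soft-tissue artefact, no strap slip), gravity-only
accelerometry and white, stationary sensor errors. Passing round-trip
tests therefore validates the algorithmic chain — calibration algebra,
drift correction, fusion, angle extraction, feature logic — under the
stated error model. It does not validate robustness to skin motion,
movement variability between repetitions, magnetic or thermal effects, or
imperfectly performed calibration postures; the mis-calibration scenario
(a 20°-flexed elbow during calibration reading as −20° apparent
overextension at true full extension) is modelled explicitly precisely
because it is the dominant real-world artefact of this method family.

## Numerical choices

* Quaternions renormalized every step; traces assert unit norm within 1e-6
  at construction and 1e-9 in tests.
* Rotation-matrix invariants: orthonormal within 1e-8, det +1 within 1e-8.
* Accelerometer upsampling: linear interpolation onto the gyro timebase
  (the simplest scheme consistent with its use as a slowly varying
  inclination reference).
* Static intervals are half-open, 0-based sample index pairs.
* Angle wrap-around maps to (−180°, 180°]; NaN marks missing samples.
* Validity-suite problem sizes: 10 s scenes at 200 Hz, eight sensors,
  five to seven single-joint movements; chosen to mirror one repetition of
  a guided clinical movement.

## Known limitations

* Heading is gyro-only; absolute heading drifts and only relative angles
  are meaningful. All reported channels are relative.
* Projection angles degenerate when the moved segment aligns with a plane
  normal; affected samples are reported missing rather than extrapolated.
* The forearm supination channel is a defined interpretation (twist
  decomposition); other conventions (e.g. Euler sequences) differ at
  combined large elbow/shoulder configurations.
* The left-arm protocol is the sagittal mirror of the right-arm one; it is
  exercised in simulation only.
* Exact tests at the study's group sizes have a granular p-value lattice;
  significance at 0.05 should be read accordingly.
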