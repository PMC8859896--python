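# Methods

`imukin` estimates lower-extremity joint kinematics from body-worn inertial
measurement units (IMUs) and quantifies how well — and for how long — those
estimates hold up. This note documents the models, conventions, numerical
choices and known limitations.

## Frames and conventions

* **Earth/ground frame**: right-handed, Z up, X along the horizontal
  component of the magnetic field measured during initialization
  ("magnetic north"), Y completing the triad. The skeletal model's ground
  frame is the same frame; any offset between the subject's facing direction
  and magnetic north is absorbed by sensor-to-segment calibration.
* **Quaternions**: scalar-first `(w, x, y, z)`, mapping sensor- or
  segment-frame vectors into the ground frame. `q` and `−q` are one
  rotation; outputs canonicalize `w ≥ 0` and all comparisons are
  angle-based.
* **Accelerometers measure specific force**: a static sensor with its z
  axis up reads `(0, 0, +9.81)` m/s². Sign errors here are the dominant
  failure mode of attitude pipelines, hence the explicit statement.
* **Units**: radians and SI internally; degrees in every file written or
  read (joint-angle and diagnostic outputs), seconds everywhere.

## Orientation distance

All error metrics, the IK objective and the screening rules use one scalar:
the angle of the axis-angle form of the relative rotation between two
orientations,

    theta = arccos((tr(Ra^T Rb) − 1) / 2)  =  2 arccos(|⟨qa, qb⟩|).

`rotation_angle` clamps the arccos argument into [−1, 1] so rounding can
never produce NaN; `orientation_difference` uses an atan2 formulation of the
same quantity, which keeps full precision near zero where arccos loses ~8
digits (this matters for the filter-equivalence contracts below).

## Sensor fusion

Two complementary filters and a baseline are provided, all sharing one
integration primitive (a normalized quaternion-derivative Euler step driven
by the trapezoidal midpoint of adjacent gyro samples), so that with all
corrective gains at zero the three are numerically identical:

* **Gradient-descent filter (Madgwick)** — gain `beta` (rad/s), default 0.1
  for 100 Hz data; 0.025 is the appropriate retuning at 40 Hz, where 0.1
  over-corrects. Two deliberate departures from the classic published step:
  1. *Predictor–corrector ordering.* The measurement gradient is evaluated
     at the gyro-propagated state rather than the pre-step state. The
     accel/mag sample belongs to the post-step instant; evaluating the
     gradient one sample early creates a phantom error of order ω·dt
     (≈1.4° at 2.5 rad/s and 100 Hz) toward which the normalized correction
     constantly steers, which dominated zero-noise tracking error.
  2. *Soft normalization.* The gradient is scaled by
     `1 / max(‖g‖, 0.02)`. The classic unit-norm step applies a full
     `beta·dt` kick however small the residual, leaving a `beta·dt`
     amplitude limit cycle (0.057° at default settings); below the floor
     the step becomes proportional and vanishes at the fixed point.
  The gravity/magnetic-field Jacobians are the standard simplified
  (unit-quaternion) closed forms; the magnetic reference is re-derived each
  step from the current estimate as a horizontal-plus-vertical field
  `(bx, 0, bz)`, so only heading information is taken from the magnetometer.
* **PI filter (Mahony)** — error signal from cross products of measured vs
  predicted gravity (and field) directions; `kp` (default 0.5) drives the
  proportional correction, `ki` (default 0, i.e. off) integrates the error
  into a gyro-bias estimate. Defaults are deliberately conservative since
  only the gradient filter's gain was tuned in the validation study this
  package emulates.
* **Gyro-only strap-down integration** — the drift baseline.

Initialization is a TRIAD construction from the mean accelerometer and
magnetometer over the standing-rest window (default 5 s): gravity fixes
earth Z, the horizontal field fixes earth X. The filter then runs over all
samples, so output timestamps match input. Per-sample dt comes from
timestamps, not the nominal rate, for robustness to dropped samples.

**Magnetometer duty-cycling** (`mag_divisor` m: use the magnetometer every
m-th update) is available per sensor as a mitigation for floor-level
ferromagnetic disturbance, which hits foot sensors hardest; it trades
heading stability against disturbance rejection and is off (m=1) by default.

## Kinematic model

The default chain has 19 coordinates: a 6-dof free joint to ground for the
pelvis (3 rotations tilt/list/rotation + 3 translations), a 3-dof lumbar
ball joint carrying the torso, and per side a 3-dof ball hip
(flexion/adduction/rotation), a 1-dof pin knee and a 1-dof pin ankle
(plantarflexion–dorsiflexion, with the distal foot joints treated as
welded). Eight virtual IMU sites mirror the validation protocol: upper back
(T2), lower back (L5), bilateral thigh/shank/foot.

Ball-joint rotations are intrinsic flexion→adduction→rotation about the
mediolateral / anteroposterior / vertical segment axes — the standard
gait-analysis angle set; the rotation order is a convention choice
documented in the model config (the named angles do not determine it).
The knee is a pure pin: the small coupled translations of an
anatomically-fitted knee affect marker-based inverse kinematics but not
orientation-only tracking, so the rotational dof is kept and translations
dropped (an approximation, listed here deliberately). The all-zero pose is
the neutral standing calibration pose. Coordinate bounds default to
generous physiologic ranges (hip flexion ±120°, knee 0–140°, ankle ±60°)
and are configurable; pelvis heading is effectively unbounded so that
accumulated turning is representable.

Forward kinematics composes joint rotations root-first; segment positions
(from nominal segment geometry) exist only for the synthetic generator —
orientation-only IK never uses them, which is also why the model needs no
subject-specific scaling.

## Calibration

With the model posed at the calibration pose `q_cal` (default: the zero
pose; an externally supplied pose is accepted to reproduce protocols that
posed the model from optical data), each sensor's fixed rotational offset is

    R_offset_i = R_segment(q_cal)^T · R_i^measured,

where the measured orientation is the sign-aligned quaternion mean over the
calibration window, with the window's worst deviation from the mean
reported (warning above 10°, optionally an error). By construction the
virtual IMU reproduces the measured orientation exactly at `q_cal`, so IK on
the calibration frame returns `q_cal`.

`heading_align` optionally rotates each offset about earth Z so all sensors
agree with a reference sensor's heading at `q_cal`: with zero-pose
calibration, per-sensor magnetometer heading disagreement otherwise injects
a constant hip-rotation bias. It is off by default; inclination is never
touched.

## Inverse kinematics

Per frame, the solver minimizes `Σᵢ wᵢ·θᵢ(q)²` over the non-frozen
coordinates, where θᵢ is the orientation distance between sensor i's
measured orientation and its virtual IMU `R_segment(q)·R_offset_i`. Rather
than optimizing the angles directly (arccos is non-smooth at 0, exactly
where solutions live), each sensor contributes the 3-vector rotation vector
of the residual rotation scaled by √wᵢ to a least-squares residual —
`‖rotvec‖ = θ`, so the squared norm is the same objective with a smooth
parameterization. Frames are solved by bounded trust-region least squares
(scipy `least_squares`, method `trf`) with 2-point numeric Jacobians, tight
tolerances (ftol/xtol 1e-15), and warm starts from the previous frame;
frame 0 starts at the zero pose. Pelvis translations are frozen:
orientations carry no translation information.

Default weights downweight distal sensors — 1.0 for torso/pelvis/thighs,
0.5 shanks, 0.25 feet — because floor-proximity magnetic disturbance
corrupts distal heading most and propagates chiefly into hip rotation.
The exact values are a monotone-decreasing convention, config-overridable.

Multimodality (hip internal/external rotation ambiguity under
heading-corrupted sensors) is handled only by warm starting; there is no
global search. A sensor absent from a frame (NaN) has its term dropped, not
interpolated; a sensor with no data at all is removed from the problem
outright, making a zero-weight run bit-identical to a sensor-removed run.

## Screening

Two rules applied to each sensor's IK orientation differences over the
first 10 s of a trial: (i) any sample above 45° (poor tracking), and
(ii) mean of per-60-ms-bin ranges above 30° (unrealistic variability). Bins
are `round(bin_ms·rate/1000)` samples (6 at 100 Hz), floored at 2 samples
with a warning at low rates, final partial bin dropped. Values exactly at a
threshold do **not** fire (strict inequality). Rule (i) uses the window
maximum — the strictest simple reading of "exceeded a threshold"; a mean
statistic is available by configuration. Screening runs one all-sensor IK
pass over the window; the recommended workflow is screen → zero the
excluded sensors' weights → re-run IK on the full trial.

## Evaluation statistics

Per-window (default 60 s = per-minute) RMS of the wrapped angle difference;
ordinary least-squares drift fit of per-minute RMS against time (slope in
deg/min; `r²` is the with-intercept coefficient of determination, which is
non-negative — out-of-sample conventions that can go negative are not
used); Pearson correlation (errors rather than NaN on constant input);
integer-sample cross-correlation synchronization with ties broken toward
zero lag and boundary maxima flagged; median/IQR summaries with 1.5·IQR
outlier fences using type-7 (linear-interpolation) quantiles so outlier
counts are reproducible. Bilateral coordinates can be pooled by base name,
pooling subject-minute RMS values.

## Synthetic trials

The generator emulates the validation protocol's structure: every trial
opens with 5 s of the zero (standing) pose, then ramps smoothly (2 s
smoothstep) into movement; activities are `static_pose`, `walk`,
`walk_turn` (alternating smooth 180° heading ramps every 10 s, emulating
walk-5-m-and-turn), and `activity_cycle` (sit / stand / stairs / side-step /
walk / run blocks with blockwise amplitude and cadence modulation). Gait
profiles are smooth sinusoids per coordinate at a set cadence (default
100 steps/min → 1.2 s stride period; hip flexion 20° about 5°, knee
30°±30°, ankle ±10°, smaller pelvis/lumbar terms; left side phase-shifted
by π). These are *not* biomechanically exact gait curves — they are
band-limited, bounded trajectories that exercise every code path. Passing
tests therefore demonstrate pipeline correctness and noise/drift behavior,
not clinical accuracy on real gait; soft-tissue artifact, foot-impact
transients and non-stationary magnetic environments are all absent.

The forward signal model is the exact inverse of what the pipeline
estimates: true sensor orientation `R_seg(q(t))·R_offset` with per-sensor
planted offsets (random 5–25° mountings); gyro as the sensor-frame angular
velocity from central differences of the true orientations (one-sided at
the ends) so generator and model can never disagree; accelerometer as
re-oriented gravity by default (`gravity_only=True`, an idealized sensor —
the default because the round-trip contracts describe ideal measurements),
with optional full specific force from double-differentiated site
positions; magnetometer as the earth field (unit-order, 60° inclination)
seen through an optional per-sensor, time-windowed heading rotation
emulating floor-level ferromagnetic disturbance.

Default noise is consumer-MEMS order: gyro white-noise density
0.005 rad/s/√Hz, constant per-axis gyro bias drawn with sd 0.002 rad/s,
accel white noise 0.05 m/s², magnetometer noise 1% of field, optional gyro
bias random walk (off). One `numpy` Generator seeded explicitly threads
through every stochastic call; same seed → bit-identical trials.

## Problem sizes and tolerances

Long-duration checks fuse at the full 100 Hz but solve IK on a subsampled
timeline — 5 Hz for the 10-minute drift experiment (per-minute RMS uses 300
frames per minute), 20 Hz for the 60-s round trip, 10 Hz for the
downweighting experiment — chosen as comfortable sampling margins for the
statistics computed from them. Filter fixed-point and equivalence contracts
are held to 1e-9 rad; conversion round trips to 1e-12; IK convergence to
cost changes below ~1e-15 with 200-ish residual evaluations per frame
budgeted. Quaternion dispersion above 10° in a calibration window warns;
screening thresholds are strict inequalities; angle differences are wrapped
to (−180°, 180°] before squaring (a safety net — gait angles live far from
the wrap).

## Known limitations

* Orientation-only: no position tracking, kinetics, or zero-velocity
  updates.
* The knee pin ignores anatomical coupled translations; the lumbar joint is
  a guess at 3 dof (configurable).
* Static zero-pose calibration inherits the subject's actual pose error;
  functional/anatomical calibration methods are out of scope.
* Hip rotation is the least observable coordinate under heading
  disturbance; downweighting mitigates but does not remove this.
* The gradient filter's soft-normalization floor (0.02) is a fixed
  regularization constant, not adaptive.
* Real-time operation and vendor binary formats are out of scope.
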