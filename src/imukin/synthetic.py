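"""Synthetic trials: ground-truth joint trajectories and the IMU signals a
sensor array would record while executing them.

The generator emulates the structure of the validation protocol: 8 sensors
(upper/lower back, bilateral thigh/shank/foot), a 5-s standing calibration
window at the start of every trial, and 10-min walking-and-turning or
mixed-activity conditions sampled at 100 Hz (40 Hz variant available).

Joint trajectories are smooth parametric sinusoid profiles at a set gait
cadence — band-limited and bounded, sufficient to exercise every pipeline
stage, but not biomechanically exact gait curves.  The forward signal model
is the exact inverse of what the pipeline estimates: sensor orientation
``R_i(t) = R_segment(q(t)) R_offset_i``; gyro from orientation finite
differences (so generator and model can never disagree); accelerometer as
specific force; magnetometer as the earth field seen through an optional
time-varying heading disturbance emulating floor-level ferromagnetic
distortion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from .fusion import ImuSeries, OrientationSeries
from .model import SENSOR_IDS, KinematicModel, Pose, build_default_model
from .rotations import (
    quat_canonical,
    quat_from_axis_angle,
    quat_multiply,
    quat_normalize,
    quat_rotate,
    quat_to_rotvec,
    quat_conjugate,
)

__all__ = [
    "TrajectoryConfig",
    "NoiseModel",
    "MagDisturbance",
    "SyntheticTrial",
    "generate_trajectory",
    "synthesize_imu",
    "generate_trial",
    "make_study_fixture",
    "corrupt_heading",
    "default_offsets",
]

GRAVITY = 9.81
#: Earth magnetic field (arbitrary units): horizontal component along +X
#: with a realistic downward inclination.
DEFAULT_MAG_FIELD = np.array([0.5, 0.0, -0.866])


@dataclass
class TrajectoryConfig:
    """Ground-truth trajectory parameters.

    ``activity``: static_pose | walk | walk_turn | activity_cycle.
    ``cadence_spm`` is steps per minute (stride frequency = cadence/120 Hz).
    ``profiles`` maps coordinate → (amplitude_deg, offset_deg, phase_rad)
    for the sinusoidal gait profile; defaults emulate moderate walking.
    Every trial starts with ``calibration_s`` seconds of the zero (neutral
    standing) pose, ramped into movement over ``ramp_s`` seconds.
    """

    duration_s: float = 600.0
    rate_hz: float = 100.0
    activity: str = "walk"
    cadence_spm: float = 100.0
    profiles: Mapping | None = None
    turn_interval_s: float = 10.0
    turn_angle_deg: float = 180.0
    turn_ramp_s: float = 1.5
    calibration_s: float = 5.0
    ramp_s: float = 2.0
    seed: int = 0

    def __post_init__(self):
        if self.activity not in ("static_pose", "walk", "walk_turn", "activity_cycle"):
            raise ValueError(f"unknown activity {self.activity!r}")
        if self.rate_hz <= 0 or self.duration_s <= 0:
            raise ValueError("rate_hz and duration_s must be positive")


#: (amplitude_deg, offset_deg, phase_rad) of each right-side/axial gait
#: profile; left-side coordinates use the same numbers phase-shifted by pi.
DEFAULT_GAIT_PROFILES = {
    "pelvis_tilt": (3.0, 2.0, 0.0),
    "pelvis_list": (4.0, 0.0, 0.5),
    "pelvis_rotation": (8.0, 0.0, 0.0),
    "lumbar_extension": (3.0, -2.0, 0.0),
    "lumbar_bending": (2.0, 0.0, 1.0),
    "lumbar_rotation": (3.0, 0.0, 2.0),
    "hip_flexion": (20.0, 5.0, 0.0),
    "hip_adduction": (5.0, 0.0, 1.2),
    "hip_rotation": (5.0, 0.0, 2.4),
    "knee_flexion": (30.0, 30.0, 4.0),
    "ankle_flexion": (10.0, 0.0, 5.2),
}


@dataclass
class MagDisturbance:
    """Time-varying rotation of the local magnetic field about earth Z,
    emulating ground-proximity ferromagnetic distortion."""

    amplitude_deg: float
    t_on: float = 0.0
    t_off: float = math.inf

    def rotation(self, t: float) -> np.ndarray | None:
        if self.t_on <= t < self.t_off and self.amplitude_deg != 0.0:
            return quat_from_axis_angle([0, 0, 1], math.radians(self.amplitude_deg))
        return None


@dataclass
class NoiseModel:
    """Consumer-MEMS-order sensor noise.

    ``gyro_noise_density`` is the white-noise density (rad/s/sqrt(Hz));
    the per-sample standard deviation is density * sqrt(rate).
    ``gyro_bias_sd`` draws one constant per-axis bias per sensor (rad/s);
    ``gyro_bias_walk_sd`` adds a per-sample random walk on that bias.
    Magnetometer noise is absolute in the (unit-order) field units.
    ``mag_disturbance`` maps sensor id → :class:`MagDisturbance`.
    """

    gyro_noise_density: float = 0.005
    gyro_bias_sd: float = 0.002
    gyro_bias_walk_sd: float = 0.0
    accel_noise_sd: float = 0.05
    mag_noise_sd: float = 0.01
    mag_disturbance: dict = field(default_factory=dict)

    def __post_init__(self):
        for name in (
            "gyro_noise_density",
            "gyro_bias_sd",
            "gyro_bias_walk_sd",
            "accel_noise_sd",
            "mag_noise_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


ZERO_NOISE = NoiseModel(0.0, 0.0, 0.0, 0.0, 0.0)


@dataclass
class SyntheticTrial:
    """A complete simulated trial: truth plus synthesized raw signals."""

    model: KinematicModel
    t: np.ndarray
    coords: tuple
    q: np.ndarray  # (n, n_coords) ground-truth pose trajectory
    labels: list
    offsets: dict  # planted sensor-to-segment rotations (quaternions)
    sensor_truth: dict  # sensor id -> OrientationSeries (ground truth)
    imu: dict  # sensor id -> ImuSeries
    config: TrajectoryConfig
    noise: NoiseModel
    seed: int

    def truth_angles_deg(self) -> dict:
        out = {}
        for i, c in enumerate(self.coords):
            col = self.q[:, i]
            out[c] = col.copy() if self.model._is_translation(c) else np.degrees(col)
        return out

    def pose(self, k: int) -> Pose:
        return Pose(self.coords, self.q[k].copy())


def _smoothstep(x):
    x = np.clip(x, 0.0, 1.0)
    return x * x * (3.0 - 2.0 * x)


def generate_trajectory(model: KinematicModel, config: TrajectoryConfig):
    """Ground-truth joint trajectory and per-sample activity labels.

    Returns ``(t, Q, labels)`` with ``Q`` in radians, shape
    ``(n, n_coords)``.  The first ``calibration_s`` seconds are the zero
    pose; profiles then ramp in smoothly (no discontinuities).
    """
    n = int(round(config.duration_s * config.rate_hz)) + 1
    t = np.arange(n) / config.rate_hz
    nc = len(model.coordinates)
    Q = np.zeros((n, nc))
    labels = np.array(["calibration"] * n, dtype=object)
    if config.activity == "static_pose":
        labels[t >= config.calibration_s] = "static_pose"
        return t, Q, list(labels)

    profiles = dict(DEFAULT_GAIT_PROFILES)
    if config.profiles:
        profiles.update(config.profiles)
    f_stride = config.cadence_spm / 120.0  # one full stride cycle per leg
    ramp = _smoothstep((t - config.calibration_s) / max(config.ramp_s, 1e-9))
    labels[t >= config.calibration_s] = "walk"

    # activity_cycle modulates amplitude/cadence blockwise (smoothly)
    amp_scale = np.ones(n)
    freq_scale = np.ones(n)
    static_knee = np.zeros(n)  # extra quasi-static knee/hip flexion (sitting)
    if config.activity == "activity_cycle":
        blocks = [
            ("sit", 10.0, 0.15, 0.3),
            ("stand", 5.0, 0.0, 0.3),
            ("stairs", 15.0, 1.3, 1.0),
            ("sidestep", 10.0, 0.8, 0.9),
            ("walk", 15.0, 1.0, 1.0),
            ("run", 15.0, 1.3, 1.6),
        ]
        cycle_T = sum(b[1] for b in blocks)
        tt = np.maximum(t - config.calibration_s, 0.0) % cycle_T
        edges = np.cumsum([0.0] + [b[1] for b in blocks])
        for (name, _dur, a_s, f_s), lo, hi in zip(blocks, edges[:-1], edges[1:]):
            m = (tt >= lo) & (tt < hi) & (t >= config.calibration_s)
            labels[m] = name
            # cosine taper over 1 s inside each block edge keeps it smooth
            local = np.clip(np.minimum(tt[m] - lo, hi - tt[m]), 0.0, 1.0)
            w = _smoothstep(local)
            amp_scale[m] = a_s * w + amp_scale[m] * 0.0 + (1 - w) * 0.3
            freq_scale[m] = f_s
            if name == "sit":
                static_knee[m] = math.radians(70.0) * w

    phase = 2.0 * math.pi * f_stride * np.cumsum(freq_scale) / config.rate_hz

    lo = np.array([model.bounds[c][0] for c in model.coordinates])
    hi = np.array([model.bounds[c][1] for c in model.coordinates])
    for i, cname in enumerate(model.coordinates):
        base = cname
        side_phase = 0.0
        if cname.endswith("_r"):
            base = cname[:-2]
        elif cname.endswith("_l"):
            base = cname[:-2]
            side_phase = math.pi
        if base not in profiles:
            continue
        amp, off, ph = profiles[base]
        # offset and amplitude scale together so bounded profiles (knee
        # flexion >= 0) stay bounded under blockwise amplitude modulation
        col = amp_scale * (
            math.radians(off) + math.radians(amp) * np.sin(phase + ph + side_phase)
        )
        if base in ("knee_flexion", "hip_flexion"):
            col = col + static_knee
        Q[:, i] = ramp * col

    if config.activity == "walk_turn":
        # alternating smooth 180-degree heading ramps every turn interval
        heading = np.zeros(n)
        t_move = config.calibration_s + config.ramp_s
        turn_t = t_move + config.turn_interval_s
        direction = 1.0
        while turn_t < t[-1]:
            s = _smoothstep((t - turn_t) / config.turn_ramp_s)
            heading = heading + direction * math.radians(config.turn_angle_deg) * s
            direction = -direction
            turn_t += config.turn_interval_s
        labels[(np.abs(np.gradient(heading, t)) > 0.1)] = "turn"
        Q[:, model.coord_index["pelvis_rotation"]] += heading

    if np.any(Q < lo - 1e-12) or np.any(Q > hi + 1e-12):
        bad = [
            model.coordinates[i]
            for i in range(nc)
            if Q[:, i].min() < lo[i] - 1e-12 or Q[:, i].max() > hi[i] + 1e-12
        ]
        raise ValueError(f"trajectory exceeds model bounds for {bad}")
    return t, Q, list(labels)


def default_offsets(rng: np.random.Generator, sensors=SENSOR_IDS) -> dict:
    """Random plausible sensor-to-segment mounting rotations (5-25 deg)."""
    out = {}
    for s in sensors:
        axis = rng.normal(size=3)
        angle = math.radians(rng.uniform(5.0, 25.0))
        out[s] = quat_from_axis_angle(axis, angle)
    return out


def synthesize_imu(
    model: KinematicModel,
    t: np.ndarray,
    Q: np.ndarray,
    offsets: Mapping[str, np.ndarray],
    noise: NoiseModel | None = None,
    rng: np.random.Generator | None = None,
    gravity: float = GRAVITY,
    mag_field: np.ndarray = DEFAULT_MAG_FIELD,
    gravity_only: bool = True,
    registration_mapping: Mapping[str, str] | None = None,
):
    """Forward signal model: raw IMU streams for every sensor in ``offsets``.

    Returns ``(imu_map, sensor_truth)``.  ``gravity_only=True`` (default)
    makes the accelerometer read pure re-oriented gravity — an idealized
    sensor; with ``False`` the linear acceleration of the sensor site
    (double-differentiated site position) is added.
    """
    noise = noise or ZERO_NOISE
    rng = rng or np.random.default_rng(0)
    n = len(t)
    dt = float(np.median(np.diff(t)))
    rate = 1.0 / dt
    mapping = registration_mapping or {s: model.site_segment(s) for s in offsets}

    # segment orientations for every frame (fast scalar path)
    seg_quats = np.empty((n, len(model.segments), 4))
    for k in range(n):
        seg_quats[k] = model.segment_quats(Q[k])

    positions = None
    if not gravity_only:
        positions = {s: np.empty((n, 3)) for s in offsets}
        for k in range(n):
            ors, pos = model.forward_kinematics(Pose(model.coordinates, Q[k]))
            for s in offsets:
                site = model.imu_sites[s]
                positions[s][k] = pos[site.segment] + ors[site.segment] @ site.position

    imu_map, truth_map = {}, {}
    g_vec = np.array([0.0, 0.0, -gravity])
    for s, off in offsets.items():
        seg_i = model._seg_index[mapping[s]]
        off = quat_normalize(off)
        q_true = np.empty((n, 4))
        for k in range(n):
            q_true[k] = quat_canonical(quat_multiply(seg_quats[k, seg_i], off))
        truth_map[s] = OrientationSeries(s, t.copy(), q_true)

        # gyro: sensor-frame angular velocity from orientation differences
        gyro = np.empty((n, 3))
        for k in range(n):
            if k == 0:
                dq = quat_multiply(quat_conjugate(q_true[0]), q_true[1])
                gyro[k] = quat_to_rotvec(dq) / dt
            elif k == n - 1:
                dq = quat_multiply(quat_conjugate(q_true[-2]), q_true[-1])
                gyro[k] = quat_to_rotvec(dq) / dt
            else:
                dq = quat_multiply(quat_conjugate(q_true[k - 1]), q_true[k + 1])
                gyro[k] = quat_to_rotvec(dq) / (2.0 * dt)

        accel = np.empty((n, 3))
        lin_acc = np.zeros((n, 3))
        if positions is not None:
            p = positions[s]
            lin_acc[1:-1] = (p[2:] - 2.0 * p[1:-1] + p[:-2]) / dt**2
            lin_acc[0] = lin_acc[1]
            lin_acc[-1] = lin_acc[-2]
        mag = np.empty((n, 3))
        disturbance = noise.mag_disturbance.get(s)
        for k in range(n):
            qc = quat_conjugate(q_true[k])
            accel[k] = quat_rotate(qc, lin_acc[k] - g_vec)
            fld = mag_field
            if disturbance is not None:
                D = disturbance.rotation(t[k])
                if D is not None:
                    fld = quat_rotate(D, mag_field)
            mag[k] = quat_rotate(qc, fld)

        if noise.gyro_noise_density > 0:
            gyro = gyro + rng.normal(0.0, noise.gyro_noise_density * math.sqrt(rate), (n, 3))
        if noise.gyro_bias_sd > 0:
            gyro = gyro + rng.normal(0.0, noise.gyro_bias_sd, 3)
        if noise.gyro_bias_walk_sd > 0:
            gyro = gyro + np.cumsum(rng.normal(0.0, noise.gyro_bias_walk_sd, (n, 3)), axis=0)
        if noise.accel_noise_sd > 0:
            accel = accel + rng.normal(0.0, noise.accel_noise_sd, (n, 3))
        if noise.mag_noise_sd > 0:
            mag = mag + rng.normal(0.0, noise.mag_noise_sd, (n, 3))

        imu_map[s] = ImuSeries(s, t.copy(), gyro, accel, mag, rate)
    return imu_map, truth_map


def generate_trial(
    model: KinematicModel | None = None,
    config: TrajectoryConfig | None = None,
    noise: NoiseModel | None = None,
    seed: int = 0,
    offsets: Mapping[str, np.ndarray] | None = None,
    gravity_only: bool = True,
) -> SyntheticTrial:
    """Generate a complete trial (trajectory + truth + raw IMU streams).

    Regenerating with the same arguments and seed is bit-identical.
    """
    model = model or build_default_model()
    config = config or TrajectoryConfig()
    config = replace(config, seed=seed)
    noise = noise or ZERO_NOISE
    rng = np.random.default_rng(seed)
    t, Q, labels = generate_trajectory(model, config)
    offsets = dict(offsets) if offsets is not None else default_offsets(rng)
    imu_map, truth_map = synthesize_imu(
        model, t, Q, offsets, noise, rng, gravity_only=gravity_only
    )
    return SyntheticTrial(
        model=model,
        t=t,
        coords=model.coordinates,
        q=Q,
        labels=labels,
        offsets=offsets,
        sensor_truth=truth_map,
        imu=imu_map,
        config=config,
        noise=noise,
        seed=seed,
    )


def corrupt_heading(
    series: OrientationSeries,
    heading_deg: float,
    t_on: float = 0.0,
    alternate_deg: float = 0.0,
) -> OrientationSeries:
    """Compose a constant earth-frame heading error (optionally alternating
    sample-to-sample by ±alternate_deg) onto an orientation stream from
    ``t_on`` — emulating a sensor that starts mis-tracking after
    calibration."""
    q = series.q.copy()
    for k in range(len(series)):
        if series.t[k] < t_on:
            continue
        ang = math.radians(heading_deg)
        if alternate_deg:
            ang += math.radians(alternate_deg) * (1.0 if k % 2 == 0 else -1.0)
        if ang == 0.0:
            continue
        Rz = quat_from_axis_angle([0, 0, 1], ang)
        q[k] = quat_canonical(quat_multiply(Rz, q[k]))
    return OrientationSeries(series.sensor_id, series.t.copy(), q)


def make_study_fixture(
    seed: int = 0,
    duration_s: float = 600.0,
    rate_hz: float = 100.0,
    noise: NoiseModel | None = None,
) -> dict:
    """Trial suite emulating the validation protocol: a walking-and-turning
    condition and a mixed-activity condition, 8 sensors with distinct
    planted offsets, foot sensors exposed to magnetic disturbance segments.

    Returns ``{"walk_turn": SyntheticTrial, "activity": SyntheticTrial}``.
    """
    model = build_default_model()
    if noise is None:
        noise = NoiseModel(
            mag_disturbance={
                "calcn_r_imu": MagDisturbance(20.0, duration_s * 0.3, duration_s * 0.6),
                "calcn_l_imu": MagDisturbance(20.0, duration_s * 0.5, duration_s * 0.8),
            }
        )
    trials = {}
    for i, activity in enumerate(("walk_turn", "activity_cycle")):
        cfg = TrajectoryConfig(duration_s=duration_s, rate_hz=rate_hz, activity=activity)
        trials["walk_turn" if activity == "walk_turn" else "activity"] = generate_trial(
            model, cfg, noise, seed=seed + i
        )
    return trials
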