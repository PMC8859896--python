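"""Orientation-tracking inverse kinematics on the constrained chain.

Per frame, the solver finds the joint-angle vector q minimizing

    sum_i  w_i * theta_i(q)^2,

where ``theta_i`` is the axis-angle difference between sensor i's measured
orientation and the model's virtual IMU orientation
``R_segment(q) R_offset_i``, and ``w_i`` are per-sensor weights.  Distal
sensors (shank, foot) are downweighted by default because floor-level
magnetic disturbance corrupts their heading most; reducing their influence
measurably improves hip-rotation accuracy.

Implementation notes: each weighted term contributes the 3-component
rotation vector of the residual rotation, scaled by sqrt(w_i), to a
least-squares residual (|rotvec| = theta, so the squared norm equals the
objective and the residual is smooth at theta = 0 where arccos is not).
Frames are solved by bounded trust-region least squares with numeric
Jacobians, warm-started from the previous frame; pelvis translations are
frozen (orientations carry no translation information).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .calibration import SensorRegistration
from .model import KinematicModel, Pose

__all__ = ["DEFAULT_WEIGHTS", "IKResult", "ik_frame", "ik_trajectory", "cost"]

log = logging.getLogger(__name__)

#: Default per-sensor weights: unit weight for proximal sensors, distal
#: sensors downweighted (shank 0.5, foot 0.25).
DEFAULT_WEIGHTS = {
    "torso_imu": 1.0,
    "pelvis_imu": 1.0,
    "femur_r_imu": 1.0,
    "femur_l_imu": 1.0,
    "tibia_r_imu": 0.5,
    "tibia_l_imu": 0.5,
    "calcn_r_imu": 0.25,
    "calcn_l_imu": 0.25,
}

_FTOL = 1e-15
_XTOL = 1e-15
_GTOL = 1e-12
_MAX_NFEV = 4000


@dataclass
class IKResult:
    """Joint-angle trajectory with per-sensor orientation-difference
    diagnostics.

    ``theta_deg`` maps sensor id → per-frame axis-angle difference between
    measured and virtual IMU orientation (degrees); ``cost`` is the weighted
    sum of squared differences (radians²) actually minimized.
    """

    t: np.ndarray
    coords: tuple
    q: np.ndarray  # (n_frames, n_coords), radians / meters
    theta_deg: dict
    cost: np.ndarray
    iterations: np.ndarray
    converged: np.ndarray

    def pose(self, k: int) -> Pose:
        return Pose(self.coords, self.q[k].copy())

    def angles_deg(self) -> dict:
        """Joint angles in degrees keyed by coordinate (translations in m)."""
        out = {}
        for i, c in enumerate(self.coords):
            col = self.q[:, i]
            out[c] = col.copy() if c.startswith("pelvis_t") and c[-1] in "xyz" else np.degrees(col)
        return out


class _FrameProblem:
    """Pre-compiled residual for one model + registration + weight set."""

    def __init__(self, model, registration, weights, frozen):
        self.model = model
        self.coords = model.coordinates
        trans = {c for j in model.joints for c in j.translations}
        frozen = set(frozen) | trans
        self.free_idx = np.array(
            [i for i, c in enumerate(self.coords) if c not in frozen], dtype=int
        )
        self.lb = np.array([model.bounds[self.coords[i]][0] for i in self.free_idx])
        self.ub = np.array([model.bounds[self.coords[i]][1] for i in self.free_idx])
        self.sensors = []  # (sensor_id, segment_index, offset_quat, sqrt_weight)
        for sensor_id, segment in registration.mapping.items():
            w = float(weights.get(sensor_id, 1.0))
            if w < 0:
                raise ValueError(f"negative weight for {sensor_id!r}")
            if w == 0.0:
                continue
            self.sensors.append(
                (
                    sensor_id,
                    model._seg_index[segment],
                    tuple(registration.offsets[sensor_id]),
                    math.sqrt(w),
                )
            )
        if not self.sensors:
            raise ValueError("no sensor with positive weight")

    def residual(self, x, qvec, measured):
        """measured: list aligned with self.sensors of (w,x,y,z) tuples or
        None (term dropped)."""
        qvec[self.free_idx] = x
        seg_q = self.model.segment_quats(qvec)
        out = np.zeros(3 * len(self.sensors))
        for j, (sid, seg_i, off, sw) in enumerate(self.sensors):
            m = measured[j]
            if m is None:
                continue
            pw, px, py, pz = seg_q[seg_i]
            bw, bx, by, bz = off
            # virtual = segment ∘ offset
            vw = pw * bw - px * bx - py * by - pz * bz
            vx = pw * bx + px * bw + py * bz - pz * by
            vy = pw * by - px * bz + py * bw + pz * bx
            vz = pw * bz + px * by - py * bx + pz * bw
            mw, mx, my, mz = m
            # err = conj(measured) ∘ virtual
            ew = mw * vw + mx * vx + my * vy + mz * vz
            ex = mw * vx - mx * vw - my * vz + mz * vy
            ey = mw * vy + mx * vz - my * vw - mz * vx
            ez = mw * vz - mx * vy + my * vx - mz * vw
            if ew < 0.0:
                ew, ex, ey, ez = -ew, -ex, -ey, -ez
            s = math.sqrt(ex * ex + ey * ey + ez * ez)
            if s < 1e-9:
                scale = 2.0 * sw
            else:
                scale = sw * 2.0 * math.atan2(s, ew) / s
            k = 3 * j
            out[k] = scale * ex
            out[k + 1] = scale * ey
            out[k + 2] = scale * ez
        return out


def _theta_cost(problem, qvec, measured, weights_sqrt_used=True):
    r = problem.residual(qvec[problem.free_idx].copy(), qvec.copy(), measured)
    theta = {}
    total = 0.0
    for j, (sid, _seg, _off, sw) in enumerate(problem.sensors):
        if measured[j] is None:
            theta[sid] = math.nan
            continue
        block = r[3 * j : 3 * j + 3]
        th = float(np.linalg.norm(block)) / sw
        theta[sid] = math.degrees(th)
        total += (sw * th) ** 2
    return theta, total


def _measured_list(problem, measured_map):
    out = []
    for sid, _seg, _off, _sw in problem.sensors:
        q = measured_map.get(sid)
        if q is None or (hasattr(q, "__len__") and np.any(np.isnan(q))):
            out.append(None)
        else:
            out.append(tuple(np.asarray(q, float)))
    return out


def _solve(problem, qvec, measured):
    x0 = np.clip(qvec[problem.free_idx], problem.lb, problem.ub)

    def fun(x):
        return problem.residual(x, qvec.copy(), measured)

    res = least_squares(
        fun,
        x0,
        jac="2-point",
        bounds=(problem.lb, problem.ub),
        method="trf",
        ftol=_FTOL,
        xtol=_XTOL,
        gtol=_GTOL,
        max_nfev=_MAX_NFEV,
    )
    q_out = qvec.copy()
    q_out[problem.free_idx] = res.x
    return q_out, res


def ik_frame(
    model: KinematicModel,
    registration: SensorRegistration,
    measured: dict,
    weights: dict | None = None,
    q_init: Pose | None = None,
    frozen: tuple = (),
):
    """Solve one frame.  Returns ``(pose, theta_deg_map, cost)``.

    ``measured`` maps sensor id → sensor-to-earth quaternion; sensors missing
    from it (or with NaN entries) are dropped from the objective for the
    frame.  ``cost`` is in radians².
    """
    weights = DEFAULT_WEIGHTS if weights is None else weights
    # a sensor with no measurement at all is dropped from the problem
    # outright, which makes weight-0 and sensor-absent runs bit-identical
    w_eff = {
        s: (float(weights.get(s, 1.0)) if s in measured else 0.0)
        for s in registration.mapping
    }
    problem = _FrameProblem(model, registration, w_eff, frozen)
    qvec = (q_init.q.copy() if q_init is not None else np.zeros(len(model.coordinates)))
    meas = _measured_list(problem, measured)
    if all(m is None for m in meas):
        raise ValueError("no measured orientation available for any weighted sensor")
    q_out, res = _solve(problem, qvec, meas)
    theta, total = _theta_cost(problem, q_out, meas)
    if res.status <= 0:
        log.warning("IK frame did not converge (status %d)", res.status)
    return Pose(model.coordinates, q_out), theta, total


def ik_trajectory(
    model: KinematicModel,
    registration: SensorRegistration,
    orientations: dict,
    weights: dict | None = None,
    q0: Pose | None = None,
    frozen: tuple = (),
) -> IKResult:
    """Solve a whole trial frame by frame with warm starts.

    ``orientations`` maps sensor id → :class:`~imukin.fusion.OrientationSeries`
    sharing identical timestamps (resample upstream if needed).  Frame 0 is
    initialized from ``q0`` (default: zero pose); frame k from the frame k-1
    solution.
    """
    weights = DEFAULT_WEIGHTS if weights is None else weights
    w_eff = {
        s: (float(weights.get(s, 1.0)) if s in orientations else 0.0)
        for s in registration.mapping
    }
    problem = _FrameProblem(model, registration, w_eff, frozen)
    series = {s: orientations[s] for s, _seg, _off, _sw in problem.sensors
              if s in orientations}
    if not series:
        raise ValueError("no weighted sensor has an orientation series")
    t_ref = next(iter(series.values())).t
    for s, ser in series.items():
        if len(ser) != len(t_ref) or not np.allclose(ser.t, t_ref, atol=1e-9):
            raise ValueError(f"orientation series for {s!r} is not time-aligned")
    n = len(t_ref)
    nc = len(model.coordinates)
    qvec = q0.q.copy() if q0 is not None else np.zeros(nc)
    Q = np.empty((n, nc))
    cost_arr = np.empty(n)
    iters = np.empty(n, dtype=int)
    conv = np.empty(n, dtype=bool)
    theta_out = {s: np.full(n, np.nan) for s, _seg, _off, _sw in problem.sensors}
    for k in range(n):
        meas_map = {}
        for s, ser in series.items():
            meas_map[s] = ser.q[k]
        meas = _measured_list(problem, meas_map)
        if all(m is None for m in meas):
            log.warning("frame %d: no usable sensor, holding previous pose", k)
            Q[k] = qvec
            cost_arr[k] = math.nan
            iters[k] = 0
            conv[k] = False
            continue
        qvec, res = _solve(problem, qvec, meas)
        theta, total = _theta_cost(problem, qvec, meas)
        Q[k] = qvec
        cost_arr[k] = total
        iters[k] = res.nfev
        conv[k] = res.status > 0
        for s, th in theta.items():
            theta_out[s][k] = th
    return IKResult(
        t=t_ref.copy(),
        coords=model.coordinates,
        q=Q,
        theta_deg=theta_out,
        cost=cost_arr,
        iterations=iters,
        converged=conv,
    )


def cost(
    model: KinematicModel,
    registration: SensorRegistration,
    measured: dict,
    weights: dict | None,
    pose: Pose,
) -> float:
    """The weighted-squared orientation-difference objective at ``pose``
    (radians²): pure function, no optimization."""
    weights = DEFAULT_WEIGHTS if weights is None else weights
    problem = _FrameProblem(model, registration, weights, frozen=())
    meas = _measured_list(problem, measured)
    _theta, total = _theta_cost(problem, pose.q.copy(), meas)
    return total
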