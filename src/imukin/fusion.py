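"""Per-sensor orientation estimation from raw gyro/accel/mag streams.

Two complementary filters are provided — a gradient-descent filter (Madgwick)
whose single gain ``beta`` (rad/s) scales the accelerometer/magnetometer
correction, and a proportional–integral filter (Mahony) with gains ``kp`` and
``ki`` whose integral term tracks gyro bias — plus a pure strap-down
gyroscope-integration baseline for drift comparisons.

Conventions
-----------
* Estimated quaternions map sensor-frame vectors to the earth frame
  (Z up; X = horizontal magnetic field direction at initialization).
* Accelerometers measure specific force: a static sensor with its z axis up
  reads ``(0, 0, +9.81)`` m/s².
* With all corrective gains at zero, every filter reduces to the identical
  quaternion-derivative integration step, so ``madgwick(beta=0)``,
  ``mahony(kp=ki=0)`` and ``integrate_gyro`` agree to rounding.
* The magnetometer can be duty-cycled: it is incorporated only on every
  ``mag_divisor``-th update, an option for sensors near strong floor-level
  magnetic disturbance (e.g. foot sensors over in-ground force plates).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
import numpy as np

from .rotations import (
    matrix_to_quat,
    orientation_difference,
    quat_normalize,
)

__all__ = [
    "ImuSeries",
    "OrientationSeries",
    "FilterConfig",
    "DegenerateFieldError",
    "initial_orientation",
    "madgwick_step",
    "mahony_step",
    "integrate_gyro",
    "run_filter",
    "fusion_error",
]

log = logging.getLogger(__name__)


class DegenerateFieldError(ValueError):
    """Raised when accelerometer/magnetometer geometry cannot fix a frame."""


@dataclass
class ImuSeries:
    """Timestamped triaxial gyro (rad/s), accel (m/s²) and mag (consistent
    arbitrary units) samples for one sensor, all in the sensor frame."""

    sensor_id: str
    t: np.ndarray
    gyro: np.ndarray
    accel: np.ndarray
    mag: np.ndarray
    rate_hz: float

    def __post_init__(self):
        self.t = np.asarray(self.t, float)
        self.gyro = np.asarray(self.gyro, float)
        self.accel = np.asarray(self.accel, float)
        self.mag = np.asarray(self.mag, float)
        n = len(self.t)
        for name in ("gyro", "accel", "mag"):
            arr = getattr(self, name)
            if arr.shape != (n, 3):
                raise ValueError(f"{name} must have shape ({n}, 3), got {arr.shape}")
        if n > 1 and np.any(np.diff(self.t) <= 0):
            raise ValueError("timestamps must be strictly increasing")

    def __len__(self):
        return len(self.t)


@dataclass
class OrientationSeries:
    """Sensor-to-earth orientation quaternions (scalar-first) over time."""

    sensor_id: str
    t: np.ndarray
    q: np.ndarray

    def __post_init__(self):
        self.t = np.asarray(self.t, float)
        self.q = np.asarray(self.q, float)
        if self.q.shape != (len(self.t), 4):
            raise ValueError(f"q must have shape ({len(self.t)}, 4), got {self.q.shape}")

    def __len__(self):
        return len(self.t)

    def slice(self, t0: float, t1: float) -> "OrientationSeries":
        m = (self.t >= t0) & (self.t < t1)
        return OrientationSeries(self.sensor_id, self.t[m], self.q[m])


@dataclass
class FilterConfig:
    """Fusion configuration.

    ``beta`` is the gradient-descent filter gain; 0.1 suits 100 Hz sampling
    while ~0.025 is appropriate at 40 Hz (a 0.1 gain over-corrects there).
    ``mag_divisor`` m incorporates the magnetometer only every m-th update.
    ``init_window_s`` seconds of standing rest feed the initial orientation.
    """

    algorithm: str = "madgwick"
    beta: float = 0.1
    kp: float = 0.5
    ki: float = 0.0
    mag_divisor: int = 1
    init_window_s: float = 5.0
    use_mag: bool = True

    def __post_init__(self):
        if self.algorithm not in ("madgwick", "mahony", "gyro_only"):
            raise ValueError(f"unknown algorithm {self.algorithm!r}")
        if self.beta < 0 or self.kp < 0 or self.ki < 0:
            raise ValueError("filter gains must be non-negative")
        if self.mag_divisor < 1:
            raise ValueError("mag_divisor must be >= 1")


# -- initialization ----------------------------------------------------------


def initial_orientation(accel_mean, mag_mean) -> np.ndarray:
    """TRIAD attitude from rest-window mean accelerometer and magnetometer.

    The gravity estimate fixes earth +Z (the static specific force points up)
    and the horizontal magnetic component fixes earth +X.
    """
    a = np.asarray(accel_mean, float)
    m = np.asarray(mag_mean, float)
    na = np.linalg.norm(a)
    if na < 1e-9:
        raise DegenerateFieldError("zero accelerometer mean: cannot find vertical")
    z_s = a / na  # earth +Z expressed in the sensor frame
    m_h = m - (m @ z_s) * z_s
    nm = np.linalg.norm(m_h)
    if nm < 1e-9 * max(np.linalg.norm(m), 1.0) or nm < 1e-12:
        raise DegenerateFieldError(
            "magnetic field parallel to gravity: heading is unobservable"
        )
    x_s = m_h / nm
    y_s = np.cross(z_s, x_s)
    R = np.array([x_s, y_s, z_s])  # rows = earth axes in sensor coordinates
    return matrix_to_quat(R)


# -- shared integration primitive -------------------------------------------


def _integrate_step(q, wx, wy, wz, dt):
    """One quaternion-derivative Euler step, renormalized."""
    qw, qx, qy, qz = q
    h = 0.5 * dt
    nw = qw + h * (-qx * wx - qy * wy - qz * wz)
    nx = qx + h * (qw * wx + qy * wz - qz * wy)
    ny = qy + h * (qw * wy - qx * wz + qz * wx)
    nz = qz + h * (qw * wz + qx * wy - qy * wx)
    n = math.sqrt(nw * nw + nx * nx + ny * ny + nz * nz)
    return np.array([nw / n, nx / n, ny / n, nz / n])


def _pred_jac(q, v):
    """Predicted sensor-frame direction ``u = R(q)^T v`` of an earth-frame
    unit vector ``v``, with its 3x4 Jacobian d u / d q (analytic)."""
    w = q[0]
    r = q[1:]
    u = (w * w - r @ r) * v + 2.0 * r * (r @ v) - 2.0 * w * np.cross(r, v)
    du_dw = 2.0 * w * v - 2.0 * np.cross(r, v)
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0.0]])
    du_dr = (
        -2.0 * np.outer(v, r)
        + 2.0 * ((r @ v) * np.eye(3) + np.outer(r, v))
        + 2.0 * w * vx
    )
    return u, np.column_stack([du_dw, du_dr])


_EZ = np.array([0.0, 0.0, 1.0])

#: gradient norm below which the Madgwick correction switches from
#: unit-normalized to proportional (about a degree of attitude error)
_GRAD_FLOOR = 0.02


def madgwick_step(q, gyro, accel, mag, dt, beta, use_mag=True):
    """One update of the gradient-descent complementary filter.

    The gyro quaternion derivative is corrected by a normalized
    gradient-descent step on the gravity (and, when ``use_mag``, magnetic)
    direction objective, scaled by ``beta`` (rad/s).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    # predictor: gyro quaternion-derivative integration over dt
    q_pred = _integrate_step(q, float(gyro[0]), float(gyro[1]), float(gyro[2]), dt)
    if beta <= 0.0:
        return q_pred
    # corrector: normalized gradient-descent step on the measurement
    # objective, evaluated at the propagated state (the accel/mag sample
    # belongs to the post-step instant; evaluating the gradient before
    # propagation injects a spurious one-sample-lag error at high rates).
    # Explicit scalar gradient formulas (gravity + magnetic-field terms).
    ax, ay, az = float(accel[0]), float(accel[1]), float(accel[2])
    na = math.sqrt(ax * ax + ay * ay + az * az)
    if na < 1e-9:
        log.warning("zero accelerometer sample: skipping corrective step")
        return q_pred
    ax, ay, az = ax / na, ay / na, az / na
    w, x, y, z = q_pred
    # f_g = R(q)^T e_z - a_hat
    fgx = 2.0 * (x * z - w * y) - ax
    fgy = 2.0 * (y * z + w * x) - ay
    fgz = 1.0 - 2.0 * (x * x + y * y) - az
    gw = -2.0 * y * fgx + 2.0 * x * fgy
    gx = 2.0 * z * fgx + 2.0 * w * fgy - 4.0 * x * fgz
    gy = -2.0 * w * fgx + 2.0 * z * fgy - 4.0 * y * fgz
    gz = 2.0 * x * fgx + 2.0 * y * fgy
    if use_mag:
        mx, my, mz = float(mag[0]), float(mag[1]), float(mag[2])
        nm = math.sqrt(mx * mx + my * my + mz * mz)
        if nm > 1e-12:
            mx, my, mz = mx / nm, my / nm, mz / nm
            # earth-frame field reference from the current estimate:
            # horizontal magnitude on +X, vertical on +Z
            hx = (1.0 - 2.0 * (y * y + z * z)) * mx + 2.0 * (x * y - w * z) * my + 2.0 * (x * z + w * y) * mz
            hy = 2.0 * (x * y + w * z) * mx + (1.0 - 2.0 * (x * x + z * z)) * my + 2.0 * (y * z - w * x) * mz
            hz = 2.0 * (x * z - w * y) * mx + 2.0 * (y * z + w * x) * my + (1.0 - 2.0 * (x * x + y * y)) * mz
            bx = math.hypot(hx, hy)
            bz = hz
            # f_b = R(q)^T (bx, 0, bz) - m_hat
            fbx = bx * (1.0 - 2.0 * (y * y + z * z)) + bz * 2.0 * (x * z - w * y) - mx
            fby = bx * 2.0 * (x * y - w * z) + bz * 2.0 * (y * z + w * x) - my
            fbz = bx * 2.0 * (x * z + w * y) + bz * (1.0 - 2.0 * (x * x + y * y)) - mz
            gw += -2.0 * bz * y * fbx + (-2.0 * bx * z + 2.0 * bz * x) * fby + 2.0 * bx * y * fbz
            gx += 2.0 * bz * z * fbx + (2.0 * bx * y + 2.0 * bz * w) * fby + (2.0 * bx * z - 4.0 * bz * x) * fbz
            gy += (-4.0 * bx * y - 2.0 * bz * w) * fbx + (2.0 * bx * x + 2.0 * bz * z) * fby + (2.0 * bx * w - 4.0 * bz * y) * fbz
            gz += (-4.0 * bx * z + 2.0 * bz * x) * fbx + (-2.0 * bx * w + 2.0 * bz * y) * fby + 2.0 * bx * x * fbz
    ng = math.sqrt(gw * gw + gx * gx + gy * gy + gz * gz)
    if ng == 0.0:
        return q_pred
    # soft normalization: the classic unit-norm gradient step applies a full
    # beta*dt kick however small the residual, leaving a beta*dt-amplitude
    # limit cycle; below _GRAD_FLOOR the step becomes proportional instead,
    # vanishing smoothly at the fixed point
    s = beta * dt / max(ng, _GRAD_FLOOR)
    nw, nx, ny, nz = w - s * gw, x - s * gx, y - s * gy, z - s * gz
    n = math.sqrt(nw * nw + nx * nx + ny * ny + nz * nz)
    return np.array([nw / n, nx / n, ny / n, nz / n])


def _quat_rotate_fast(q, v):
    w = q[0]
    r = q[1:]
    return (w * w - r @ r) * v + 2.0 * r * (r @ v) + 2.0 * w * np.cross(r, v)


def mahony_step(q, gyro, accel, mag, dt, kp, ki, bias, use_mag=True):
    """One update of the proportional–integral (explicit) complementary
    filter.  Returns ``(q_next, bias_next)`` where ``bias`` is the current
    gyro-bias estimate (rad/s) maintained by the integral term."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    q = np.asarray(q, float)
    bias = np.asarray(bias, float)
    # predictor: bias-corrected gyro integration
    omega = np.asarray(gyro, float) - bias
    q_pred = _integrate_step(q, omega[0], omega[1], omega[2], dt)
    if kp <= 0.0 and ki <= 0.0:
        return q_pred, bias
    # corrector: error from cross products of measured vs predicted field
    # directions, evaluated at the propagated state (see madgwick_step)
    na = float(np.linalg.norm(accel))
    if na < 1e-9:
        log.warning("zero accelerometer sample: skipping corrective step")
        return q_pred, bias
    a_hat = np.asarray(accel, float) / na
    v_pred = _pred_jac(q_pred, _EZ)[0]
    e = np.cross(a_hat, v_pred)
    if use_mag:
        nm = float(np.linalg.norm(mag))
        if nm > 1e-12:
            m_hat = np.asarray(mag, float) / nm
            h = _quat_rotate_fast(q_pred, m_hat)
            b = np.array([math.hypot(h[0], h[1]), 0.0, h[2]])
            b /= np.linalg.norm(b)
            w_pred = _pred_jac(q_pred, b)[0]
            e = e + np.cross(m_hat, w_pred)
    if ki > 0.0:
        bias = bias - ki * e * dt
    corr = kp * e * dt
    q_next = _integrate_step(q_pred, corr[0], corr[1], corr[2], 1.0)
    return q_next, bias


def integrate_gyro(series: ImuSeries, q0) -> OrientationSeries:
    """Strap-down integration of angular velocity only (drift baseline)."""
    q = quat_normalize(q0)
    n = len(series)
    out = np.empty((n, 4))
    out[0] = q
    t = series.t
    g = series.gyro
    for k in range(1, n):
        dt = t[k] - t[k - 1]
        # trapezoidal angular rate over the step (second-order accurate)
        wx = 0.5 * (g[k - 1, 0] + g[k, 0])
        wy = 0.5 * (g[k - 1, 1] + g[k, 1])
        wz = 0.5 * (g[k - 1, 2] + g[k, 2])
        q = _integrate_step(q, wx, wy, wz, dt)
        out[k] = q
    return OrientationSeries(series.sensor_id, t.copy(), out)


def run_filter(series: ImuSeries, config: FilterConfig) -> OrientationSeries:
    """Fuse one sensor's streams into an orientation series.

    The first ``init_window_s`` seconds (a standing rest window) provide the
    mean accelerometer/magnetometer vectors for the initial orientation; the
    filter then runs over every sample, so output timestamps match input.
    """
    n = len(series)
    t = series.t
    window = t <= t[0] + config.init_window_s - 0.5 / series.rate_hz
    n_init = int(np.sum(window))
    if n_init < 1 or t[-1] - t[0] < config.init_window_s - 1.0 / series.rate_hz:
        raise ValueError(
            f"series shorter than initialization window "
            f"({t[-1] - t[0]:.2f} s < {config.init_window_s} s)"
        )
    q = initial_orientation(
        series.accel[:n_init].mean(axis=0), series.mag[:n_init].mean(axis=0)
    )
    if config.algorithm == "gyro_only":
        return integrate_gyro(series, q)
    out = np.empty((n, 4))
    out[0] = q
    bias = np.zeros(3)
    for k in range(1, n):
        dt = t[k] - t[k - 1]
        use_mag = config.use_mag and (k % config.mag_divisor == 0)
        w_mid = 0.5 * (series.gyro[k - 1] + series.gyro[k])
        if config.algorithm == "madgwick":
            q = madgwick_step(
                q, w_mid, series.accel[k], series.mag[k], dt, config.beta, use_mag
            )
        else:
            q, bias = mahony_step(
                q, w_mid, series.accel[k], series.mag[k], dt,
                config.kp, config.ki, bias, use_mag,
            )
        out[k] = q
    return OrientationSeries(series.sensor_id, t.copy(), out)


def fusion_error(
    est: OrientationSeries, ref: OrientationSeries, window_s: float = 60.0
) -> np.ndarray:
    """Per-window RMS of the axis-angle orientation difference, in degrees.

    Both series must share timestamps; trailing samples that do not fill a
    complete window are dropped.
    """
    if len(est) != len(ref) or not np.allclose(est.t, ref.t, atol=1e-9):
        raise ValueError("orientation series are not time-aligned")
    ang = np.array(
        [orientation_difference(est.q[k], ref.q[k]) for k in range(len(est))]
    )
    ang_deg = np.degrees(ang)
    if len(est) > 1:
        dt = np.median(np.diff(est.t))
    else:
        dt = 1.0
    per = max(int(round(window_s / dt)), 1)
    n_win = len(ang_deg) // per
    if n_win < 1:
        raise ValueError("series shorter than one window")
    w = ang_deg[: n_win * per].reshape(n_win, per)
    return np.sqrt(np.mean(w**2, axis=1))
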