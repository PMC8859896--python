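"""Sensor-to-segment registration from a standing calibration pose.

With the model posed at the (known or assumed) calibration pose ``q_cal``,
each sensor's fixed rotational offset is

    R_offset_i = R_segment(q_cal)^T  R_i^measured,

so that the model's virtual IMU, ``R_segment(q) R_offset_i``, reproduces the
measured orientation exactly at the calibration pose.  The measured
orientation per sensor is the sign-aligned quaternion mean over the
calibration window (the protocol's 5-s standing rest).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import yaml

from .fusion import OrientationSeries
from .model import KinematicModel, ModelConfigError, Pose
from .rotations import (
    matrix_to_quat,
    orientation_difference,
    quat_canonical,
    quat_from_axis_angle,
    quat_normalize,
    quat_to_matrix,
)

__all__ = [
    "SensorRegistration",
    "CalibrationError",
    "average_orientation",
    "calibrate",
    "heading_align",
    "save_registration",
    "load_registration",
]

log = logging.getLogger(__name__)


class CalibrationError(ValueError):
    pass


@dataclass
class SensorRegistration:
    """IMU → segment mapping with per-sensor fixed rotational offsets
    (segment frame → sensor frame, stored as scalar-first quaternions)."""

    mapping: dict
    offsets: dict
    q_cal: Pose | None = None
    window: tuple | None = None

    def __post_init__(self):
        extra = set(self.offsets) - set(self.mapping)
        missing = set(self.mapping) - set(self.offsets)
        if extra or missing:
            raise CalibrationError(
                f"offsets/mapping mismatch (extra {sorted(extra)}, missing {sorted(missing)})"
            )
        self.offsets = {
            s: quat_canonical(quat_normalize(q)) for s, q in self.offsets.items()
        }


def average_orientation(window: OrientationSeries, max_dispersion_deg: float = 10.0,
                        strict: bool = False) -> np.ndarray:
    """Sign-aligned normalized mean quaternion over a window.

    Quaternions are aligned to the first sample's hemisphere before
    averaging (the double cover makes a naive mean meaningless).  If any
    sample lies further than ``max_dispersion_deg`` from the mean the window
    is flagged as unstable (warning, or error when ``strict``).
    """
    if len(window) < 1:
        raise CalibrationError("empty calibration window")
    q0 = window.q[0]
    signs = np.where(window.q @ q0 < 0.0, -1.0, 1.0)
    mean = quat_normalize((window.q * signs[:, None]).mean(axis=0))
    worst = max(orientation_difference(mean, qk) for qk in window.q)
    if math.degrees(worst) > max_dispersion_deg:
        msg = (
            f"calibration window for {window.sensor_id!r} is unstable: "
            f"max deviation from mean {math.degrees(worst):.1f} deg"
        )
        if strict:
            raise CalibrationError(msg)
        log.warning(msg)
    return quat_canonical(mean)


def calibrate(
    model: KinematicModel,
    q_cal: Pose | None,
    measured: Mapping[str, np.ndarray],
    mapping: Mapping[str, str] | None = None,
) -> SensorRegistration:
    """Compute fixed rotational offsets from measured orientations at the
    calibration pose.

    ``measured`` maps sensor id → sensor-to-earth quaternion (typically the
    window mean from :func:`average_orientation`).  ``q_cal`` defaults to the
    all-zero neutral standing pose.  ``mapping`` defaults to the model's IMU
    sites.
    """
    if q_cal is None:
        q_cal = model.zero_pose()
    if mapping is None:
        mapping = {s: model.site_segment(s) for s in measured}
    missing = sorted(set(mapping) - set(measured))
    if missing:
        raise CalibrationError(f"sensors missing from measured orientations: {missing}")
    orientations, _ = model.forward_kinematics(q_cal)
    offsets = {}
    for sensor_id, segment in mapping.items():
        if segment not in model.segments:
            raise ModelConfigError(
                f"sensor {sensor_id!r} mapped to unknown segment {segment!r}"
            )
        R_seg = orientations[segment]
        R_meas = quat_to_matrix(measured[sensor_id])
        offsets[sensor_id] = matrix_to_quat(R_seg.T @ R_meas)
    return SensorRegistration(dict(mapping), offsets, q_cal=q_cal)


def heading_align(
    model: KinematicModel,
    registration: SensorRegistration,
    measured: Mapping[str, np.ndarray],
    reference_sensor: str,
) -> SensorRegistration:
    """Rotate each sensor's offset about earth Z so all sensors agree with
    the reference sensor's heading at the calibration pose.

    Optional mitigation for per-sensor magnetometer heading disagreement:
    only the vertical-axis (heading) component of each sensor's
    virtual-vs-measured discrepancy is corrected; inclination is untouched.
    """
    if reference_sensor not in registration.mapping:
        raise CalibrationError(f"reference sensor {reference_sensor!r} not registered")
    q_cal = registration.q_cal if registration.q_cal is not None else model.zero_pose()
    orientations, _ = model.forward_kinematics(q_cal)

    def heading_error(sensor_id):
        R_seg = orientations[registration.mapping[sensor_id]]
        R_vir = R_seg @ quat_to_matrix(registration.offsets[sensor_id])
        R_meas = quat_to_matrix(measured[sensor_id])
        A = R_meas @ R_vir.T  # earth-frame discrepancy
        return math.atan2(A[1, 0] - A[0, 1], A[0, 0] + A[1, 1])

    phi_ref = heading_error(reference_sensor)
    new_offsets = {}
    for sensor_id in registration.mapping:
        phi = heading_error(sensor_id) - phi_ref
        R_seg = orientations[registration.mapping[sensor_id]]
        Rz = quat_to_matrix(quat_from_axis_angle([0, 0, 1], phi))
        R_off = R_seg.T @ Rz @ R_seg @ quat_to_matrix(registration.offsets[sensor_id])
        new_offsets[sensor_id] = matrix_to_quat(R_off)
    return SensorRegistration(
        dict(registration.mapping), new_offsets, q_cal=q_cal, window=registration.window
    )


def save_registration(registration: SensorRegistration, path):
    doc = {
        "mapping": dict(registration.mapping),
        "offsets_quat_wxyz": {
            s: [float(v) for v in q] for s, q in registration.offsets.items()
        },
    }
    if registration.q_cal is not None:
        # raw coordinate units (radians / meters) for a lossless round trip
        doc["q_cal"] = registration.q_cal.as_dict()
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_registration(path, model: KinematicModel | None = None) -> SensorRegistration:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    try:
        mapping = doc["mapping"]
        offsets = {s: np.asarray(q, float) for s, q in doc["offsets_quat_wxyz"].items()}
    except (KeyError, TypeError) as e:
        raise CalibrationError(f"{path}: malformed registration file ({e})") from None
    q_cal = None
    if model is not None and "q_cal" in doc:
        q_cal = model.make_pose(doc["q_cal"])
    return SensorRegistration(mapping, offsets, q_cal=q_cal)
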