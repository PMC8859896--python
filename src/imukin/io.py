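"""Readers and writers for the pipeline's file formats.

* Raw IMU CSV, one file per sensor, SI units, named header:
  ``time,gyro_x,gyro_y,gyro_z,acc_x,acc_y,acc_z,mag_x,mag_y,mag_z``.
* Orientation / joint-angle tables in an STO dialect (tab-separated with a
  ``name / nRows= / nColumns= / endheader`` header block) plus CSV mirrors.
  Orientation columns are ``<sensor>_q_w .. _q_z`` (scalar-first, unit
  quaternions); angle columns are coordinate names in degrees
  (pelvis translations in meters).

All round trips are lossless to 9 significant digits.
"""

from __future__ import annotations

import math
from typing import Mapping

import numpy as np
import pandas as pd

from .fusion import ImuSeries, OrientationSeries
from .rotations import quat_canonical, quat_normalize

__all__ = [
    "FileFormatError",
    "read_imu_csv",
    "write_imu_csv",
    "write_orientations_sto",
    "read_orientations_sto",
    "write_orientations_csv",
    "read_orientations_csv",
    "write_angles_sto",
    "read_angles_sto",
    "write_angles_csv",
    "read_angles_csv",
    "resample_orientations",
]

IMU_COLUMNS = [
    "time",
    "gyro_x",
    "gyro_y",
    "gyro_z",
    "acc_x",
    "acc_y",
    "acc_z",
    "mag_x",
    "mag_y",
    "mag_z",
]

_FLOAT_FMT = "%.9g"


class FileFormatError(ValueError):
    pass


def _check_time(t, path):
    if len(t) > 1 and np.any(np.diff(t) <= 0):
        k = int(np.argmax(np.diff(t) <= 0))
        raise FileFormatError(
            f"{path}: time not strictly increasing at data line {k + 2}"
        )


def read_imu_csv(path, sensor_id: str | None = None) -> ImuSeries:
    try:
        df = pd.read_csv(path)
    except Exception as e:
        raise FileFormatError(f"{path}: cannot parse CSV ({e})") from None
    missing = [c for c in IMU_COLUMNS if c not in df.columns]
    if missing:
        raise FileFormatError(f"{path}: missing required columns {missing}")
    if df[IMU_COLUMNS].isna().any().any():
        k = int(df[IMU_COLUMNS].isna().any(axis=1).idxmax())
        raise FileFormatError(f"{path}: ragged/non-numeric row at data line {k + 2}")
    t = df["time"].to_numpy(float)
    _check_time(t, path)
    rate = 1.0 / float(np.median(np.diff(t))) if len(t) > 1 else 0.0
    if sensor_id is None:
        import os

        sensor_id = os.path.splitext(os.path.basename(str(path)))[0]
    return ImuSeries(
        sensor_id,
        t,
        df[["gyro_x", "gyro_y", "gyro_z"]].to_numpy(float),
        df[["acc_x", "acc_y", "acc_z"]].to_numpy(float),
        df[["mag_x", "mag_y", "mag_z"]].to_numpy(float),
        rate,
    )


def write_imu_csv(series: ImuSeries, path):
    df = pd.DataFrame(
        np.column_stack([series.t, series.gyro, series.accel, series.mag]),
        columns=IMU_COLUMNS,
    )
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


# -- STO dialect -------------------------------------------------------------


def _write_sto(path, name: str, columns, data: np.ndarray):
    n_rows, n_cols = data.shape
    assert n_cols == len(columns)
    with open(path, "w") as fh:
        fh.write(f"{name}\n")
        fh.write(f"nRows={n_rows}\n")
        fh.write(f"nColumns={n_cols}\n")
        fh.write("endheader\n")
        fh.write("\t".join(columns) + "\n")
        for row in data:
            fh.write("\t".join(_FLOAT_FMT % v for v in row) + "\n")


def _read_sto(path):
    with open(path) as fh:
        lines = fh.read().splitlines()
    header = {}
    body_start = None
    for i, line in enumerate(lines):
        if line.strip() == "endheader":
            body_start = i + 1
            break
        if "=" in line:
            k, _, v = line.partition("=")
            header[k.strip()] = v.strip()
    if body_start is None:
        raise FileFormatError(f"{path}: no 'endheader' line found")
    try:
        n_rows = int(header["nRows"])
        n_cols = int(header["nColumns"])
    except (KeyError, ValueError):
        raise FileFormatError(f"{path}: header must define integer nRows and nColumns") from None
    columns = lines[body_start].split("\t")
    if len(columns) != n_cols:
        raise FileFormatError(
            f"{path}: header declares nColumns={n_cols} but found {len(columns)} column labels"
        )
    body = lines[body_start + 1 :]
    body = [l for l in body if l.strip()]
    if len(body) != n_rows:
        raise FileFormatError(
            f"{path}: header declares nRows={n_rows} but body has {len(body)} rows"
        )
    data = np.empty((n_rows, n_cols))
    for r, line in enumerate(body):
        parts = line.split("\t")
        if len(parts) != n_cols:
            raise FileFormatError(
                f"{path}: ragged row at line {body_start + 2 + r} "
                f"({len(parts)} fields, expected {n_cols})"
            )
        try:
            data[r] = [float(p) for p in parts]
        except ValueError:
            raise FileFormatError(
                f"{path}: non-numeric value at line {body_start + 2 + r}"
            ) from None
    return columns, data


def write_orientations_sto(orientations: Mapping[str, OrientationSeries], path, name="orientations"):
    sensors = list(orientations)
    ref = orientations[sensors[0]]
    cols = ["time"]
    for s in sensors:
        ser = orientations[s]
        if len(ser) != len(ref) or not np.allclose(ser.t, ref.t, atol=1e-9):
            raise FileFormatError(f"orientation series {s!r} is not time-aligned")
        cols += [f"{s}_q_w", f"{s}_q_x", f"{s}_q_y", f"{s}_q_z"]
    data = np.column_stack([ref.t] + [orientations[s].q for s in sensors])
    _write_sto(path, name, cols, data)


def _orientations_from_table(columns, data, path):
    if columns[0] != "time":
        raise FileFormatError(f"{path}: first column must be 'time', got {columns[0]!r}")
    t = data[:, 0]
    _check_time(t, path)
    sensors = []
    for c in columns[1:]:
        if c.endswith("_q_w"):
            sensors.append(c[: -len("_q_w")])
    out = {}
    for s in sensors:
        try:
            idx = [columns.index(f"{s}_q_{a}") for a in "wxyz"]
        except ValueError as e:
            raise FileFormatError(f"{path}: incomplete quaternion columns for {s!r}") from None
        q = data[:, idx]
        norms = np.linalg.norm(q, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-6):
            k = int(np.argmax(np.abs(norms - 1.0) > 1e-6))
            raise FileFormatError(
                f"{path}: non-unit quaternion for {s!r} at data row {k + 1}"
            )
        out[s] = OrientationSeries(s, t.copy(), q / norms[:, None])
    if not out:
        raise FileFormatError(f"{path}: no quaternion columns found")
    return out


def read_orientations_sto(path) -> dict:
    columns, data = _read_sto(path)
    return _orientations_from_table(columns, data, path)


def write_orientations_csv(orientations: Mapping[str, OrientationSeries], path):
    sensors = list(orientations)
    ref = orientations[sensors[0]]
    cols = ["time"] + [f"{s}_q_{a}" for s in sensors for a in "wxyz"]
    data = np.column_stack([ref.t] + [orientations[s].q for s in sensors])
    pd.DataFrame(data, columns=cols).to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_orientations_csv(path) -> dict:
    df = pd.read_csv(path)
    return _orientations_from_table(list(df.columns), df.to_numpy(float), path)


def write_angles_sto(t, angles_deg: Mapping[str, np.ndarray], path, name="joint_angles"):
    cols = ["time"] + list(angles_deg)
    data = np.column_stack([np.asarray(t, float)] + [np.asarray(v, float) for v in angles_deg.values()])
    _write_sto(path, name, cols, data)


def read_angles_sto(path):
    columns, data = _read_sto(path)
    if columns[0] != "time":
        raise FileFormatError(f"{path}: first column must be 'time'")
    t = data[:, 0]
    _check_time(t, path)
    return t, {c: data[:, i] for i, c in enumerate(columns) if i > 0}


def write_angles_csv(t, angles_deg: Mapping[str, np.ndarray], path):
    data = np.column_stack([np.asarray(t, float)] + [np.asarray(v, float) for v in angles_deg.values()])
    pd.DataFrame(data, columns=["time"] + list(angles_deg)).to_csv(
        path, index=False, float_format=_FLOAT_FMT
    )


def read_angles_csv(path):
    df = pd.read_csv(path)
    if df.columns[0] != "time":
        raise FileFormatError(f"{path}: first column must be 'time'")
    t = df["time"].to_numpy(float)
    _check_time(t, path)
    return t, {c: df[c].to_numpy(float) for c in df.columns[1:]}


# -- resampling --------------------------------------------------------------


def _slerp(qa, qb, alpha: float):
    qa = quat_normalize(qa)
    qb = quat_normalize(qb)
    if qa @ qb < 0.0:
        qb = -qb
    dot = min(max(float(qa @ qb), -1.0), 1.0)
    ang = math.acos(dot)
    if ang < 1e-9:
        return quat_normalize(qa + alpha * (qb - qa))
    sa = math.sin((1.0 - alpha) * ang) / math.sin(ang)
    sb = math.sin(alpha * ang) / math.sin(ang)
    return quat_normalize(sa * qa + sb * qb)


def resample_orientations(series: OrientationSeries, t_new) -> OrientationSeries:
    """Spherical linear interpolation between bracketing samples onto new
    timestamps (must lie within the series' span)."""
    t_new = np.asarray(t_new, float)
    t = series.t
    if t_new[0] < t[0] - 1e-9 or t_new[-1] > t[-1] + 1e-9:
        raise ValueError("requested timestamps outside the series span")
    idx = np.clip(np.searchsorted(t, t_new, side="right") - 1, 0, len(t) - 2)
    out = np.empty((len(t_new), 4))
    for k, (i, tk) in enumerate(zip(idx, t_new)):
        alpha = (tk - t[i]) / (t[i + 1] - t[i])
        out[k] = quat_canonical(_slerp(series.q[i], series.q[i + 1], float(np.clip(alpha, 0.0, 1.0))))
    return OrientationSeries(series.sensor_id, t_new.copy(), out)
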