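"""Kinematic-chain skeletal model: segments, joints, poses, forward kinematics.

The default model is a torso + pelvis + bilateral lower-extremity chain with
19 coordinates:

* pelvis: free joint to ground — 3 rotations (tilt, list, rotation) and
  3 translations (frozen during orientation-only inverse kinematics),
* lumbar: ball joint carrying the torso (extension, bending, rotation),
* per side: ball hip (flexion, adduction, rotation), pin knee
  (flexion), pin ankle (plantarflexion–dorsiflexion).

Ground frame: right-handed, Z up, X forward (set by the horizontal magnetic
field at fusion initialization), Y to the subject's left.  Ball-joint Euler
sequences are intrinsic flexion→adduction→rotation about the (Y, X, Z)
segment axes — the mediolateral / anteroposterior / vertical axes in this
frame — mirroring standard gait-analysis angle definitions.

Coordinates are radians (meters for pelvis translations) internally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import yaml

from .rotations import (
    quat_canonical,
    quat_normalize,
    quat_rotate,
    quat_to_matrix,
)

__all__ = [
    "ModelConfigError",
    "Joint",
    "Segment",
    "ImuSite",
    "Pose",
    "KinematicModel",
    "build_default_model",
    "load_model",
    "save_model",
    "SENSOR_IDS",
]

JOINT_KINDS = ("free6", "ball3", "pin1", "weld0")

#: The eight sensor sites of the study protocol: upper back (T2), lower back
#: (L5), and bilateral thigh / shank / foot.
SENSOR_IDS = (
    "torso_imu",
    "pelvis_imu",
    "femur_r_imu",
    "femur_l_imu",
    "tibia_r_imu",
    "tibia_l_imu",
    "calcn_r_imu",
    "calcn_l_imu",
)


class ModelConfigError(ValueError):
    """Raised for malformed or inconsistent model configurations."""


@dataclass(frozen=True)
class Joint:
    """A joint connecting ``parent`` to ``child``.

    ``axes`` lists the rotational coordinates in intrinsic application order
    as ``(coordinate_name, unit_axis_in_parent_frame)``.  ``translations``
    lists translational coordinate names (free6 only, ground-frame x/y/z).
    """

    name: str
    kind: str
    parent: str
    child: str
    axes: tuple = ()
    translations: tuple = ()

    def __post_init__(self):
        if self.kind not in JOINT_KINDS:
            raise ModelConfigError(
                f"joint {self.name!r}: unknown kind {self.kind!r}; "
                f"expected one of {JOINT_KINDS}"
            )
        n_rot = {"free6": 3, "ball3": 3, "pin1": 1, "weld0": 0}[self.kind]
        n_tr = 3 if self.kind == "free6" else 0
        if len(self.axes) != n_rot:
            raise ModelConfigError(
                f"joint {self.name!r}: kind {self.kind} needs {n_rot} "
                f"rotational axes, got {len(self.axes)}"
            )
        if len(self.translations) != n_tr:
            raise ModelConfigError(
                f"joint {self.name!r}: kind {self.kind} needs {n_tr} "
                f"translations, got {len(self.translations)}"
            )


@dataclass
class Segment:
    """A rigid body.  ``origin_in_parent`` locates its joint center in the
    parent segment frame; ``offset_rot`` is a fixed child-frame rotation
    applied after the joint rotation.  ``length`` is only used when the
    synthetic generator needs positions."""

    name: str
    origin_in_parent: np.ndarray = field(default_factory=lambda: np.zeros(3))
    offset_rot: np.ndarray = field(default_factory=lambda: np.array([1.0, 0, 0, 0]))
    length: float = 0.0


@dataclass
class ImuSite:
    """Nominal placement of a (virtual) IMU on a segment."""

    segment: str
    position: np.ndarray = field(default_factory=lambda: np.zeros(3))


@dataclass
class Pose:
    """A joint-coordinate vector keyed by the model's coordinate names."""

    coords: tuple
    q: np.ndarray

    def __post_init__(self):
        self.q = np.asarray(self.q, dtype=float)
        if self.q.shape != (len(self.coords),):
            raise ValueError(
                f"pose has {self.q.shape} values for {len(self.coords)} coordinates"
            )

    def __getitem__(self, name: str) -> float:
        return float(self.q[self.coords.index(name)])

    def as_dict(self) -> dict:
        return {c: float(v) for c, v in zip(self.coords, self.q)}

    def copy(self) -> "Pose":
        return Pose(self.coords, self.q.copy())


class KinematicModel:
    """Segment tree + joints + coordinate layout + virtual IMU sites."""

    def __init__(
        self,
        segments: Mapping[str, Segment],
        joints: Iterable[Joint],
        imu_sites: Mapping[str, ImuSite],
        bounds_deg: Mapping[str, tuple] | None = None,
        name: str = "model",
    ):
        self.name = name
        self.segments = dict(segments)
        self.joints = list(joints)
        self.imu_sites = dict(imu_sites)
        self._validate_tree()
        self.coordinates: tuple = tuple(
            c for j in self.joints for c in ([a[0] for a in j.axes] + list(j.translations))
        )
        if len(set(self.coordinates)) != len(self.coordinates):
            raise ModelConfigError("duplicate coordinate names in joint definitions")
        self.bounds: dict = {}
        bounds_deg = dict(bounds_deg or {})
        for c in self.coordinates:
            if c in bounds_deg:
                lo, hi = bounds_deg.pop(c)
                self.bounds[c] = (math.radians(lo), math.radians(hi))
            elif self._is_translation(c):
                self.bounds[c] = (-5.0, 5.0)
            else:
                self.bounds[c] = (-2.0 * math.pi, 2.0 * math.pi)
        if bounds_deg:
            raise ModelConfigError(
                f"bounds given for unknown coordinates: {sorted(bounds_deg)}"
            )
        for site_name, site in self.imu_sites.items():
            if site.segment not in self.segments:
                raise ModelConfigError(
                    f"imu site {site_name!r} references unknown segment {site.segment!r}"
                )
        self._compile()

    # -- structure ---------------------------------------------------------

    def _is_translation(self, coord: str) -> bool:
        return any(coord in j.translations for j in self.joints)

    def _validate_tree(self):
        children = [j.child for j in self.joints]
        if len(set(children)) != len(children):
            raise ModelConfigError("a segment is the child of more than one joint")
        for j in self.joints:
            if j.child not in self.segments:
                raise ModelConfigError(f"joint {j.name!r}: unknown child {j.child!r}")
            if j.parent != "ground" and j.parent not in self.segments:
                raise ModelConfigError(f"joint {j.name!r}: unknown parent {j.parent!r}")
        roots = [j.child for j in self.joints if j.parent == "ground"]
        if len(roots) != 1:
            raise ModelConfigError(f"model must have exactly one root segment, got {roots}")
        self.root = roots[0]
        # detect cycles / unreached segments by walking from ground
        reached = {"ground"}
        pending = list(self.joints)
        progress = True
        while pending and progress:
            progress = False
            for j in list(pending):
                if j.parent in reached:
                    if j.child in reached:
                        raise ModelConfigError(f"cycle at segment {j.child!r}")
                    reached.add(j.child)
                    pending.remove(j)
                    progress = True
        if pending:
            raise ModelConfigError(
                f"segments not reachable from ground (cycle?): {[j.child for j in pending]}"
            )
        unreached = set(self.segments) - reached
        if unreached:
            raise ModelConfigError(f"segments without a joint: {sorted(unreached)}")

    def _compile(self):
        """Flatten the tree into index-based tables for the fast FK path."""
        self._seg_index = {s: i for i, s in enumerate(self.segments)}
        coord_index = {c: i for i, c in enumerate(self.coordinates)}
        self.coord_index = coord_index
        # topological joint order (parents first)
        order, placed = [], {"ground"}
        remaining = list(self.joints)
        while remaining:
            for j in list(remaining):
                if j.parent in placed:
                    order.append(j)
                    placed.add(j.child)
                    remaining.remove(j)
        self._joint_order = order
        self._fk_table = []
        for j in order:
            parent_i = -1 if j.parent == "ground" else self._seg_index[j.parent]
            child = self.segments[j.child]
            axes = tuple(
                (coord_index[c], tuple(np.asarray(ax, float) / np.linalg.norm(ax)))
                for c, ax in j.axes
            )
            trans = tuple(coord_index[c] for c in j.translations)
            self._fk_table.append(
                (
                    parent_i,
                    self._seg_index[j.child],
                    axes,
                    trans,
                    tuple(quat_canonical(quat_normalize(child.offset_rot))),
                    tuple(np.asarray(child.origin_in_parent, float)),
                )
            )

    # -- poses -------------------------------------------------------------

    def zero_pose(self) -> Pose:
        return Pose(self.coordinates, np.zeros(len(self.coordinates)))

    def make_pose(self, values: Mapping[str, float]) -> Pose:
        q = np.zeros(len(self.coordinates))
        for name, v in values.items():
            if name not in self.coord_index:
                raise ModelConfigError(f"unknown coordinate {name!r}")
            q[self.coord_index[name]] = v
        return Pose(self.coordinates, q)

    def clamp(self, q: np.ndarray) -> np.ndarray:
        lo = np.array([self.bounds[c][0] for c in self.coordinates])
        hi = np.array([self.bounds[c][1] for c in self.coordinates])
        return np.clip(q, lo, hi)

    # -- forward kinematics -------------------------------------------------

    def segment_quats(self, qvec: np.ndarray) -> list:
        """Ground-frame orientation quaternion of every segment (fast path).

        Returns a list of 4-tuples indexed like ``self._seg_index``.
        Child orientation = parent ∘ joint rotation ∘ fixed child offset,
        with intrinsic axis rotations applied in the declared order.
        """
        out = [None] * len(self.segments)
        for parent_i, child_i, axes, _trans, offset, _origin in self._fk_table:
            if parent_i < 0:
                pw, px, py, pz = 1.0, 0.0, 0.0, 0.0
            else:
                pw, px, py, pz = out[parent_i]
            for ci, (ux, uy, uz) in axes:
                half = 0.5 * qvec[ci]
                c, s = math.cos(half), math.sin(half)
                bw, bx, by, bz = c, s * ux, s * uy, s * uz
                pw, px, py, pz = (
                    pw * bw - px * bx - py * by - pz * bz,
                    pw * bx + px * bw + py * bz - pz * by,
                    pw * by - px * bz + py * bw + pz * bx,
                    pw * bz + px * by - py * bx + pz * bw,
                )
            bw, bx, by, bz = offset
            if bx != 0.0 or by != 0.0 or bz != 0.0 or bw != 1.0:
                pw, px, py, pz = (
                    pw * bw - px * bx - py * by - pz * bz,
                    pw * bx + px * bw + py * bz - pz * by,
                    pw * by - px * bz + py * bw + pz * bx,
                    pw * bz + px * by - py * bx + pz * bw,
                )
            out[child_i] = (pw, px, py, pz)
        return out

    def forward_kinematics(self, pose: Pose):
        """Ground-frame orientation matrix and position of every segment.

        Positions use the nominal segment geometry and are consumed only by
        the synthetic generator; orientation-only IK never reads them.
        """
        if tuple(pose.coords) != self.coordinates:
            raise ModelConfigError("pose coordinates do not match model")
        qvec = pose.q
        lo = np.array([self.bounds[c][0] for c in self.coordinates])
        hi = np.array([self.bounds[c][1] for c in self.coordinates])
        if np.any(qvec < lo - 1e-12) or np.any(qvec > hi + 1e-12):
            import warnings

            warnings.warn("pose outside coordinate bounds", stacklevel=2)
        quats = self.segment_quats(qvec)
        orientations, positions = {}, {}
        pos = [None] * len(self.segments)
        for parent_i, child_i, _axes, trans, _offset, origin in self._fk_table:
            if parent_i < 0:
                p = np.zeros(3)
                parent_q = (1.0, 0.0, 0.0, 0.0)
            else:
                p = pos[parent_i]
                parent_q = quats[parent_i]
            p = p + quat_rotate(np.array(parent_q), np.array(origin))
            if trans:
                p = p + qvec[list(trans)]
            pos[child_i] = p
        for name, i in self._seg_index.items():
            orientations[name] = quat_to_matrix(np.array(quats[i]))
            positions[name] = pos[i]
        return orientations, positions

    def site_segment(self, sensor_id: str) -> str:
        try:
            return self.imu_sites[sensor_id].segment
        except KeyError:
            raise ModelConfigError(f"unknown IMU site {sensor_id!r}") from None


def virtual_imu_orientations(model: KinematicModel, pose: Pose, registration):
    """Ground-frame orientation of each registered virtual IMU,
    ``R_vir_i = R_segment(q) @ R_offset_i``."""
    orientations, _ = model.forward_kinematics(pose)
    out = {}
    for sensor_id, segment in registration.mapping.items():
        if segment not in model.segments:
            raise ModelConfigError(
                f"sensor {sensor_id!r} mapped to unknown segment {segment!r}"
            )
        out[sensor_id] = orientations[segment] @ quat_to_matrix(
            registration.offsets[sensor_id]
        )
    return out


def build_default_model() -> KinematicModel:
    """The default torso + lower-body chain with 19 coordinates and the
    study's 8 IMU sites."""
    ax_flex = (0.0, 1.0, 0.0)  # mediolateral
    ax_add = (1.0, 0.0, 0.0)  # anteroposterior
    ax_rot = (0.0, 0.0, 1.0)  # vertical
    segments = {
        "pelvis": Segment("pelvis", np.zeros(3), length=0.18),
        "torso": Segment("torso", np.array([0.0, 0.0, 0.12]), length=0.45),
        "femur_r": Segment("femur_r", np.array([0.0, -0.09, 0.0]), length=0.40),
        "femur_l": Segment("femur_l", np.array([0.0, 0.09, 0.0]), length=0.40),
        "tibia_r": Segment("tibia_r", np.array([0.0, 0.0, -0.40]), length=0.40),
        "tibia_l": Segment("tibia_l", np.array([0.0, 0.0, -0.40]), length=0.40),
        "calcn_r": Segment("calcn_r", np.array([0.0, 0.0, -0.40]), length=0.20),
        "calcn_l": Segment("calcn_l", np.array([0.0, 0.0, -0.40]), length=0.20),
    }
    joints = [
        Joint(
            "ground_pelvis",
            "free6",
            "ground",
            "pelvis",
            axes=(("pelvis_tilt", ax_flex), ("pelvis_list", ax_add), ("pelvis_rotation", ax_rot)),
            translations=("pelvis_tx", "pelvis_ty", "pelvis_tz"),
        ),
        Joint(
            "back",
            "ball3",
            "pelvis",
            "torso",
            axes=(
                ("lumbar_extension", ax_flex),
                ("lumbar_bending", ax_add),
                ("lumbar_rotation", ax_rot),
            ),
        ),
    ]
    for side in ("r", "l"):
        joints += [
            Joint(
                f"hip_{side}",
                "ball3",
                "pelvis",
                f"femur_{side}",
                axes=(
                    (f"hip_flexion_{side}", ax_flex),
                    (f"hip_adduction_{side}", ax_add),
                    (f"hip_rotation_{side}", ax_rot),
                ),
            ),
            Joint(f"knee_{side}", "pin1", f"femur_{side}", f"tibia_{side}", axes=((f"knee_flexion_{side}", ax_flex),)),
            Joint(f"ankle_{side}", "pin1", f"tibia_{side}", f"calcn_{side}", axes=((f"ankle_flexion_{side}", ax_flex),)),
        ]
    imu_sites = {
        "torso_imu": ImuSite("torso", np.array([0.0, 0.0, 0.30])),  # T2
        "pelvis_imu": ImuSite("pelvis", np.array([-0.08, 0.0, 0.05])),  # L5
        "femur_r_imu": ImuSite("femur_r", np.array([0.05, 0.0, -0.20])),
        "femur_l_imu": ImuSite("femur_l", np.array([0.05, 0.0, -0.20])),
        "tibia_r_imu": ImuSite("tibia_r", np.array([0.03, 0.0, -0.20])),
        "tibia_l_imu": ImuSite("tibia_l", np.array([0.03, 0.0, -0.20])),
        "calcn_r_imu": ImuSite("calcn_r", np.array([0.08, 0.0, 0.03])),
        "calcn_l_imu": ImuSite("calcn_l", np.array([0.08, 0.0, 0.03])),
    }
    bounds_deg = {
        "pelvis_tilt": (-90, 90),
        "pelvis_list": (-90, 90),
        "pelvis_rotation": (-100000, 100000),  # heading accumulates across turns
        "lumbar_extension": (-90, 90),
        "lumbar_bending": (-90, 90),
        "lumbar_rotation": (-90, 90),
    }
    for side in ("r", "l"):
        bounds_deg.update(
            {
                f"hip_flexion_{side}": (-120, 120),
                f"hip_adduction_{side}": (-60, 60),
                f"hip_rotation_{side}": (-60, 60),
                f"knee_flexion_{side}": (0, 140),
                f"ankle_flexion_{side}": (-60, 60),
            }
        )
    return KinematicModel(segments, joints, imu_sites, bounds_deg, name="lower_body_torso")


# -- model config I/O --------------------------------------------------------


def save_model(model: KinematicModel, path):
    doc = {
        "name": model.name,
        "segments": {
            s.name: {
                "origin_in_parent": [float(v) for v in s.origin_in_parent],
                "offset_rot_quat": [float(v) for v in s.offset_rot],
                "length": float(s.length),
            }
            for s in model.segments.values()
        },
        "joints": [
            {
                "name": j.name,
                "kind": j.kind,
                "parent": j.parent,
                "child": j.child,
                "axes": [{"coordinate": c, "axis": [float(v) for v in ax]} for c, ax in j.axes],
                "translations": list(j.translations),
            }
            for j in model.joints
        ],
        "imu_sites": {
            name: {"segment": s.segment, "position": [float(v) for v in s.position]}
            for name, s in model.imu_sites.items()
        },
        "bounds_deg": {
            c: [math.degrees(lo), math.degrees(hi)]
            for c, (lo, hi) in model.bounds.items()
            if not model._is_translation(c)
        },
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_model(path) -> KinematicModel:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ModelConfigError(f"{path}: model config must be a mapping")
    for key in ("segments", "joints"):
        if key not in doc:
            raise ModelConfigError(f"{path}: missing required section {key!r}")
    try:
        segments = {
            name: Segment(
                name,
                np.asarray(s.get("origin_in_parent", [0, 0, 0]), float),
                np.asarray(s.get("offset_rot_quat", [1, 0, 0, 0]), float),
                float(s.get("length", 0.0)),
            )
            for name, s in doc["segments"].items()
        }
        joints = [
            Joint(
                j["name"],
                j["kind"],
                j["parent"],
                j["child"],
                axes=tuple((a["coordinate"], tuple(a["axis"])) for a in j.get("axes", [])),
                translations=tuple(j.get("translations", [])),
            )
            for j in doc["joints"]
        ]
        imu_sites = {
            name: ImuSite(s["segment"], np.asarray(s.get("position", [0, 0, 0]), float))
            for name, s in doc.get("imu_sites", {}).items()
        }
    except KeyError as e:
        raise ModelConfigError(f"{path}: missing field {e.args[0]!r}") from None
    return KinematicModel(
        segments,
        joints,
        imu_sites,
        {c: tuple(b) for c, b in doc.get("bounds_deg", {}).items()},
        name=doc.get("name", "model"),
    )
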