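"""Inverse kinematics: exact recovery, closed-form pin joint, weighting
properties, cost function contracts."""

import math

import numpy as np
import pytest

from imukin import rotations as rot
from imukin.calibration import SensorRegistration, calibrate
from imukin.fusion import OrientationSeries
from imukin.ik import DEFAULT_WEIGHTS, cost, ik_frame, ik_trajectory
from imukin.model import ImuSite, Joint, KinematicModel, Segment


def measured_at(model, qvec, offsets):
    quats = model.segment_quats(np.asarray(qvec, float))
    return {
        s: rot.quat_canonical(
            rot.quat_multiply(np.array(quats[model._seg_index[model.site_segment(s)]]), off)
        )
        for s, off in offsets.items()
    }


@pytest.fixture
def registration(model, rng):
    offsets = {
        s: rot.quat_from_axis_angle(rng.normal(size=3), rng.uniform(0.1, 0.4))
        for s in model.imu_sites
    }
    measured = measured_at(model, np.zeros(19), offsets)
    return calibrate(model, None, measured)


def random_inbounds_pose(model, rng, scale_deg=30.0):
    q = np.zeros(len(model.coordinates))
    for i, c in enumerate(model.coordinates):
        if model._is_translation(c):
            continue
        lo, hi = model.bounds[c]
        q[i] = rng.uniform(
            max(lo, -math.radians(scale_deg)), min(hi, math.radians(scale_deg))
        )
    return q


class TestIkFrame:
    def test_global_minimum_at_start(self, model, registration, rng):
        qt = random_inbounds_pose(model, rng)
        measured = measured_at(model, qt, registration.offsets)
        pose, theta, c = ik_frame(
            model, registration, measured, q_init=model.make_pose(dict(zip(model.coordinates, qt)))
        )
        assert c < 1e-12
        assert np.degrees(np.abs(pose.q - qt)).max() < 1e-6

    def test_recovery_from_zero_pose_start(self, model, registration, rng):
        for _ in range(3):
            qt = random_inbounds_pose(model, rng)
            measured = measured_at(model, qt, registration.offsets)
            pose, theta, c = ik_frame(model, registration, measured)
            assert c < 1e-8
            assert np.degrees(np.abs(pose.q - qt)).max() < 0.1

    def test_calibration_frame_returns_calibration_pose(self, model, registration):
        measured = measured_at(model, np.zeros(19), registration.offsets)
        pose, _, c = ik_frame(model, registration, measured)
        assert c < 1e-12
        assert np.degrees(np.abs(pose.q)).max() < 1e-4

    def test_pin_joint_closed_form(self):
        """Single pin joint, one sensor: the 1-D solution equals the planted
        rotation angle about the joint axis exactly."""
        segs = {"base": Segment("base"), "arm": Segment("arm")}
        joints = [
            Joint("ground_base", "weld0", "ground", "base"),
            Joint("elbow", "pin1", "base", "arm", axes=(("elbow_flexion", (0, 1, 0)),)),
        ]
        m = KinematicModel(
            segs, joints, {"arm_imu": ImuSite("arm")}, {"elbow_flexion": (-150, 150)}
        )
        reg = SensorRegistration({"arm_imu": "arm"}, {"arm_imu": np.array([1.0, 0, 0, 0])})
        for phi_deg in (-77.3, -10.0, 0.0, 12.5, 149.0):
            q_meas = rot.quat_from_axis_angle([0, 1, 0], math.radians(phi_deg))
            pose, theta, c = ik_frame(m, reg, {"arm_imu": q_meas}, weights={"arm_imu": 1.0})
            assert pose["elbow_flexion"] == pytest.approx(math.radians(phi_deg), abs=1e-8)
            assert c < 1e-14

    def test_no_usable_sensor_raises(self, model, registration):
        with pytest.raises(ValueError):
            ik_frame(model, registration, {}, weights={"torso_imu": 1.0})


class TestIkTrajectory:
    def test_noiseless_walk_recovers_truth(self, model, registration, rng):
        # 4 s of smoothly varying poses sampled at 20 Hz, truth-measured
        n = 80
        t = np.arange(n) / 20.0
        Q = np.zeros((n, 19))
        for i, c in enumerate(model.coordinates):
            if model._is_translation(c):
                continue
            amp = math.radians(20 if "flexion" in c else 8)
            off = math.radians(25) if c.startswith("knee") else 0.0
            Q[:, i] = off + amp * np.sin(2 * math.pi * 0.8 * t + i)
        orient = {}
        for s in registration.mapping:
            qs = np.array([measured_at(model, Q[k], registration.offsets)[s] for k in range(n)])
            orient[s] = OrientationSeries(s, t, qs)
        res = ik_trajectory(model, registration, orient)
        rms = np.degrees(np.sqrt(np.mean((res.q - Q) ** 2, axis=0)))
        assert rms.max() < 0.5
        assert np.nanmax(res.cost) < 1e-10

    def test_zero_weight_equals_sensor_removed(self, model, registration, rng):
        qt = random_inbounds_pose(model, rng)
        measured = measured_at(model, qt, registration.offsets)
        # corrupt one foot sensor badly
        measured["calcn_r_imu"] = rot.quat_multiply(
            rot.quat_from_axis_angle([0, 0, 1], math.radians(45)), measured["calcn_r_imu"]
        )
        w0 = dict(DEFAULT_WEIGHTS, calcn_r_imu=0.0)
        pose_a, _, _ = ik_frame(model, registration, measured, weights=w0)
        removed = {s: q for s, q in measured.items() if s != "calcn_r_imu"}
        w1 = {s: w for s, w in DEFAULT_WEIGHTS.items() if s != "calcn_r_imu"}
        pose_b, _, _ = ik_frame(model, registration, removed, weights=w1)
        assert np.array_equal(pose_a.q, pose_b.q)  # bit-identical

    def test_downweighting_corrupt_foot_improves_hip_rotation(self, model, registration, rng):
        qt = random_inbounds_pose(model, rng, scale_deg=25.0)
        measured = measured_at(model, qt, registration.offsets)
        measured["calcn_r_imu"] = rot.quat_multiply(
            rot.quat_from_axis_angle([0, 0, 1], math.radians(45)), measured["calcn_r_imu"]
        )
        i_hr = model.coord_index["hip_rotation_r"]
        errs = []
        for w_foot in (1.0, 0.25, 0.0):
            w = dict(DEFAULT_WEIGHTS, tibia_r_imu=1.0, tibia_l_imu=1.0,
                     calcn_l_imu=1.0, calcn_r_imu=w_foot)
            pose, _, _ = ik_frame(
                model, registration, measured, weights=w,
                q_init=model.make_pose(dict(zip(model.coordinates, qt))),
            )
            errs.append(abs(math.degrees(pose.q[i_hr] - qt[i_hr])))
        assert errs[0] > errs[1] > errs[2]
        assert errs[2] < 1e-6

    def test_weight_scaling_leaves_argmin_unchanged(self, model, registration, rng):
        qt = random_inbounds_pose(model, rng)
        measured = measured_at(model, qt, registration.offsets)
        measured["torso_imu"] = rot.quat_multiply(
            rot.quat_from_axis_angle([1, 0, 0], math.radians(5)), measured["torso_imu"]
        )
        pose_a, _, ca = ik_frame(model, registration, measured, weights=DEFAULT_WEIGHTS)
        scaled = {s: 3.0 * w for s, w in DEFAULT_WEIGHTS.items()}
        pose_b, _, cb = ik_frame(model, registration, measured, weights=scaled)
        assert np.degrees(np.abs(pose_a.q - pose_b.q)).max() < 1e-4
        assert cb == pytest.approx(3.0 * ca, rel=1e-3)


class TestCost:
    def test_zero_at_generating_pose(self, model, registration, rng):
        qt = random_inbounds_pose(model, rng)
        measured = measured_at(model, qt, registration.offsets)
        pose = model.make_pose(dict(zip(model.coordinates, qt)))
        assert cost(model, registration, measured, None, pose) < 1e-18

    def test_single_sensor_arithmetic(self, model, registration):
        measured = measured_at(model, np.zeros(19), registration.offsets)
        q = measured["torso_imu"]
        measured_one = {"torso_imu": rot.quat_multiply(rot.quat_from_axis_angle([0, 0, 1], 0.2), q)}
        c = cost(model, registration, measured_one, {"torso_imu": 1.0}, model.zero_pose())
        assert c == pytest.approx(0.04, rel=1e-9)

    def test_cost_equals_weighted_sum_of_squared_theta(self, model, registration, rng):
        qt = random_inbounds_pose(model, rng)
        measured = measured_at(model, qt, registration.offsets)
        pose, theta, c = ik_frame(model, registration, measured)
        manual = sum(
            DEFAULT_WEIGHTS[s] * math.radians(theta[s]) ** 2 for s in theta
        )
        assert c == pytest.approx(manual, abs=1e-9)

    def test_decreases_along_negative_numeric_gradient(self, model, registration, rng):
        qt = random_inbounds_pose(model, rng, scale_deg=20.0)
        measured = measured_at(model, qt, registration.offsets)
        q0 = np.zeros(19)
        pose0 = model.make_pose(dict(zip(model.coordinates, q0)))
        c0 = cost(model, registration, measured, None, pose0)
        eps = 1e-6
        grad = np.zeros(19)
        for i, cname in enumerate(model.coordinates):
            if model._is_translation(cname):
                continue
            qp = q0.copy()
            qp[i] += eps
            grad[i] = (
                cost(model, registration, measured, None, model.make_pose(dict(zip(model.coordinates, qp)))) - c0
            ) / eps
        step = q0 - 1e-3 * grad / max(np.linalg.norm(grad), 1e-12)
        c1 = cost(model, registration, measured, None, model.make_pose(dict(zip(model.coordinates, step))))
        assert c1 < c0
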