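"""Sensor fusion: initialization, filter steps, equivalences, round trips."""

import math

import numpy as np
import pytest

from imukin import rotations as rot
from imukin.fusion import (
    DegenerateFieldError,
    FilterConfig,
    ImuSeries,
    OrientationSeries,
    fusion_error,
    initial_orientation,
    integrate_gyro,
    madgwick_step,
    mahony_step,
    run_filter,
)
from imukin.synthetic import (
    DEFAULT_MAG_FIELD,
    MagDisturbance,
    NoiseModel,
    TrajectoryConfig,
    generate_trial,
)

ACCEL_STATIC = np.array([0.0, 0.0, 9.81])
MAG_X = np.array([1.0, 0.0, 0.0])


def static_series(duration_s=10.0, rate=100.0, q_true=None, sensor_id="s"):
    """Zero-noise static IMU stream for a sensor at orientation q_true."""
    n = int(duration_s * rate) + 1
    t = np.arange(n) / rate
    if q_true is None:
        q_true = np.array([1.0, 0, 0, 0])
    qc = rot.quat_conjugate(q_true)
    accel = np.tile(rot.quat_rotate(qc, ACCEL_STATIC), (n, 1))
    mag = np.tile(rot.quat_rotate(qc, DEFAULT_MAG_FIELD), (n, 1))
    return ImuSeries(sensor_id, t, np.zeros((n, 3)), accel, mag, rate)


class TestInitialOrientation:
    def test_aligned_sensor_gives_identity(self):
        q = initial_orientation(ACCEL_STATIC, MAG_X)
        assert np.allclose(q, [1, 0, 0, 0], atol=1e-12)

    def test_mag_along_y_gives_quarter_turn_yaw(self):
        q = initial_orientation(ACCEL_STATIC, [0, 1, 0])
        assert math.degrees(rot.orientation_difference(q, [1, 0, 0, 0])) == pytest.approx(90)
        # the horizontal field maps to earth +X
        assert np.allclose(rot.quat_rotate(q, [0, 1, 0]), [1, 0, 0], atol=1e-12)

    def test_sideways_sensor_maps_earth_z_to_sensor_x(self):
        q = initial_orientation([9.81, 0, 0], [0.2, 0.3, 0.9])
        # inverse rotation takes earth +Z to the sensor axis that saw gravity
        assert np.allclose(
            rot.quat_rotate(rot.quat_conjugate(q), [0, 0, 1]), [1, 0, 0], atol=1e-9
        )

    def test_degenerate_field_errors(self):
        with pytest.raises(DegenerateFieldError):
            initial_orientation(ACCEL_STATIC, [0, 0, 2.0])  # parallel to gravity
        with pytest.raises(DegenerateFieldError):
            initial_orientation([0, 0, 0], MAG_X)


class TestFilterSteps:
    def test_static_truth_is_fixed_point(self):
        q = rot.quat_from_axis_angle([0.2, 0.9, 0.1], 0.6)
        accel = rot.quat_rotate(rot.quat_conjugate(q), ACCEL_STATIC)
        mag = rot.quat_rotate(rot.quat_conjugate(q), DEFAULT_MAG_FIELD)
        q2 = madgwick_step(q, np.zeros(3), accel, mag, 0.01, beta=0.1)
        assert rot.orientation_difference(q, q2) < 1e-9
        q3, _ = mahony_step(q, np.zeros(3), accel, mag, 0.01, 0.5, 0.1, np.zeros(3))
        assert rot.orientation_difference(q, q3) < 1e-9

    def test_beta_zero_is_pure_integration(self):
        q = np.array([1.0, 0, 0, 0])
        w = np.array([0.0, 0.0, math.radians(10)])
        for _ in range(100):
            q = madgwick_step(q, w, ACCEL_STATIC, MAG_X, 0.01, beta=0.0)
        # 10 deg/s for 1 s -> 10 deg of heading
        assert math.degrees(rot.orientation_difference(q, [1, 0, 0, 0])) == pytest.approx(
            10.0, abs=0.01
        )

    def test_madgwick_converges_from_20_deg_static(self):
        q_true = np.array([1.0, 0, 0, 0])
        q = rot.quat_from_axis_angle([0.3, 0.5, 0.8], math.radians(20))
        for _ in range(1000):  # 10 s at 100 Hz
            q = madgwick_step(q, np.zeros(3), ACCEL_STATIC, np.array(DEFAULT_MAG_FIELD), 0.01, 0.1)
        assert math.degrees(rot.orientation_difference(q, q_true)) < 1.0

    def test_mahony_gains_zero_equals_gyro_only(self, walk_trial):
        series = walk_trial.imu["tibia_l_imu"]
        q0 = rot.quat_from_axis_angle([1, 2, 3], 0.4)
        ref = integrate_gyro(series, q0)
        cfg = FilterConfig(algorithm="mahony", kp=0.0, ki=0.0, init_window_s=5.0)
        q = ref.q[0]
        bias = np.zeros(3)
        t, g = series.t, series.gyro
        for k in range(1, min(len(series), 500)):
            w_mid = 0.5 * (g[k - 1] + g[k])
            q, bias = mahony_step(
                q, w_mid, series.accel[k], series.mag[k], t[k] - t[k - 1], 0.0, 0.0, bias
            )
            assert rot.orientation_difference(q, ref.q[k]) <= 1e-9

    def test_mahony_estimates_constant_gyro_bias(self):
        bias_true = np.array([0.05, -0.03, 0.02])
        q = np.array([1.0, 0, 0, 0])
        bias = np.zeros(3)
        for _ in range(20000):  # 200 s static
            q, bias = mahony_step(
                q, bias_true, ACCEL_STATIC, np.array(DEFAULT_MAG_FIELD), 0.01, 0.5, 0.1, bias
            )
        assert np.allclose(bias, bias_true, rtol=0.05, atol=0.002)


class TestIntegrateGyro:
    def test_zero_gyro_holds_initial(self):
        ser = static_series(2.0)
        q0 = rot.quat_from_axis_angle([1, 1, 0], 0.3)
        out = integrate_gyro(ser, q0)
        assert all(rot.orientation_difference(q, q0) < 1e-12 for q in out.q)

    def test_constant_rate_closed_form(self):
        n = 101
        t = np.arange(n) / 100.0
        w = np.tile([0.0, 0.0, math.radians(90)], (n, 1))
        ser = ImuSeries("s", t, w, np.zeros((n, 3)), np.zeros((n, 3)), 100.0)
        out = integrate_gyro(ser, np.array([1.0, 0, 0, 0]))
        expected = rot.quat_from_axis_angle([0, 0, 1], math.radians(90))
        assert math.degrees(rot.orientation_difference(out.q[-1], expected)) < 0.1

    def test_noise_drives_error_growth(self):
        rng = np.random.default_rng(0)
        n = 3001
        t = np.arange(n) / 100.0
        errs = []
        for trial in range(8):
            w = rng.normal(0.0, 0.05, (n, 3))
            ser = ImuSeries("s", t, w, np.zeros((n, 3)), np.zeros((n, 3)), 100.0)
            out = integrate_gyro(ser, np.array([1.0, 0, 0, 0]))
            errs.append(
                [
                    rot.orientation_difference(out.q[k], [1, 0, 0, 0])
                    for k in (1000, 2000, 3000)
                ]
            )
        mean = np.mean(errs, axis=0)
        assert mean[0] < mean[1] < mean[2]

    def test_reproduces_synthetic_truth(self, walk_trial):
        # forward-inverse consistency of the generator's finite-difference gyro
        s = "femur_r_imu"
        truth = walk_trial.sensor_truth[s]
        out = integrate_gyro(walk_trial.imu[s], truth.q[0])
        worst = max(
            rot.orientation_difference(out.q[k], truth.q[k]) for k in range(len(out))
        )
        assert math.degrees(worst) < 0.2


class TestRunFilter:
    def test_static_series_stays_at_initial_orientation(self):
        q_true = rot.quat_from_axis_angle([0.1, 0.8, 0.2], 0.5)
        ser = static_series(8.0, q_true=q_true)
        for algo in ("madgwick", "mahony", "gyro_only"):
            out = run_filter(ser, FilterConfig(algorithm=algo))
            for q in out.q[::100]:
                assert math.degrees(rot.orientation_difference(q, q_true)) < 1e-6

    def test_too_short_series_raises(self):
        ser = static_series(3.0)
        with pytest.raises(ValueError, match="initialization window"):
            run_filter(ser, FilterConfig(init_window_s=5.0))

    def test_walking_round_trip_rms_below_2_deg(self, walk_trial, walk_fused):
        for s in ("femur_r_imu", "calcn_l_imu", "torso_imu"):
            rms = fusion_error(walk_fused[s], walk_trial.sensor_truth[s], window_s=5.0)
            assert np.all(rms[1:] < 2.0), s  # after the initial 5 s

    def test_mag_off_keeps_inclination_despite_corrupt_mag(self):
        # corrupted magnetometer, clean gyro/accel: with the magnetometer
        # effectively disabled the heading may drift but inclination must hold
        cfg = TrajectoryConfig(duration_s=30.0, rate_hz=100.0, activity="walk")
        noise = NoiseModel(
            0.0, 0.0, 0.0, 0.0, 0.0,
            mag_disturbance={"tibia_r_imu": MagDisturbance(70.0, t_on=6.0)},
        )
        trial = generate_trial(config=cfg, noise=noise, seed=21)
        out = run_filter(
            trial.imu["tibia_r_imu"], FilterConfig(algorithm="madgwick", mag_divisor=10**9)
        )
        truth = trial.sensor_truth["tibia_r_imu"]
        incl = []
        for k in range(500, len(out), 10):
            up_est = rot.quat_rotate(rot.quat_conjugate(out.q[k]), [0, 0, 1])
            up_true = rot.quat_rotate(rot.quat_conjugate(truth.q[k]), [0, 0, 1])
            incl.append(math.degrees(math.acos(np.clip(up_est @ up_true, -1, 1))))
        assert np.sqrt(np.mean(np.square(incl))) < 2.0

    def test_40hz_retuned_gain_tracks_within_2x_of_100hz(self):
        errs = {}
        for rate, beta in ((100.0, 0.1), (40.0, 0.025)):
            cfg = TrajectoryConfig(duration_s=30.0, rate_hz=rate, activity="walk")
            trial = generate_trial(config=cfg, noise=NoiseModel(), seed=5)
            out = run_filter(trial.imu["femur_r_imu"], FilterConfig(beta=beta))
            rms = fusion_error(out, trial.sensor_truth["femur_r_imu"], window_s=25.0)
            errs[rate] = rms[-1]
        assert errs[40.0] < 2.0 * errs[100.0] + 0.5


class TestFusionError:
    def test_identical_series_zero(self, walk_fused):
        est = walk_fused["torso_imu"]
        assert np.allclose(fusion_error(est, est, window_s=5.0), 0.0)

    def test_constant_offset_gives_constant_rms(self, walk_fused):
        est = walk_fused["torso_imu"]
        dq = rot.quat_from_axis_angle([0.3, -0.2, 0.9], math.radians(10))
        shifted = OrientationSeries(
            est.sensor_id, est.t, np.array([rot.quat_multiply(dq, q) for q in est.q])
        )
        rms = fusion_error(shifted, est, window_s=5.0)
        assert np.allclose(rms, 10.0, atol=1e-6)

    def test_sinusoidal_error_rms_matches_closed_form(self):
        rate, dur = 100.0, 20.0
        n = int(rate * dur)
        t = np.arange(n) / rate
        amp = math.radians(20.0)
        angles = amp * np.abs(np.sin(2 * math.pi * 0.5 * t))
        base = np.tile([1.0, 0, 0, 0], (n, 1))
        perturbed = np.array(
            [rot.quat_from_axis_angle([0, 0, 1], a) for a in angles]
        )
        ref = OrientationSeries("s", t, base)
        est = OrientationSeries("s", t, perturbed)
        rms = fusion_error(est, ref, window_s=dur)
        expected = math.degrees(amp) / math.sqrt(2)  # RMS of a sinusoid
        assert rms[0] == pytest.approx(expected, rel=0.01)

    def test_length_mismatch_raises(self, walk_fused):
        est = walk_fused["torso_imu"]
        short = OrientationSeries(est.sensor_id, est.t[:-1], est.q[:-1])
        with pytest.raises(ValueError):
            fusion_error(est, short)


def test_gain_zero_equivalence_across_filters(walk_trial):
    """madgwick(beta=0), mahony(kp=ki=0) and strap-down integration agree."""
    series = walk_trial.imu["calcn_r_imu"]
    ref = run_filter(series, FilterConfig(algorithm="gyro_only"))
    mad = run_filter(series, FilterConfig(algorithm="madgwick", beta=0.0))
    mah = run_filter(series, FilterConfig(algorithm="mahony", kp=0.0, ki=0.0))
    for k in range(0, len(ref), 7):
        assert rot.orientation_difference(mad.q[k], ref.q[k]) <= 1e-9
        assert rot.orientation_difference(mah.q[k], ref.q[k]) <= 1e-9
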