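import numpy as np
import pytest

from gaitkit.core_types import (
    GRAVITY_VECTOR,
    ImuRecording,
    IntervalList,
    quat_conjugate,
    quat_from_axis_angle,
    quat_multiply,
    quat_rotate,
    quat_to_rotation_vector,
)
from gaitkit.event_detection import detect_events, to_min_vel_strides
from gaitkit.parameters import spatial_parameters
from gaitkit.synthetic_gait import GaitProfile, simulate_session
from gaitkit.trajectory import (
    KalmanConfig,
    _trapezoid_cumulative,
    _world_linear_acc,
    forward_backward_integration,
    integrate_gyro,
    madgwick,
    piecewise_linear_dedrifted_integration,
    rts_kalman,
)


def _static_rec(n, rate=100.0):
    return ImuRecording(acc=np.tile(GRAVITY_VECTOR, (n, 1)),
                        gyr=np.zeros((n, 3)), sampling_rate=rate)


def _min_vel_strides(bundle):
    return IntervalList(
        np.column_stack([bundle.events.min_vel[:-1],
                         bundle.events.min_vel[1:]]).astype(int)
    )


class TestIntegrateGyro:
    def test_zero_rate_keeps_initial_orientation(self):
        q0 = quat_from_axis_angle(np.array([0.0, 0, 1]), 0.3)
        out = integrate_gyro(_static_rec(50), q0)
        assert np.allclose(out, q0, atol=1e-15)

    def test_constant_rate_matches_closed_form(self):
        # 90 deg/s about z for 1 s at 100 Hz
        rec = ImuRecording(acc=np.tile(GRAVITY_VECTOR, (101, 1)),
                           gyr=np.tile([0.0, 0, 90.0], (101, 1)),
                           sampling_rate=100.0)
        out = integrate_gyro(rec)
        angle = quat_to_rotation_vector(out[-1])
        assert np.allclose(angle, [0, 0, np.pi / 2], atol=1e-6)

    def test_half_integrations_compose(self, rng):
        gyr = rng.normal(0, 50, (100, 3))
        acc = np.tile(GRAVITY_VECTOR, (100, 1))
        rec = ImuRecording(acc=acc, gyr=gyr, sampling_rate=100.0)
        full = integrate_gyro(rec)
        first = ImuRecording(acc=acc[:51], gyr=gyr[:51], sampling_rate=100.0)
        second = ImuRecording(acc=acc[50:], gyr=gyr[50:], sampling_rate=100.0)
        q_mid = integrate_gyro(first)[-1]
        q_end = integrate_gyro(second, q_mid)[-1]
        assert np.allclose(q_end, full[-1], atol=1e-10)

    def test_outputs_are_unit_quaternions(self, rng):
        rec = ImuRecording(acc=np.tile(GRAVITY_VECTOR, (500, 1)),
                           gyr=rng.normal(0, 200, (500, 3)),
                           sampling_rate=100.0)
        out = integrate_gyro(rec)
        assert np.allclose(np.linalg.norm(out, axis=1), 1.0, atol=1e-9)


class TestMadgwick:
    def test_beta_zero_equals_gyro_integration_bitwise(self, rng):
        rec = ImuRecording(acc=rng.normal(0, 3, (200, 3)) + GRAVITY_VECTOR,
                           gyr=rng.normal(0, 100, (200, 3)),
                           sampling_rate=100.0)
        assert np.array_equal(madgwick(rec, beta=0.0), integrate_gyro(rec))

    def test_static_tilt_converges_within_half_degree(self):
        tilt = quat_from_axis_angle(np.array([0.0, 1, 0]), np.deg2rad(20))
        acc = quat_rotate(quat_conjugate(tilt), GRAVITY_VECTOR)
        rec = ImuRecording(acc=np.tile(acc, (1000, 1)),
                           gyr=np.zeros((1000, 3)), sampling_rate=100.0)
        q = madgwick(rec, beta=0.1)
        mapped = quat_rotate(q[-1], acc)
        misalign = np.degrees(
            np.arccos(np.clip(mapped @ [0, 0, 1] / 9.81, -1, 1))
        )
        assert misalign < 0.5

    def test_zero_acc_sample_skips_gradient(self):
        acc = np.tile(GRAVITY_VECTOR, (50, 1))
        acc[10:20] = 0.0
        rec = ImuRecording(acc=acc, gyr=np.zeros((50, 3)), sampling_rate=100.0)
        q = madgwick(rec, beta=0.5)
        assert np.all(np.isfinite(q))
        assert np.allclose(np.linalg.norm(q, axis=1), 1.0, atol=1e-9)


class TestForwardBackwardIntegration:
    def test_static_input_gives_zero_displacement(self):
        rec = _static_rec(300)
        q = integrate_gyro(rec)
        traj = forward_backward_integration(rec, q, (0, 300))
        assert np.allclose(traj.position, 0.0, atol=1e-9)

    def test_recovers_simulated_stride_length(self, default_session):
        rec = default_session.recording
        q = integrate_gyro(rec)
        for start, end in _min_vel_strides(default_session):
            traj = forward_backward_integration(rec, q, (start, end))
            disp = traj.position[-1] - traj.position[0]
            length = np.hypot(disp[0], disp[1])
            assert length == pytest.approx(
                default_session.profile.stride_length, abs=0.01
            )

    def test_combined_beats_forward_only_under_gyro_bias(self):
        bundle = simulate_session(GaitProfile(n_strides=3, gyro_bias=1.0))
        rec = bundle.recording
        q = integrate_gyro(rec)
        start, end = _min_vel_strides(bundle).intervals[0]
        a_w = _world_linear_acc(rec.acc[start:end], q[start:end])
        v_fwd = _trapezoid_cumulative(a_w, 1 / rec.sampling_rate)
        traj = forward_backward_integration(rec, q, (start, end))
        v_comb_end = (traj.position[-1] - traj.position[-2]) * rec.sampling_rate
        assert np.linalg.norm(v_fwd[-1]) > np.linalg.norm(v_comb_end)

    def test_too_short_region_rejected(self):
        rec = _static_rec(10)
        with pytest.raises(ValueError):
            forward_backward_integration(rec, integrate_gyro(rec), (0, 2))


class TestPiecewiseLinearDedrift:
    def test_clean_input_equals_plain_double_integration(self):
        rec = _static_rec(200)
        q = integrate_gyro(rec)
        zupts = IntervalList([[0, 20], [180, 200]])
        traj = piecewise_linear_dedrifted_integration(rec, q, zupts)
        assert np.allclose(traj.position, 0.0, atol=1e-12)

    def test_constant_accel_bias_removed_exactly(self):
        n, rate = 500, 100.0
        acc = np.tile(GRAVITY_VECTOR + [0.08, -0.03, 0.05], (n, 1))
        rec = ImuRecording(acc=acc, gyr=np.zeros((n, 3)), sampling_rate=rate)
        q = integrate_gyro(rec)
        zupts = IntervalList([[0, 30], [470, 500]])
        traj = piecewise_linear_dedrifted_integration(rec, q, zupts)
        end_vel = (traj.position[-1] - traj.position[-2]) * rate
        assert np.linalg.norm(end_vel) <= 1e-9

    def test_recovers_simulated_stride_lengths(self, default_session):
        rec = default_session.recording
        q = integrate_gyro(rec)
        traj = piecewise_linear_dedrifted_integration(
            rec, q, default_session.zupts
        )
        spatial = spatial_parameters(traj, _min_vel_strides(default_session))
        assert np.all(
            np.abs(spatial["stride_length"]
                   - default_session.profile.stride_length) <= 0.01
        )

    def test_fewer_than_two_zupts_rejected(self):
        rec = _static_rec(100)
        with pytest.raises(ValueError, match="forward_backward"):
            piecewise_linear_dedrifted_integration(
                rec, integrate_gyro(rec), IntervalList([[0, 20]])
            )


class TestRtsKalman:
    def test_static_recording_stays_at_origin(self):
        rec = _static_rec(400)
        result = rts_kalman(rec, IntervalList([[0, 400]]))
        assert np.allclose(result.trajectory.position, 0.0, atol=1e-6)

    def test_recovers_simulated_stride_lengths(self, default_session):
        result = rts_kalman(default_session.recording, default_session.zupts)
        spatial = spatial_parameters(result.trajectory,
                                     _min_vel_strides(default_session))
        assert np.all(
            np.abs(spatial["stride_length"]
                   - default_session.profile.stride_length) <= 0.01
        )

    def test_smoothing_never_increases_covariance_trace(self, noisy_session):
        result = rts_kalman(noisy_session.recording, noisy_session.zupts)
        assert np.all(result.smoothed_cov_trace
                      <= result.filtered_cov_trace + 1e-9)

    def test_velocity_near_zero_inside_zupts(self, default_session):
        cfg = KalmanConfig()
        result = rts_kalman(default_session.recording, default_session.zupts,
                            cfg)
        mask = default_session.zupts.to_mask(
            default_session.recording.n_samples
        )
        speeds = np.linalg.norm(result.velocity[mask], axis=1)
        assert np.all(speeds <= 3 * cfg.zupt_measurement_noise)

    def test_smoothing_reduces_state_error_under_noise(self):
        """With a matched noise model, smoothing beats filtering in velocity
        RMS on every seed and in position RMS on average (position error is
        only indirectly observable from zero-velocity measurements)."""
        cfg = KalmanConfig(accel_noise=0.02, gyro_noise=0.1)
        pos_s, pos_f = [], []
        for seed in range(3):
            bundle = simulate_session(
                GaitProfile(n_strides=10, gyro_noise_sigma=0.1,
                            acc_noise_sigma=0.02, seed=seed)
            )
            result = rts_kalman(bundle.recording, bundle.zupts, cfg)
            truth_p = bundle.trajectory.position
            truth_v = np.gradient(truth_p, axis=0) * bundle.recording.sampling_rate
            rms = lambda a, b: np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1)))
            assert rms(result.velocity, truth_v) \
                <= rms(result.filtered_velocity, truth_v)
            pos_s.append(rms(result.trajectory.position, truth_p))
            pos_f.append(rms(result.filtered_trajectory.position, truth_p))
        assert np.mean(pos_s) <= np.mean(pos_f)

    def test_warns_without_initial_zupt(self):
        rec = _static_rec(100)
        with pytest.warns(UserWarning, match="initial velocity"):
            rts_kalman(rec, IntervalList([[50, 100]]))

    def test_orientation_outputs_are_unit(self, noisy_session):
        result = rts_kalman(noisy_session.recording, noisy_session.zupts)
        norms = np.linalg.norm(result.trajectory.orientation, axis=1)
        assert np.allclose(norms, 1.0, atol=1e-9)


def test_all_methods_agree_on_stride_length(default_session):
    """The two dedrifted integrators and the smoother agree within 2 cm."""
    rec = default_session.recording
    q = integrate_gyro(rec)
    mv = _min_vel_strides(default_session)
    lengths = {}
    res = rts_kalman(rec, default_session.zupts)
    lengths["rts"] = spatial_parameters(res.trajectory, mv)["stride_length"]
    traj = piecewise_linear_dedrifted_integration(rec, q,
                                                  default_session.zupts)
    lengths["pwl"] = spatial_parameters(traj, mv)["stride_length"]
    fbi = []
    for start, end in mv:
        t = forward_backward_integration(rec, q, (start, end))
        d = t.position[-1] - t.position[0]
        fbi.append(np.hypot(d[0], d[1]))
    lengths["fbi"] = np.asarray(fbi)
    for a in lengths.values():
        for b in lengths.values():
            assert np.all(np.abs(np.asarray(a) - np.asarray(b)) <= 0.02)
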