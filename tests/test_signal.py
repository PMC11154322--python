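import numpy as np
import pytest

from imupose.core import (
    FrameConvention,
    ImuSample,
    ImuStream,
    SensorNoiseModel,
    TrackerState,
    quat_canonical,
    quat_from_rotvec,
    quat_identity,
    quat_mul,
    quat_conj,
    quat_to_rotvec,
)
from imupose.signal import (
    FilterConfig,
    KalmanChannel,
    drift_compensate,
    filter_stream,
    integrate_step,
    integrate_stream,
    kalman_predict,
    kalman_update,
    riccati_fixed_point,
    strength_to_qr,
)


# ---------------------------------------------------------------------------
# Kalman filter
# ---------------------------------------------------------------------------

class TestKalmanPredict:
    def test_static_model(self):
        ch = KalmanChannel(x_hat=5.0, p=2.0, a=1.0, b=0.0, q=0.0)
        out = kalman_predict(ch)
        assert out.x_hat == 5.0 and out.p == 2.0

    def test_process_noise(self):
        out = kalman_predict(KalmanChannel(x_hat=5.0, p=2.0, q=0.1))
        assert np.isclose(out.p, 2.1)

    def test_hand_arithmetic(self):
        out = kalman_predict(KalmanChannel(x_hat=1.0, p=1.0, a=0.9, b=0.5, u=2.0, q=0.0))
        assert np.isclose(out.x_hat, 1.9)
        assert np.isclose(out.p, 0.81)


class TestKalmanUpdate:
    def test_perfect_measurement(self):
        ch = KalmanChannel(x_hat=3.0, p=1.0, r=0.0, h=1.0)
        out = kalman_update(ch, z=7.0)
        assert out.x_hat == 7.0  # gain saturates at 1

    def test_perfect_prior(self):
        ch = KalmanChannel(x_hat=3.0, p=0.0, r=1.0, h=1.0)
        out = kalman_update(ch, z=100.0)
        assert out.x_hat == 3.0  # gain 0

    def test_hand_arithmetic(self):
        ch = KalmanChannel(x_hat=0.0, p=1.0, r=1.0, h=1.0)
        out = kalman_update(ch, z=2.0)
        assert np.isclose(out.x_hat, 1.0)  # k = 0.5
        assert np.isclose(out.p, 0.5)

    def test_degenerate_gain(self):
        with pytest.raises(ZeroDivisionError):
            kalman_update(KalmanChannel(x_hat=0.0, p=0.0, r=0.0), z=1.0)

    def test_recursion_matches_hand_computed_sequence(self):
        # two steps of the full predict/update cycle, checked by hand
        q, r = 0.5, 2.0
        ch = KalmanChannel(x_hat=0.0, p=1.0, q=q, r=r)
        zs = [1.0, -1.0]
        xs, ps = [], []
        x, p = 0.0, 1.0
        for z in zs:
            pp = p + q
            k = pp / (pp + r)
            x = x + k * (z - x)
            p = (1 - k) * pp
            xs.append(x)
            ps.append(p)
        for z, xe, pe in zip(zs, xs, ps):
            ch = kalman_update(kalman_predict(ch), z)
            assert np.isclose(ch.x_hat, xe, atol=1e-15)
            assert np.isclose(ch.p, pe, atol=1e-15)


class TestFilterStream:
    def make_stream(self, z, tracker="chest"):
        n = len(z)
        arr = np.tile(np.asarray(z, dtype=float)[:, None], (1, 3))
        return ImuStream(t=np.arange(n) * 0.01, accel=arr, gyro=arr * 0.1,
                         tracker_id=tracker)

    def test_strength_zero_identity(self, rng):
        z = rng.standard_normal(200)
        s = self.make_stream(z)
        out = filter_stream(s, FilterConfig(filtering_strength=0.0))
        assert np.array_equal(out.accel, s.accel)
        assert np.array_equal(out.gyro, s.gyro)

    def test_strength_mapping_gain(self):
        # K_inf = 1 - s, from the Riccati fixed point
        for s in (0.2, 0.5, 0.8):
            q, r = strength_to_qr(s)
            p_inf = riccati_fixed_point(q, r)
            k_inf = (p_inf + q) / (p_inf + q + r)
            assert np.isclose(k_inf, 1.0 - s, atol=1e-12)

    def test_constant_signal_convergence(self):
        s = self.make_stream(np.full(500, 3.3))
        out = filter_stream(s, FilterConfig(filtering_strength=0.5))
        assert np.allclose(out.accel[-1], 3.3, atol=1e-9)

    def test_riccati_fixed_point_formula(self):
        q, r = strength_to_qr(0.5)
        p = r  # start the posterior variance recursion anywhere
        for _ in range(200):
            pp = p + q
            k = pp / (pp + r)
            p = (1 - k) * pp
        assert np.isclose(p, riccati_fixed_point(q, r), atol=1e-12)
        assert np.isclose(riccati_fixed_point(q, r), (-q + np.sqrt(q * q + 4 * q * r)) / 2)

    def test_white_noise_variance_reduced(self):
        rng = np.random.default_rng(99)
        z = rng.standard_normal(10_000)
        s = self.make_stream(z)
        out = filter_stream(s, FilterConfig(filtering_strength=0.5))
        assert out.accel[:, 0].var() < s.accel[:, 0].var()

    def test_variance_monotone_in_strength(self):
        rng = np.random.default_rng(7)
        z = rng.standard_normal(10_000)
        s = self.make_stream(z)
        variances = []
        for strength in (0.0, 0.25, 0.5, 0.75, 0.95):
            out = filter_stream(s, FilterConfig(filtering_strength=strength))
            variances.append(out.accel[:, 0].var())
        assert all(a > b for a, b in zip(variances, variances[1:]))

    def test_empty_stream_error(self):
        s = ImuStream(t=np.empty(0), accel=np.empty((0, 3)), gyro=np.empty((0, 3)))
        with pytest.raises(ValueError):
            filter_stream(s, FilterConfig())

    def test_matches_scalar_recursion(self, rng):
        # fast path (lfilter tail) must equal the plain per-sample recursion
        z = rng.standard_normal(400)
        s = self.make_stream(z)
        out = filter_stream(s, FilterConfig(filtering_strength=0.3))
        q, r = strength_to_qr(0.3)
        x, p = z[0], r
        expected = []
        for zi in z:
            pp = p + q
            k = pp / (pp + r)
            x = x + k * (zi - x)
            p = (1 - k) * pp
            expected.append(x)
        assert np.allclose(out.accel[:, 0], expected, atol=1e-10)


# ---------------------------------------------------------------------------
# Strapdown integration
# ---------------------------------------------------------------------------

def sample(t, accel, gyro):
    return ImuSample(t=t, accel=np.asarray(accel, float), gyro=np.asarray(gyro, float))


class TestIntegrateStep:
    def test_stationary(self, frame, noiseless):
        rest = frame.rest_specific_force
        st = TrackerState(q=quat_identity(), v=np.zeros(3), d=np.zeros(3), t=0.0)
        out = integrate_step(st, sample(0.0, rest, np.zeros(3)),
                             sample(0.01, rest, np.zeros(3)), noiseless, frame)
        assert np.allclose(out.q, quat_identity(), atol=1e-15)
        assert np.allclose(out.v, 0.0, atol=1e-12)
        assert np.allclose(out.d, 0.0, atol=1e-12)

    def test_inertial_coasting_zero_gravity(self, noiseless):
        frame0 = FrameConvention(gravity_vector=np.zeros(3))
        st = TrackerState(q=quat_identity(), v=np.array([1.0, 0, 0]), d=np.zeros(3), t=0.0)
        out = integrate_step(st, sample(0.0, np.zeros(3), np.zeros(3)),
                             sample(0.01, np.zeros(3), np.zeros(3)), noiseless, frame0)
        assert np.allclose(out.d, [0.01, 0, 0], atol=1e-15)

    def test_rotation_closed_form(self, frame, noiseless):
        # 90 deg about Z after 100 steps at pi/2 rad/s
        st = TrackerState(q=quat_identity(), v=np.zeros(3), d=np.zeros(3), t=0.0)
        w = np.array([0.0, 0.0, np.pi / 2])
        for i in range(100):
            # specific force consistent with the current orientation so that
            # the world acceleration stays zero (tracker spinning in place)
            def f(q):
                from imupose.core import quat_rotate
                return quat_rotate(quat_conj(q), frame.rest_specific_force)
            s0 = sample(i * 0.01, f(st.q), w)
            q_next = quat_mul(st.q, quat_from_rotvec(w * 0.01))
            s1 = sample((i + 1) * 0.01, f(q_next), w)
            st = integrate_step(st, s0, s1, noiseless, frame)
        expected = quat_from_rotvec([0, 0, np.pi / 2])
        err = quat_mul(quat_conj(st.q), expected)
        assert np.degrees(np.linalg.norm(quat_to_rotvec(err))) < 1e-6

    def test_constant_accel_displacement(self, frame, noiseless):
        # 1 m/s² world accel for 1 s from rest -> D = 0.5 m
        st = TrackerState(q=quat_identity(), v=np.zeros(3), d=np.zeros(3), t=0.0)
        f = np.array([1.0, 0.0, 0.0]) + frame.rest_specific_force
        for i in range(100):
            st = integrate_step(st, sample(i * 0.01, f, np.zeros(3)),
                                sample((i + 1) * 0.01, f, np.zeros(3)), noiseless, frame)
        assert abs(st.d[0] - 0.5) < 1e-3
        assert np.allclose(st.v, [1.0, 0, 0], atol=1e-9)

    def test_errors(self, frame, noiseless):
        st = TrackerState(q=quat_identity(), v=np.zeros(3), d=np.zeros(3), t=0.0)
        rest = frame.rest_specific_force
        with pytest.raises(ValueError, match="monotone"):
            integrate_step(st, sample(0.01, rest, np.zeros(3)),
                           sample(0.0, rest, np.zeros(3)), noiseless, frame)
        with pytest.raises(ValueError, match="0.1"):
            integrate_step(st, sample(0.0, rest, np.zeros(3)),
                           sample(0.5, rest, np.zeros(3)), noiseless, frame)
        bad = TrackerState(q=np.array([0.5, 0.5, 0, 0]), v=np.zeros(3), d=np.zeros(3), t=0.0)
        with pytest.raises(ValueError, match="unit"):
            integrate_step(bad, sample(0.0, rest, np.zeros(3)),
                           sample(0.01, rest, np.zeros(3)), noiseless, frame)


class TestIntegrateStream:
    def random_stream(self, rng, n=50):
        t = np.arange(n) * 0.01
        accel = rng.normal(0, 2.0, size=(n, 3))
        gyro = rng.normal(0, 1.0, size=(n, 3))
        return ImuStream(t=t, accel=accel, gyro=gyro, tracker_id="chest")

    def test_two_samples(self, frame, noiseless, rng):
        s = self.random_stream(rng, 2)
        init = TrackerState(q=quat_identity(), v=np.zeros(3), d=np.zeros(3), t=0.0)
        out = integrate_stream(s, init, noiseless, frame)
        assert len(out) == 2
        step = integrate_step(init, s[0], s[1], noiseless, frame)
        assert np.allclose(out.q[1], step.q, atol=1e-14)
        assert np.allclose(out.d[1], step.d, atol=1e-14)

    def test_equals_folding_integrate_step(self, frame, noiseless, rng):
        s = self.random_stream(rng, 40)
        init = TrackerState(q=quat_identity(), v=np.zeros(3), d=np.zeros(3), t=0.0)
        out = integrate_stream(s, init, noiseless, frame)
        st = init
        for i in range(len(s) - 1):
            st = integrate_step(st, s[i], s[i + 1], noiseless, frame)
            assert np.allclose(out.q[i + 1], st.q, atol=1e-12)
            assert np.allclose(out.v[i + 1], st.v, atol=1e-12)
            assert np.allclose(out.d[i + 1], st.d, atol=1e-12)

    def test_gyro_bias_cancellation(self, frame, rng):
        s = self.random_stream(rng, 30)
        bias = np.array([0.05, -0.02, 0.01])
        biased = ImuStream(t=s.t, accel=s.accel, gyro=s.gyro + bias, tracker_id="chest")
        init = TrackerState(q=quat_identity(), v=np.zeros(3), d=np.zeros(3), t=0.0)
        out_clean = integrate_stream(s, init, SensorNoiseModel(0, 0), frame)
        out_biased = integrate_stream(
            biased, init, SensorNoiseModel(0, 0, gyro_bias=bias), frame)
        assert np.allclose(out_clean.q, out_biased.q, atol=1e-12)

    def test_quaternion_norm_preserved_long_run(self, frame, noiseless, rng):
        s = self.random_stream(rng, 5000)
        init = TrackerState(q=quat_identity(), v=np.zeros(3), d=np.zeros(3), t=0.0)
        out = integrate_stream(s, init, noiseless, frame)
        norms = np.linalg.norm(out.q, axis=1)
        assert np.max(np.abs(norms - 1.0)) < 1e-9

    def test_motionless_any_orientation_zero_world_accel(self, frame, noiseless, rng):
        # Eq-consistency: fixed orientation, zero motion -> v, d stay zero
        from imupose.core import quat_normalize, quat_rotate
        q0 = quat_normalize(rng.standard_normal(4))
        f = quat_rotate(quat_conj(q0), frame.rest_specific_force)
        n = 200
        s = ImuStream(t=np.arange(n) * 0.01, accel=np.tile(f, (n, 1)),
                      gyro=np.zeros((n, 3)), tracker_id="chest")
        init = TrackerState(q=q0, v=np.zeros(3), d=np.zeros(3), t=0.0)
        out = integrate_stream(s, init, noiseless, frame)
        assert np.max(np.abs(out.v)) < 1e-12
        assert np.max(np.abs(out.d)) < 1e-12

    def test_too_short(self, frame, noiseless):
        s = ImuStream(t=[0.0], accel=np.zeros((1, 3)), gyro=np.zeros((1, 3)))
        init = TrackerState(q=quat_identity(), v=np.zeros(3), d=np.zeros(3), t=0.0)
        with pytest.raises(ValueError):
            integrate_stream(s, init, noiseless, frame)


# ---------------------------------------------------------------------------
# Drift compensation
# ---------------------------------------------------------------------------

def make_drifting_states(frame, drift_deg=10.0, n=101):
    """Identity reference with heading drift growing linearly to drift_deg."""
    from imupose.core import TrackerStates
    axis = frame.down
    angles = np.deg2rad(np.linspace(0.0, drift_deg, n))
    q = quat_from_rotvec(angles[:, None] * axis[None, :])
    return TrackerStates(t=np.arange(n) * 0.01, q=q, v=np.zeros((n, 3)),
                         d=np.zeros((n, 3)), tracker_id="chest")


class TestDriftCompensate:
    def test_strength_zero_identity(self, frame):
        states = make_drifting_states(frame)
        out = drift_compensate(states, quat_identity(),
                               FilterConfig(drift_compensation_strength=0.0), frame)
        assert np.array_equal(out.q, states.q)

    def test_full_strength_removes_drift(self, frame):
        from imupose.core import heading_angle
        states = make_drifting_states(frame, 10.0)
        out = drift_compensate(states, quat_identity(),
                               FilterConfig(drift_compensation_strength=1.0), frame)
        final = np.degrees(heading_angle(out.q[-1], frame.down))
        assert abs(final) < 1e-6

    def test_partial_strength_linear(self, frame):
        from imupose.core import heading_angle
        states = make_drifting_states(frame, 10.0)
        out = drift_compensate(states, quat_identity(),
                               FilterConfig(drift_compensation_strength=0.2), frame)
        final = np.degrees(heading_angle(out.q[-1], frame.down))
        assert abs(final - 8.0) < 1e-6

    def test_ramp_is_linear(self, frame):
        from imupose.core import heading_angle
        states = make_drifting_states(frame, 10.0)
        out = drift_compensate(states, quat_identity(),
                               FilterConfig(drift_compensation_strength=1.0), frame)
        # correction at the midpoint is half the final correction
        mid_in = np.degrees(heading_angle(states.q[50], frame.down))
        mid_out = np.degrees(heading_angle(out.q[50], frame.down))
        assert np.isclose(mid_in - mid_out, 5.0, atol=1e-9)

    def test_displacement_rotated_consistently(self, frame):
        states = make_drifting_states(frame, 10.0)
        states.d[:] = np.array([1.0, 0.0, 0.0])
        out = drift_compensate(states, quat_identity(),
                               FilterConfig(drift_compensation_strength=1.0), frame)
        assert np.allclose(np.linalg.norm(out.d, axis=1), 1.0, atol=1e-12)
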