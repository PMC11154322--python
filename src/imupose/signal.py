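"""Signal-processing chain: per-channel Kalman smoothing, strapdown
integration of orientation/velocity/displacement, and heading drift
compensation.

The Kalman filter runs independently on each of the six IMU channels with a
scalar random-walk model (a=1, b=0, h=1).  Its single "filtering strength"
dial s in [0, 1] maps to the steady-state gain K∞ = 1 - s, from which the
process/measurement variance ratio is solved via the scalar Riccati fixed
point.  s = 0 therefore reproduces the measurements exactly; larger s smooths
harder.

Drift compensation corrects only the heading (rotation about the gravity
axis): pitch and roll are observable from the accelerometer, heading is the
axis that slowly drifts.  The estimated heading deviation of the final state
from a calibration reference is removed by an inverse rotation scaled by the
compensation strength and ramped linearly across the sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import lfilter

from .core import (
    FrameConvention,
    ImuSample,
    ImuStream,
    SensorNoiseModel,
    TrackerState,
    TrackerStates,
    heading_angle,
    quat_conj,
    quat_from_rotvec,
    quat_mul,
    quat_rotate,
)

__all__ = [
    "KalmanChannel",
    "FilterConfig",
    "kalman_predict",
    "kalman_update",
    "strength_to_qr",
    "filter_stream",
    "integrate_step",
    "integrate_stream",
    "drift_compensate",
]


# ---------------------------------------------------------------------------
# Scalar Kalman filter
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KalmanChannel:
    """Scalar Kalman filter state for one sensor channel."""

    x_hat: float = 0.0  # state estimate
    p: float = 1.0  # estimate variance
    a: float = 1.0  # state transition
    b: float = 0.0  # control gain
    u: float = 0.0  # control input
    h: float = 1.0  # observation scalar
    q: float = 0.0  # process-noise variance
    r: float = 0.0  # measurement-noise variance

    def __post_init__(self):
        if self.p < 0 or self.q < 0 or self.r < 0:
            raise ValueError("variances must be >= 0")


def kalman_predict(ch: KalmanChannel) -> KalmanChannel:
    """Time update: x⁻ = a·x + b·u, p⁻ = a·p·a + q."""
    x_prior = ch.a * ch.x_hat + ch.b * ch.u
    p_prior = ch.a * ch.p * ch.a + ch.q
    return replace(ch, x_hat=x_prior, p=p_prior)


def kalman_update(ch: KalmanChannel, z: float) -> KalmanChannel:
    """Measurement update with gain k = p⁻h / (h p⁻ h + r)."""
    denom = ch.h * ch.p * ch.h + ch.r
    if denom == 0.0:
        raise ZeroDivisionError("degenerate Kalman gain: h·p⁻·h + r = 0")
    k = ch.p * ch.h / denom
    x_post = ch.x_hat + k * (z - ch.h * ch.x_hat)
    p_post = (1.0 - ch.h * k) * ch.p
    return replace(ch, x_hat=x_post, p=p_post)


@dataclass(frozen=True)
class FilterConfig:
    filtering_strength: float = 0.5
    drift_compensation_strength: float = 0.2

    def __post_init__(self):
        for name in ("filtering_strength", "drift_compensation_strength"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")


def strength_to_qr(strength: float) -> tuple[float, float]:
    """Map filtering strength s to (q, r) with steady-state gain K∞ = 1 - s.

    With the random-walk channel model the Riccati fixed point gives
    p⁻∞ = q / K∞ and r = q (1 - K∞) / K∞²; q is fixed at 1 (only the
    ratio r/q matters for the gain sequence).
    """
    if not (0.0 <= strength <= 1.0):
        raise ValueError("strength must be in [0, 1]")
    k_inf = 1.0 - strength
    if k_inf <= 0.0:
        # full smoothing: measurement carries no weight
        return 1.0, np.inf
    q = 1.0
    r = q * (1.0 - k_inf) / (k_inf * k_inf)
    return q, r


def riccati_fixed_point(q: float, r: float) -> float:
    """Posterior steady-state variance p∞ = (-q + sqrt(q² + 4qr)) / 2."""
    return (-q + np.sqrt(q * q + 4.0 * q * r)) / 2.0


def _gain_sequence(n: int, q: float, r: float, p0: float) -> np.ndarray:
    """Exact time-varying Kalman gain sequence for the random-walk model."""
    k = np.empty(n)
    p = p0
    k_prev = np.nan
    for i in range(n):
        p_prior = p + q
        ki = p_prior / (p_prior + r) if np.isfinite(r) else 0.0
        k[i] = ki
        p = (1.0 - ki) * p_prior
        if k_prev == ki:  # converged to fixed point exactly (float)
            k[i:] = ki
            break
        k_prev = ki
    return k


def filter_stream(stream: ImuStream, cfg: FilterConfig) -> ImuStream:
    """Kalman-filter all six channels of a stream independently.

    The state estimate is initialised at the first measurement with prior
    variance r (so the first update has gain close to the steady state
    rather than blindly trusting the first sample).
    """
    if len(stream) == 0:
        raise ValueError("empty stream")
    s = cfg.filtering_strength
    if s == 0.0:
        return ImuStream(stream.t.copy(), stream.accel.copy(), stream.gyro.copy(), stream.tracker_id)

    q, r = strength_to_qr(s)
    z = np.hstack([stream.accel, stream.gyro])  # (n, 6)
    n = len(stream)
    if not np.isfinite(r):
        out = np.repeat(z[:1], n, axis=0)  # gain 0: hold the initial estimate
    else:
        k = _gain_sequence(n, q, r, p0=r)
        out = np.empty_like(z)
        x = z[0].copy()
        # run the exact recursion until the gain converges, then apply the
        # steady-state IIR form with lfilter for the remaining samples
        i_conv = n
        for i in range(n):
            x = x + k[i] * (z[i] - x)
            out[i] = x
            if i + 1 < n and k[i + 1] == k[i]:
                i_conv = i + 1
                break
        if i_conv < n:
            kc = k[i_conv]
            bq, aq = [kc], [1.0, -(1.0 - kc)]
            zi = (1.0 - kc) * out[i_conv - 1]
            for j in range(6):
                out[i_conv:, j], _ = lfilter(bq, aq, z[i_conv:, j], zi=[zi[j]])
    return ImuStream(stream.t.copy(), out[:, :3], out[:, 3:], stream.tracker_id)


# ---------------------------------------------------------------------------
# Strapdown integration
# ---------------------------------------------------------------------------

def _world_accel(q, accel, bias, frame: FrameConvention):
    """Gravity-free world acceleration from a specific-force sample."""
    return quat_rotate(q, accel - bias) - frame.rest_specific_force


def integrate_step(
    state: TrackerState,
    s_t: ImuSample,
    s_t1: ImuSample,
    noise: SensorNoiseModel | None = None,
    frame: FrameConvention | None = None,
) -> TrackerState:
    """Advance one tracker state across one sample interval.

    Order of operations: remove accelerometer bias, rotate to world frame and
    subtract the gravity reaction; average consecutive angular rates minus
    gyro bias; advance the quaternion by the rotation-vector increment;
    recompute the world acceleration at t+1 with the advanced quaternion;
    trapezoid-average both accelerations; advance velocity and displacement.
    """
    noise = noise or SensorNoiseModel()
    frame = frame or FrameConvention()
    dt = s_t1.t - s_t.t
    if dt <= 0:
        raise ValueError("non-monotone timestamps")
    if dt > 0.1:
        raise ValueError(f"sample gap {dt:.3f}s exceeds 0.1 s")
    if abs(np.linalg.norm(state.q) - 1.0) > 1e-6:
        raise ValueError("state quaternion must be unit norm")

    b_a = np.asarray(noise.accel_bias, dtype=float)
    b_g = np.asarray(noise.gyro_bias, dtype=float)

    a_w_t = _world_accel(state.q, np.asarray(s_t.accel, float), b_a, frame)
    omega_bar = 0.5 * (np.asarray(s_t.gyro, float) + np.asarray(s_t1.gyro, float)) - b_g
    q_next = quat_mul(state.q, quat_from_rotvec(omega_bar * dt))
    a_w_t1 = _world_accel(q_next, np.asarray(s_t1.accel, float), b_a, frame)
    a_bar = 0.5 * (a_w_t + a_w_t1)
    v_next = state.v + a_bar * dt
    d_next = state.d + state.v * dt + 0.5 * a_bar * dt * dt
    return TrackerState(q=q_next, v=v_next, d=d_next, t=s_t1.t)


def integrate_stream(
    stream: ImuStream,
    initial: TrackerState,
    noise: SensorNoiseModel | None = None,
    frame: FrameConvention | None = None,
) -> TrackerStates:
    """Fold :func:`integrate_step` over consecutive sample pairs.

    Output length equals input length; the first state is ``initial`` stamped
    with the first sample time.  The loop body is an inlined scalar version
    of :func:`integrate_step` (identical arithmetic) for speed on long
    streams.
    """
    if len(stream) < 2:
        raise ValueError("need at least 2 samples to integrate")
    noise = noise or SensorNoiseModel()
    frame = frame or FrameConvention()
    initial.validate()

    n = len(stream)
    t = stream.t
    dts = np.diff(t)
    if np.any(dts <= 0):
        raise ValueError("non-monotone timestamps")
    if np.any(dts > 0.1):
        raise ValueError("sample gap exceeds 0.1 s")

    b_a = np.asarray(noise.accel_bias, dtype=float)
    b_g = np.asarray(noise.gyro_bias, dtype=float)
    rest = frame.rest_specific_force

    acc = (stream.accel - b_a).tolist()
    # average angular velocity increments per Eq-pairing, bias removed
    om = (0.5 * (stream.gyro[:-1] + stream.gyro[1:]) - b_g)
    rot = (om * dts[:, None]).tolist()
    dts_l = dts.tolist()
    rx0, ry0, rz0 = rest.tolist()

    Q = np.empty((n, 4))
    V = np.empty((n, 3))
    D = np.empty((n, 3))
    qw, qx, qy, qz = (float(c) for c in initial.q)
    vx, vy, vz = (float(c) for c in initial.v)
    dx, dy, dz = (float(c) for c in initial.d)
    Q[0] = (qw, qx, qy, qz)
    V[0] = (vx, vy, vz)
    D[0] = (dx, dy, dz)

    def rot_vec(qw, qx, qy, qz, x, y, z):
        # q v q*: v + 2 w (u x v) + 2 u x (u x v)
        cx = qy * z - qz * y
        cy = qz * x - qx * z
        cz = qx * y - qy * x
        dx_ = qy * cz - qz * cy
        dy_ = qz * cx - qx * cz
        dz_ = qx * cy - qy * cx
        return (x + 2.0 * (qw * cx + dx_),
                y + 2.0 * (qw * cy + dy_),
                z + 2.0 * (qw * cz + dz_))

    ax, ay, az = acc[0]
    awx, awy, awz = rot_vec(qw, qx, qy, qz, ax, ay, az)
    awx -= rx0; awy -= ry0; awz -= rz0

    import math

    for i in range(n - 1):
        dt = dts_l[i]
        # orientation increment
        rx, ry, rz = rot[i]
        theta = math.sqrt(rx * rx + ry * ry + rz * rz)
        if theta < 1e-12:
            pw, px, py, pz = 1.0, 0.5 * rx, 0.5 * ry, 0.5 * rz
        else:
            half = 0.5 * theta
            s = math.sin(half) / theta
            pw, px, py, pz = math.cos(half), s * rx, s * ry, s * rz
        nqw = qw * pw - qx * px - qy * py - qz * pz
        nqx = qw * px + qx * pw + qy * pz - qz * py
        nqy = qw * py - qx * pz + qy * pw + qz * px
        nqz = qw * pz + qx * py - qy * px + qz * pw
        norm = math.sqrt(nqw * nqw + nqx * nqx + nqy * nqy + nqz * nqz)
        qw, qx, qy, qz = nqw / norm, nqx / norm, nqy / norm, nqz / norm

        ax, ay, az = acc[i + 1]
        bwx, bwy, bwz = rot_vec(qw, qx, qy, qz, ax, ay, az)
        bwx -= rx0; bwy -= ry0; bwz -= rz0
        abx = 0.5 * (awx + bwx)
        aby = 0.5 * (awy + bwy)
        abz = 0.5 * (awz + bwz)
        dx += vx * dt + 0.5 * abx * dt * dt
        dy += vy * dt + 0.5 * aby * dt * dt
        dz += vz * dt + 0.5 * abz * dt * dt
        vx += abx * dt
        vy += aby * dt
        vz += abz * dt
        awx, awy, awz = bwx, bwy, bwz

        Q[i + 1] = (qw, qx, qy, qz)
        V[i + 1] = (vx, vy, vz)
        D[i + 1] = (dx, dy, dz)

    return TrackerStates(t=t.copy(), q=Q, v=V, d=D, tracker_id=stream.tracker_id)


# ---------------------------------------------------------------------------
# Drift compensation
# ---------------------------------------------------------------------------

def drift_compensate(
    states: TrackerStates,
    reference_q: np.ndarray,
    cfg: FilterConfig,
    frame: FrameConvention | None = None,
) -> TrackerStates:
    """Remove heading drift relative to a calibration reference orientation.

    The heading (twist about the gravity axis) of the final state relative to
    ``reference_q`` is estimated; the inverse heading rotation, scaled by the
    drift-compensation strength, is applied with a linear ramp from 0 at the
    first state to full correction at the last.  Velocity and displacement
    are rotated consistently.
    """
    frame = frame or FrameConvention()
    strength = cfg.drift_compensation_strength
    n = len(states)
    if strength == 0.0 or n == 0:
        return TrackerStates(states.t.copy(), states.q.copy(), states.v.copy(),
                             states.d.copy(), states.tracker_id)
    axis = frame.down / np.linalg.norm(frame.down)
    rel = quat_mul(states.q[-1], quat_conj(np.asarray(reference_q, float)))
    psi = float(heading_angle(rel, axis))
    ramp = np.linspace(0.0, 1.0, n) if n > 1 else np.ones(1)
    corr = (-strength * psi) * ramp
    rq = quat_from_rotvec(corr[:, None] * axis[None, :])
    q_new = quat_mul(rq, states.q)
    v_new = quat_rotate(rq, states.v)
    d_new = quat_rotate(rq, states.d)
    return TrackerStates(states.t.copy(), q_new, v_new, d_new, states.tracker_id)
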