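"""Synthetic session generator: scripted posture motions and a forward IMU
sensor model producing noisy six-tracker streams.

Motion model per posture class: slow random waypoint drift inside the class's
bend-angle ranges (a new waypoint every 2-5 s, minimum-jerk interpolation)
plus band-limited postural tremor (0.5° RMS, 1-4 Hz).  Trajectories are
clipped to the class ranges shrunk by a 10% margin so the rule classifier
agrees with the generating label on every in-task frame.

The forward sensor model inverts the strapdown integrator exactly: gyroscope
samples are chosen so that the integrator's averaged angular-rate increments
reproduce the frame-to-frame orientation deltas, and accelerometer samples so
that the trapezoid velocity/displacement recursion reproduces the tracker
positions, before white noise and constant biases are added.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .core import (
    ACCEL_FULL_SCALE_G,
    GRAVITY,
    GYRO_FULL_SCALE_DPS,
    TRACKER_IDS,
    FrameConvention,
    ImuStream,
    SensorNoiseModel,
    quat_conj,
    quat_mul,
    quat_rotate,
    quat_to_rotvec,
)
from .skeleton import (
    POSTURE_RANGES,
    UNCLASSIFIED,
    CalibrationResult,
    PostureFrame,
    Skeleton,
    bends_to_joint_rotvecs,
    fk_batch,
    tracker_world_pose,
)

__all__ = [
    "DEFAULT_SEED",
    "BEND_KEYS",
    "SessionScript",
    "MotionTrace",
    "default_session_script",
    "generate_posture_trajectory",
    "build_session",
    "imu_from_motion",
]

#: Default generation seed.
DEFAULT_SEED = 20240686

BEND_KEYS = ("torso", "hip_l", "hip_r", "knee_l", "knee_r")

#: Session protocol: ordered (task, duration ms).  Integer tasks are posture
#: labels; "preparation" and "break" produce standing-like excluded motion.
_SESSION_TASKS = (
    ("preparation", 60_000),
    (1, 121_800),
    (2, 123_250),
    (3, 116_550),
    (4, 140_600),
    ("break", 60_000),
    (5, 118_350),
    (6, 86_500),
    (7, 96_300),
)


@dataclass(frozen=True)
class SessionScript:
    tasks: tuple = _SESSION_TASKS
    sample_rate: float = 100.0

    def __post_init__(self):
        for task, dur in self.tasks:
            if dur <= 0:
                raise ValueError("task durations must be > 0")
            if not (task in ("preparation", "break") or task in POSTURE_RANGES):
                raise ValueError(f"unknown task {task!r}")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be > 0")


def default_session_script() -> SessionScript:
    """The published session protocol (seven tasks plus preparation/break)."""
    return SessionScript()


@dataclass
class MotionTrace:
    """Bend-angle time series [deg] with per-frame posture labels.

    ``labels`` uses 1-7 for posture classes and 0 (:data:`UNCLASSIFIED`) for
    excluded periods (preparation, breaks, transitions, task fringes).
    """

    t: np.ndarray  # (n,) seconds
    bends: dict  # key in BEND_KEYS -> (n,) degrees
    labels: np.ndarray  # (n,) int
    rate: float = 100.0

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        n = len(self.t)
        for k in BEND_KEYS:
            self.bends[k] = np.asarray(self.bends[k], dtype=float)
            if len(self.bends[k]) != n:
                raise ValueError("bend series length mismatch")
        if len(self.labels) != n:
            raise ValueError("labels length mismatch")

    def __len__(self) -> int:
        return len(self.t)

    def joint_rotvecs(self) -> dict:
        b = self.bends
        return bends_to_joint_rotvecs(
            b["torso"], b["hip_l"], b["hip_r"], b["knee_l"], b["knee_r"]
        )

    def posture_frames(self) -> list:
        rot = self.joint_rotvecs()
        frames = []
        for i in range(len(self)):
            frames.append(
                PostureFrame(
                    t=float(self.t[i]),
                    joint_angles={j: rot[j][i] for j in rot},
                    torso_bend=float(self.bends["torso"][i]),
                    hip_bend_l=float(self.bends["hip_l"][i]),
                    hip_bend_r=float(self.bends["hip_r"][i]),
                    knee_bend_l=float(self.bends["knee_l"][i]),
                    knee_bend_r=float(self.bends["knee_r"][i]),
                )
            )
        return frames

    @staticmethod
    def concatenate(traces: list) -> "MotionTrace":
        rate = traces[0].rate
        n_total = sum(len(tr) for tr in traces)
        t = np.arange(n_total) / rate
        bends = {k: np.concatenate([tr.bends[k] for tr in traces]) for k in BEND_KEYS}
        labels = np.concatenate([tr.labels for tr in traces])
        return MotionTrace(t=t, bends=bends, labels=labels, rate=rate)


# ---------------------------------------------------------------------------
# Trajectory generation
# ---------------------------------------------------------------------------

def _min_jerk(u: np.ndarray) -> np.ndarray:
    """Minimum-jerk interpolation profile on [0, 1]."""
    return u ** 3 * (10.0 - 15.0 * u + 6.0 * u * u)


def _shrunk_range(lo: float, hi: float, margin: float) -> tuple[float, float]:
    span = hi - lo
    return lo + margin * span, hi - margin * span


def _waypoint_track(rng, n: int, rate: float, lo: float, hi: float,
                    start: float | None) -> np.ndarray:
    """Piecewise minimum-jerk drift between random waypoints in [lo, hi]."""
    duration = n / rate
    times = [0.0]
    while times[-1] < duration:
        times.append(times[-1] + rng.uniform(2.0, 5.0))
    values = rng.uniform(lo, hi, size=len(times))
    if start is not None:
        values[0] = start
    t = np.arange(n) / rate
    idx = np.clip(np.searchsorted(times, t, side="right") - 1, 0, len(times) - 2)
    t0 = np.asarray(times)[idx]
    t1 = np.asarray(times)[idx + 1]
    u = _min_jerk((t - t0) / (t1 - t0))
    return values[idx] * (1.0 - u) + values[idx + 1] * u


def _tremor(rng, n: int, rate: float, rms_deg: float = 0.5,
            band: tuple[float, float] = (1.0, 4.0)) -> np.ndarray:
    """Band-limited postural tremor with the requested RMS amplitude."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / rate)
    mask = (freqs >= band[0]) & (freqs <= band[1])
    spec[~mask] = 0.0
    sig = np.fft.irfft(spec, n=n)
    rms = np.sqrt(np.mean(sig ** 2))
    if rms == 0:
        return np.zeros(n)
    return sig * (rms_deg / rms)


def generate_posture_trajectory(
    label: int,
    duration: float,
    rate: float = 100.0,
    seed=None,
    margin: float = 0.1,
    start_bends: dict | None = None,
    as_label: int | None = None,
) -> MotionTrace:
    """Random in-class motion for one posture label.

    ``start_bends`` (deg per BEND_KEYS entry) pins the first frame exactly
    (tremor is ramped in over the first second).  ``as_label`` overrides the
    emitted label (used for excluded standing-like segments).
    """
    if label not in POSTURE_RANGES:
        raise ValueError(f"invalid posture label {label}")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n = int(round(duration * rate))
    (tlo, thi), (hlo, hhi), (klo, khi) = POSTURE_RANGES[label]
    out_label = label if as_label is None else as_label

    bends = {}
    ranges = {"torso": (tlo, thi), "hip_l": (hlo, hhi), "hip_r": (hlo, hhi),
              "knee_l": (klo, khi), "knee_r": (klo, khi)}
    ramp = None
    if start_bends is not None:
        n_ramp = min(n, int(rate))
        ramp = np.ones(n)
        ramp[:n_ramp] = _min_jerk(np.arange(n_ramp) / max(n_ramp, 1))
    for key in BEND_KEYS:
        lo_s, hi_s = _shrunk_range(*ranges[key], margin)
        head = min(2.0, 0.25 * (hi_s - lo_s))
        start = start_bends.get(key) if start_bends is not None else None
        track = _waypoint_track(rng, n, rate, lo_s + head, hi_s - head, start)
        trem = _tremor(rng, n, rate)
        if ramp is not None:
            trem = trem * ramp
        sig = np.clip(track + trem, lo_s, np.nextafter(hi_s, lo_s))
        bends[key] = sig

    return MotionTrace(
        t=np.arange(n) / rate,
        bends=bends,
        labels=np.full(n, out_label, dtype=np.int64),
        rate=rate,
    )


def _blend_trace(bends_a: dict, bends_b: dict, duration: float, rate: float) -> MotionTrace:
    """Excluded minimum-jerk transition from one pose to another."""
    n = int(round(duration * rate))
    u = _min_jerk(np.arange(1, n + 1) / (n + 1))
    bends = {k: bends_a[k] * (1.0 - u) + bends_b[k] * u for k in BEND_KEYS}
    return MotionTrace(
        t=np.arange(n) / rate,
        bends=bends,
        labels=np.full(n, UNCLASSIFIED, dtype=np.int64),
        rate=rate,
    )


def build_session(
    script: SessionScript,
    seed=DEFAULT_SEED,
    transition_s: float = 2.0,
    exclude_s: float = 2.0,
) -> MotionTrace:
    """Concatenate per-task trajectories into one labeled session.

    Consecutive tasks are joined by ``transition_s`` minimum-jerk blends
    labeled excluded; the first and last ``exclude_s`` of every labeled task
    are also excluded (settling fringes).  The session starts at the exact
    neutral pose so downstream integration can assume a calibrated standing
    start.
    """
    rate = script.sample_rate
    ss = np.random.SeedSequence(seed)
    child_rngs = [np.random.default_rng(s) for s in ss.spawn(len(script.tasks))]

    pieces = []
    prev_end = None
    n_excl = int(round(exclude_s * rate))
    for i, (task, dur_ms) in enumerate(script.tasks):
        dur = dur_ms / 1000.0
        gen_label = 1 if task in ("preparation", "break") else int(task)
        out_label = UNCLASSIFIED if task in ("preparation", "break") else int(task)
        start = {k: 0.0 for k in BEND_KEYS} if i == 0 else None
        trace = generate_posture_trajectory(
            gen_label, dur, rate=rate, seed=child_rngs[i],
            start_bends=start, as_label=out_label,
        )
        if out_label != UNCLASSIFIED and n_excl > 0:
            trace.labels[:n_excl] = UNCLASSIFIED
            trace.labels[-n_excl:] = UNCLASSIFIED
        if prev_end is not None and transition_s > 0:
            start_bends = {k: trace.bends[k][0] for k in BEND_KEYS}
            pieces.append(_blend_trace(prev_end, start_bends, transition_s, rate))
        pieces.append(trace)
        prev_end = {k: trace.bends[k][-1] for k in BEND_KEYS}

    return MotionTrace.concatenate(pieces)


# ---------------------------------------------------------------------------
# Forward sensor model
# ---------------------------------------------------------------------------

def _alternating_recursion(x0: np.ndarray, d: np.ndarray) -> np.ndarray:
    """Solve x_{i+1} = 2 d_i - x_i for i = 0..m-1 given x_0 (vectorized).

    Returns the full (m+1, k) sequence.  Substituting s_i = (-1)^i x_i turns
    the recursion into a cumulative sum.  The recursion inverts a two-tap
    average, which is marginally stable: any multiple of (-1)^i is a
    homogeneous solution, so the Nyquist-mode amplitude excited by the
    initial condition is estimated against the (smooth) targets d and
    subtracted — the corrected sequence still satisfies the recursion
    exactly.
    """
    m = len(d)
    sign = (-1.0) ** np.arange(1, m + 1)
    s = x0[None, :] + np.cumsum(2.0 * sign[:, None] * d, axis=0)
    x = np.vstack([x0[None, :], s * sign[:, None]])
    alt = np.concatenate([[1.0], sign])
    c = np.mean(alt[:m, None] * (x[:m] - d), axis=0)
    return x - c[None, :] * alt[:, None]


def imu_from_motion(
    trace: MotionTrace,
    sk: Skeleton,
    cal: CalibrationResult | None = None,
    noise: SensorNoiseModel | None = None,
    frame: FrameConvention | None = None,
    seed=DEFAULT_SEED,
) -> dict:
    """Six noisy IMU streams consistent with a motion trace.

    Noiseless streams round-trip through the strapdown integrator:
    orientations are reproduced to machine precision (the gyro samples invert
    the integrator's averaged increments exactly) and positions to O(dt²)
    with no secular drift from rest.
    """
    if len(trace) < 3:
        raise ValueError("trace must have at least 3 frames")
    cal = cal or CalibrationResult.identity()
    noise = noise or SensorNoiseModel()
    frame = frame or FrameConvention()
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    dt = 1.0 / trace.rate
    rot = trace.joint_rotvecs()
    fk = fk_batch(sk, rot)
    rest = frame.rest_specific_force
    b_a = np.asarray(noise.accel_bias, dtype=float)
    b_g = np.asarray(noise.gyro_bias, dtype=float)
    a_full = ACCEL_FULL_SCALE_G * GRAVITY
    g_full = np.deg2rad(GYRO_FULL_SCALE_DPS)

    streams = {}
    for tr in TRACKER_IDS:
        pos_mm, seg_q = tracker_world_pose(sk, fk, tr)
        q = quat_mul(seg_q, quat_conj(cal.mounting_q[tr])[None, :])
        p = pos_mm / 1000.0  # m

        # gyroscope: averaged body-frame rates matching the quaternion deltas
        d_rot = quat_to_rotvec(quat_mul(quat_conj(q[:-1]), q[1:])) / dt
        omega = _alternating_recursion(d_rot[0], d_rot)

        # accelerometer: second central differences of the tracker position.
        # (An exact inversion of the trapezoid recursion would resonate at
        # Nyquist over long sessions; the smooth estimate keeps the
        # integrator's velocity consistent to O(dt²) with no secular drift.)
        a_w = np.empty_like(p)
        a_w[1:-1] = (p[2:] - 2.0 * p[1:-1] + p[:-2]) / (dt * dt)
        a_w[0] = a_w[1]
        a_w[-1] = a_w[-2]
        f_body = quat_rotate(quat_conj(q), a_w + rest) + b_a

        accel = f_body + rng.normal(0.0, noise.accel_sigma, size=f_body.shape)
        gyro = omega + b_g + rng.normal(0.0, noise.gyro_sigma, size=omega.shape)

        if np.any(np.abs(accel) > a_full) or np.any(np.abs(gyro) > g_full):
            warnings.warn(
                f"tracker {tr}: generated samples exceed sensor full scale; clipping",
                RuntimeWarning,
                stacklevel=2,
            )
            accel = np.clip(accel, -a_full, a_full)
            gyro = np.clip(gyro, -g_full, g_full)

        streams[tr] = ImuStream(t=trace.t.copy(), accel=accel, gyro=gyro, tracker_id=tr)
    return streams
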