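"""Shared domain types, unit/frame conventions, and quaternion primitives.

Conventions
-----------
* Quaternions are scalar-first ``(w, x, y, z)`` unit arrays using the Hamilton
  product.  Applied as ``q v q*`` they rotate body-frame vectors into the
  world frame.
* The world frame coincides with the tracker body frame of an upright,
  calibrated subject: **Y points down** (along gravity), **Z points forward**,
  and X completes a right-handed triad (pointing to the subject's right).
* Internal units are SI throughout (m, m/s, m/s², rad, rad/s); degrees and
  millimetres appear only at I/O boundaries.
* Accelerometer samples store *specific force*: a motionless tracker at
  identity orientation reads ``(0, -g, 0)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "TRACKER_IDS",
    "GRAVITY",
    "ImuSample",
    "ImuStream",
    "TrackerState",
    "TrackerStates",
    "SensorNoiseModel",
    "FrameConvention",
    "quat_identity",
    "quat_normalize",
    "quat_canonical",
    "quat_conj",
    "quat_mul",
    "quat_from_rotvec",
    "quat_to_rotvec",
    "quat_rotate",
    "heading_angle",
]

#: The six body-worn trackers.
TRACKER_IDS = ("chest", "waist", "l_knee", "l_ankle", "r_knee", "r_ankle")

#: Default gravitational acceleration magnitude [m/s²] (configurable via
#: :class:`FrameConvention`).
GRAVITY = 9.81

#: Accelerometer full scale [g] and gyroscope full scale [deg/s].
ACCEL_FULL_SCALE_G = 4.0
GYRO_FULL_SCALE_DPS = 250.0


# ---------------------------------------------------------------------------
# Quaternion primitives (vectorized over leading axes, scalar-first layout)
# ---------------------------------------------------------------------------

def quat_identity(shape: tuple[int, ...] = ()) -> np.ndarray:
    """Identity quaternion(s) with the given leading shape."""
    q = np.zeros(shape + (4,), dtype=float)
    q[..., 0] = 1.0
    return q


def quat_normalize(q: np.ndarray) -> np.ndarray:
    q = np.asarray(q, dtype=float)
    n = np.linalg.norm(q, axis=-1, keepdims=True)
    if np.any(n == 0):
        raise ValueError("cannot normalize zero quaternion")
    return q / n


def quat_canonical(q: np.ndarray) -> np.ndarray:
    """Resolve the double cover: flip sign so that w >= 0."""
    q = np.asarray(q, dtype=float)
    sign = np.where(q[..., :1] < 0, -1.0, 1.0)
    return q * sign


def quat_conj(q: np.ndarray) -> np.ndarray:
    q = np.asarray(q, dtype=float)
    return q * np.array([1.0, -1.0, -1.0, -1.0])


def quat_mul(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Hamilton product ``a ⊗ b``, renormalized."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    aw, ax, ay, az = (a[..., i] for i in range(4))
    bw, bx, by, bz = (b[..., i] for i in range(4))
    out = np.empty(np.broadcast(aw, bw).shape + (4,), dtype=float)
    out[..., 0] = aw * bw - ax * bx - ay * by - az * bz
    out[..., 1] = aw * bx + ax * bw + ay * bz - az * by
    out[..., 2] = aw * by - ax * bz + ay * bw + az * bx
    out[..., 3] = aw * bz + ax * by - ay * bx + az * bw
    return quat_normalize(out)


def quat_from_rotvec(v: np.ndarray) -> np.ndarray:
    """Exponential map: rotation vector [rad] -> unit quaternion.

    For |v| below 1e-12 the first-order expansion ``(1, v/2)`` is used.
    """
    v = np.asarray(v, dtype=float)
    theta = np.linalg.norm(v, axis=-1, keepdims=True)
    small = theta < 1e-12
    # avoid 0/0; the small branch overwrites these lanes
    safe = np.where(small, 1.0, theta)
    axis = v / safe
    half = theta / 2.0
    q = np.concatenate([np.cos(half), np.sin(half) * axis], axis=-1)
    q_small = np.concatenate([np.ones_like(half), v / 2.0], axis=-1)
    return quat_normalize(np.where(small, q_small, q))


def quat_to_rotvec(q: np.ndarray) -> np.ndarray:
    """Logarithmic map: unit quaternion -> rotation vector [rad], |v| <= pi."""
    q = quat_canonical(quat_normalize(q))
    w = np.clip(q[..., :1], -1.0, 1.0)
    xyz = q[..., 1:]
    s = np.linalg.norm(xyz, axis=-1, keepdims=True)
    theta = 2.0 * np.arctan2(s, w)
    small = s < 1e-12
    safe = np.where(small, 1.0, s)
    return np.where(small, 2.0 * xyz, theta * xyz / safe)


def quat_rotate(q: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Rotate vector(s) v by quaternion(s) q (body -> world for pose quats)."""
    q = np.asarray(q, dtype=float)
    v = np.asarray(v, dtype=float)
    w = q[..., :1]
    u = q[..., 1:]
    # q v q* expanded: v + 2 w (u x v) + 2 u x (u x v)
    uv = np.cross(u, v)
    return v + 2.0 * (w * uv + np.cross(u, uv))


def heading_angle(q: np.ndarray, axis: np.ndarray) -> np.ndarray:
    """Twist angle [rad] of q about the given world axis (swing-twist split).

    Positive per the right-hand rule about ``axis``; result in (-pi, pi].
    """
    q = quat_normalize(q)
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    proj = np.sum(q[..., 1:] * axis, axis=-1)
    return 2.0 * np.arctan2(proj, q[..., 0])


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FrameConvention:
    """World frame definition.

    ``gravity_vector`` points along gravity (down) in world coordinates;
    with the default axes that is +Y.  ``rest_specific_force`` is what a
    motionless, identity-oriented accelerometer reads.
    """

    gravity_vector: np.ndarray = field(
        default_factory=lambda: np.array([0.0, GRAVITY, 0.0])
    )
    world_axes: dict = field(
        default_factory=lambda: {
            "down": np.array([0.0, 1.0, 0.0]),
            "forward": np.array([0.0, 0.0, 1.0]),
            "right": np.array([1.0, 0.0, 0.0]),
        }
    )

    def __post_init__(self):
        g = np.linalg.norm(np.asarray(self.gravity_vector, dtype=float))
        if not (9.80 - 0.01 <= g <= 9.82 + 0.01):
            # allow explicit zero-gravity setups for inertial-coasting tests
            if g != 0.0:
                raise ValueError(f"|gravity_vector| = {g:.4f}, expected ~9.81 m/s²")

    @property
    def down(self) -> np.ndarray:
        return np.asarray(self.world_axes["down"], dtype=float)

    @property
    def forward(self) -> np.ndarray:
        return np.asarray(self.world_axes["forward"], dtype=float)

    @property
    def right(self) -> np.ndarray:
        return np.asarray(self.world_axes["right"], dtype=float)

    @property
    def rest_specific_force(self) -> np.ndarray:
        """Specific force read by a motionless sensor at identity orientation."""
        return -np.asarray(self.gravity_vector, dtype=float)


@dataclass(frozen=True)
class SensorNoiseModel:
    """White-noise + constant-bias sensor model.

    ``accel_noise_density`` in µg/√Hz, ``gyro_noise_density`` in °/s/√Hz;
    per-sample standard deviation = density × √(sample_rate / 2).
    """

    accel_noise_density: float = 300.0
    gyro_noise_density: float = 0.007
    accel_bias: np.ndarray = field(default_factory=lambda: np.zeros(3))
    gyro_bias: np.ndarray = field(default_factory=lambda: np.zeros(3))
    sample_rate: float = 100.0

    def __post_init__(self):
        if self.accel_noise_density < 0 or self.gyro_noise_density < 0:
            raise ValueError("noise densities must be >= 0")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be > 0")

    @property
    def accel_sigma(self) -> float:
        """Per-sample accelerometer noise sigma [m/s²]."""
        return self.accel_noise_density * 1e-6 * GRAVITY * np.sqrt(self.sample_rate / 2.0)

    @property
    def gyro_sigma(self) -> float:
        """Per-sample gyroscope noise sigma [rad/s]."""
        return np.deg2rad(self.gyro_noise_density) * np.sqrt(self.sample_rate / 2.0)


@dataclass(frozen=True)
class ImuSample:
    """One body-frame IMU sample (specific force + angular rate)."""

    t: float
    accel: np.ndarray  # m/s², body frame, specific force
    gyro: np.ndarray  # rad/s, body frame
    tracker_id: str = "chest"


@dataclass
class ImuStream:
    """A per-tracker time series of IMU samples stored as columnar arrays."""

    t: np.ndarray  # (n,) seconds, strictly increasing
    accel: np.ndarray  # (n, 3) m/s²
    gyro: np.ndarray  # (n, 3) rad/s
    tracker_id: str = "chest"

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.accel = np.asarray(self.accel, dtype=float).reshape(-1, 3)
        self.gyro = np.asarray(self.gyro, dtype=float).reshape(-1, 3)
        if not (len(self.t) == len(self.accel) == len(self.gyro)):
            raise ValueError("t/accel/gyro length mismatch")

    def __len__(self) -> int:
        return len(self.t)

    def __getitem__(self, i: int) -> ImuSample:
        return ImuSample(float(self.t[i]), self.accel[i], self.gyro[i], self.tracker_id)

    def validate(self, frame: FrameConvention | None = None) -> None:
        """Check stream invariants (monotone time, sensor full-scale)."""
        if len(self.t) == 0:
            raise ValueError("empty stream")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        g = GRAVITY
        if np.any(np.abs(self.accel) > ACCEL_FULL_SCALE_G * g + 1e-9):
            raise ValueError("acceleration exceeds ±4 g full scale")
        if np.any(np.abs(self.gyro) > np.deg2rad(GYRO_FULL_SCALE_DPS) + 1e-12):
            raise ValueError("angular velocity exceeds ±250°/s full scale")
        if self.tracker_id not in TRACKER_IDS:
            raise ValueError(f"unknown tracker_id {self.tracker_id!r}")

    # -- I/O -----------------------------------------------------------------

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t": self.t,
                "ax": self.accel[:, 0],
                "ay": self.accel[:, 1],
                "az": self.accel[:, 2],
                "gx": self.gyro[:, 0],
                "gy": self.gyro[:, 1],
                "gz": self.gyro[:, 2],
                "tracker_id": self.tracker_id,
            }
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "ImuStream":
        ids = df["tracker_id"].unique()
        if len(ids) != 1:
            raise ValueError("one stream per tracker; got " + ", ".join(map(str, ids)))
        return cls(
            t=df["t"].to_numpy(float),
            accel=df[["ax", "ay", "az"]].to_numpy(float),
            gyro=df[["gx", "gy", "gz"]].to_numpy(float),
            tracker_id=str(ids[0]),
        )

    def write_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False, float_format="%.6f")

    @classmethod
    def read_csv(cls, path: str | Path) -> "ImuStream":
        return cls.from_dataframe(pd.read_csv(path))

    def write_jsonl(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for i in range(len(self)):
                rec = {
                    "t": round(float(self.t[i]), 6),
                    "ax": float(self.accel[i, 0]),
                    "ay": float(self.accel[i, 1]),
                    "az": float(self.accel[i, 2]),
                    "gx": float(self.gyro[i, 0]),
                    "gy": float(self.gyro[i, 1]),
                    "gz": float(self.gyro[i, 2]),
                    "tracker_id": self.tracker_id,
                }
                fh.write(json.dumps(rec) + "\n")

    @classmethod
    def read_jsonl(cls, path: str | Path) -> "ImuStream":
        rows = [json.loads(line) for line in open(path) if line.strip()]
        return cls.from_dataframe(pd.DataFrame(rows))


@dataclass(frozen=True)
class TrackerState:
    """World-frame pose of one tracker: orientation, velocity, displacement."""

    q: np.ndarray  # (4,) unit quaternion, world-from-body
    v: np.ndarray  # (3,) m/s
    d: np.ndarray  # (3,) m
    t: float = 0.0

    def __post_init__(self):
        object.__setattr__(self, "q", np.asarray(self.q, dtype=float))
        object.__setattr__(self, "v", np.asarray(self.v, dtype=float))
        object.__setattr__(self, "d", np.asarray(self.d, dtype=float))

    def validate(self) -> None:
        if abs(np.linalg.norm(self.q) - 1.0) > 1e-6:
            raise ValueError("state quaternion must be unit norm")
        if not np.all(np.isfinite(self.q)) or not np.all(np.isfinite(self.v)) or not np.all(np.isfinite(self.d)):
            raise ValueError("non-finite tracker state")


@dataclass
class TrackerStates:
    """A sequence of :class:`TrackerState` stored columnar for speed."""

    t: np.ndarray  # (n,)
    q: np.ndarray  # (n, 4)
    v: np.ndarray  # (n, 3)
    d: np.ndarray  # (n, 3)
    tracker_id: str = "chest"

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.q = np.asarray(self.q, dtype=float).reshape(-1, 4)
        self.v = np.asarray(self.v, dtype=float).reshape(-1, 3)
        self.d = np.asarray(self.d, dtype=float).reshape(-1, 3)

    def __len__(self) -> int:
        return len(self.t)

    def __getitem__(self, i: int) -> TrackerState:
        return TrackerState(self.q[i], self.v[i], self.d[i], float(self.t[i]))

    @classmethod
    def from_states(cls, states: list[TrackerState], tracker_id: str = "chest") -> "TrackerStates":
        return cls(
            t=np.array([s.t for s in states]),
            q=np.stack([s.q for s in states]),
            v=np.stack([s.v for s in states]),
            d=np.stack([s.d for s in states]),
            tracker_id=tracker_id,
        )

    def to_dataframe(self) -> pd.DataFrame:
        cols = {"t": self.t}
        for j, c in enumerate("wxyz"):
            cols[f"q{c}"] = self.q[:, j]
        for j, c in enumerate("xyz"):
            cols[f"v{c}"] = self.v[:, j]
        for j, c in enumerate("xyz"):
            cols[f"d{c}"] = self.d[:, j]
        cols["tracker_id"] = self.tracker_id
        return pd.DataFrame(cols)

    def write_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False, float_format="%.9f")

    @classmethod
    def read_csv(cls, path: str | Path) -> "TrackerStates":
        df = pd.read_csv(path)
        ids = df["tracker_id"].unique()
        if len(ids) != 1:
            raise ValueError("one state file per tracker")
        return cls(
            t=df["t"].to_numpy(float),
            q=df[["qw", "qx", "qy", "qz"]].to_numpy(float),
            v=df[["vx", "vy", "vz"]].to_numpy(float),
            d=df[["dx", "dy", "dz"]].to_numpy(float),
            tracker_id=str(ids[0]),
        )


def resample_uniform(stream: ImuStream, rate: float = 100.0, jitter_tol: float = 0.1) -> ImuStream:
    """Resample a stream to a uniform grid if timestamp jitter exceeds tolerance.

    Streams whose sample intervals are already within ``jitter_tol`` of
    ``1/rate`` are returned unchanged.
    """
    dt = np.diff(stream.t)
    if len(dt) == 0:
        return stream
    target = 1.0 / rate
    if np.all(np.abs(dt - target) <= jitter_tol * target):
        return stream
    t_new = np.arange(stream.t[0], stream.t[-1] + 0.5 * target, target)
    accel = np.column_stack([np.interp(t_new, stream.t, stream.accel[:, j]) for j in range(3)])
    gyro = np.column_stack([np.interp(t_new, stream.t, stream.gyro[:, j]) for j in range(3)])
    return ImuStream(t=t_new, accel=accel, gyro=gyro, tracker_id=stream.tracker_id)
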