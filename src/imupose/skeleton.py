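"""Hierarchical digital-human model: joint tree, segment lengths from subject
height, tracker-to-segment assignment, two-pose calibration, forward
kinematics, posture-angle extraction, rule-based posture labels, BVH export.

Joint tree (root first)::

    pelvis ── lumbar ── thoracic ── (chest end site)
       ├── l_hip ── l_knee ── l_ankle ── (foot end site)
       └── r_hip ── r_knee ── r_ankle ── (foot end site)

Rotational degrees of freedom: thoracic/lumbar/hip are 3-dof, the knee is a
single-axis hinge (pitch), the ankle a 2-axis ball joint (pitch + roll).

Bend-angle definitions (flexion positive, degrees):

* ``torso_bend`` — sagittal inclination of the chest segment's long axis
  from world up.
* ``hip_bend``  — sagittal angle between the trunk axis and the femur axis
  (torso inclination + femur inclination).
* ``knee_bend`` — sagittal angle between the femur extension and the tibia.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial.transform import Rotation

from .core import (
    TRACKER_IDS,
    TrackerState,
    quat_conj,
    quat_from_rotvec,
    quat_identity,
    quat_mul,
    quat_rotate,
    quat_to_rotvec,
)

__all__ = [
    "JOINTS",
    "PARENT",
    "DOF_AXES",
    "TRACKER_SEGMENT_NODE",
    "POSTURE_RANGES",
    "POSTURE_NAMES",
    "RULE_PRIORITY",
    "UNCLASSIFIED",
    "DRILLIS_CONTINI",
    "Skeleton",
    "PostureFrame",
    "CalibrationResult",
    "MisMountedTrackerError",
    "skeleton_from_height",
    "calibrate",
    "forward_kinematics",
    "fk_batch",
    "tracker_world_pose",
    "states_to_posture",
    "states_to_bends_batch",
    "bends_to_joint_rotvecs",
    "segment_orientations_to_bends",
    "classify_by_rules",
    "classify_bends",
    "export_bvh",
    "read_bvh",
]

JOINTS = ("pelvis", "lumbar", "thoracic", "l_hip", "l_knee", "l_ankle",
          "r_hip", "r_knee", "r_ankle")

PARENT = {
    "pelvis": None,
    "lumbar": "pelvis",
    "thoracic": "lumbar",
    "l_hip": "pelvis",
    "l_knee": "l_hip",
    "l_ankle": "l_knee",
    "r_hip": "pelvis",
    "r_knee": "r_hip",
    "r_ankle": "r_knee",
}

#: Per-joint free rotation axes (indices into xyz): 3-dof joints are free,
#: the knee is a pitch hinge, the ankle pitch + roll.
DOF_AXES = {
    "pelvis": (0, 1, 2),
    "lumbar": (0, 1, 2),
    "thoracic": (0, 1, 2),
    "l_hip": (0, 1, 2),
    "r_hip": (0, 1, 2),
    "l_knee": (0,),
    "r_knee": (0,),
    "l_ankle": (0, 2),
    "r_ankle": (0, 2),
}

#: FK node whose orientation carries each tracker's segment: knee trackers
#: ride the femur (the hip node's child bone), ankle trackers the tibia.
TRACKER_SEGMENT_NODE = {
    "chest": "thoracic",
    "waist": "pelvis",
    "l_knee": "l_hip",
    "l_ankle": "l_knee",
    "r_knee": "r_hip",
    "r_ankle": "r_knee",
}

#: Standard anthropometric segment ratios (fraction of stature).
DRILLIS_CONTINI = {
    "pelvis_to_lumbar": 0.050,
    "lumbar_to_thoracic": 0.238,
    "chest": 0.100,  # thoracic joint -> chest end site
    "hip_halfwidth": 0.0955,
    "femur": 0.245,
    "tibia": 0.246,
    "foot": 0.039,  # ankle -> floor end site
}

#: Posture taxonomy: label -> (torso, hip, knee) bend-angle ranges [deg],
#: closed on the left, open on the right.
POSTURE_RANGES = {
    1: ((-15.0, 15.0), (-17.0, 5.0), (-3.0, 5.0)),
    2: ((15.0, 40.0), (5.0, 50.0), (5.0, 60.0)),
    3: ((40.0, 84.0), (70.0, 116.0), (5.0, 70.0)),
    4: ((15.0, 40.0), (50.0, 116.0), (60.0, 100.0)),
    5: ((15.0, 40.0), (50.0, 116.0), (100.0, 150.0)),
    6: ((-15.0, 15.0), (30.0, 70.0), (-3.0, 5.0)),
    7: ((-5.0, 40.0), (50.0, 100.0), (5.0, 60.0)),
}

POSTURE_NAMES = {
    1: "standing",
    2: "slightly bending",
    3: "deep bending",
    4: "half squatting",
    5: "squatting",
    6: "sitting",
    7: "supine",
}

#: Most-specific-first matching order (overlapping ranges are resolved
#: deterministically).
RULE_PRIORITY = (7, 5, 4, 3, 6, 2, 1)

#: Label used for frames matching no posture class (and excluded periods).
UNCLASSIFIED = 0


# ---------------------------------------------------------------------------
# Skeleton
# ---------------------------------------------------------------------------

class MisMountedTrackerError(ValueError):
    """Raised when the ski-pose calibration check fails for a tracker."""

    def __init__(self, trackers):
        self.trackers = tuple(trackers)
        super().__init__(
            "ski-pose pitch check failed for tracker(s): " + ", ".join(self.trackers)
        )


@dataclass
class Skeleton:
    """Joint hierarchy with neutral bone offsets in mm (parent frame)."""

    subject_height: float  # mm
    offsets: dict  # joint -> (3,) mm offset from parent joint, neutral pose
    end_sites: dict  # node -> (3,) mm
    tracker_map: dict = field(default_factory=lambda: dict(TRACKER_SEGMENT_NODE))

    def __post_init__(self):
        for j in JOINTS:
            if j != "pelvis" and j not in self.offsets:
                raise ValueError(f"missing offset for joint {j}")
        for j, off in self.offsets.items():
            if j != "pelvis" and np.linalg.norm(off) <= 0:
                raise ValueError(f"segment length for {j} must be > 0")

    @property
    def segment_lengths(self) -> dict:
        """Bone lengths [mm], keyed by the child joint the bone ends at."""
        return {j: float(np.linalg.norm(self.offsets[j])) for j in JOINTS if j != "pelvis"}

    def bone_vector(self, joint: str) -> np.ndarray:
        return np.asarray(self.offsets[joint], dtype=float)


def skeleton_from_height(height: float, proportions: dict | None = None) -> Skeleton:
    """Build a skeleton from subject stature [mm] and segment ratios."""
    if not (1000.0 <= height <= 2500.0):
        raise ValueError(f"height {height} mm outside supported range [1000, 2500]")
    p = dict(DRILLIS_CONTINI)
    if proportions:
        p.update(proportions)
    h = float(height)
    up = np.array([0.0, -1.0, 0.0])  # world up = -Y
    down = -up
    offsets = {
        "pelvis": np.zeros(3),
        "lumbar": up * (p["pelvis_to_lumbar"] * h),
        "thoracic": up * (p["lumbar_to_thoracic"] * h),
        "l_hip": np.array([-p["hip_halfwidth"] * h, 0.0, 0.0]),
        "r_hip": np.array([p["hip_halfwidth"] * h, 0.0, 0.0]),
        "l_knee": down * (p["femur"] * h),
        "r_knee": down * (p["femur"] * h),
        "l_ankle": down * (p["tibia"] * h),
        "r_ankle": down * (p["tibia"] * h),
    }
    end_sites = {
        "thoracic": up * (p["chest"] * h),
        "l_ankle": down * (p["foot"] * h),
        "r_ankle": down * (p["foot"] * h),
    }
    return Skeleton(subject_height=h, offsets=offsets, end_sites=end_sites)


# ---------------------------------------------------------------------------
# Posture frames
# ---------------------------------------------------------------------------

@dataclass
class PostureFrame:
    """Per-frame joint rotation vectors [rad] plus derived bend angles [deg]."""

    t: float
    joint_angles: dict  # joint -> (3,) rotation vector, rad
    torso_bend: float = 0.0
    hip_bend_l: float = 0.0
    hip_bend_r: float = 0.0
    knee_bend_l: float = 0.0
    knee_bend_r: float = 0.0

    def __post_init__(self):
        for j in JOINTS:
            v = np.asarray(self.joint_angles.get(j, np.zeros(3)), dtype=float)
            self.joint_angles[j] = v
        self.validate()

    def validate(self) -> None:
        for j, v in self.joint_angles.items():
            if np.any(~np.isfinite(v)):
                raise ValueError(f"non-finite angles at joint {j}")
            free = DOF_AXES[j]
            locked = [k for k in range(3) if k not in free]
            if locked and np.any(np.abs(v[locked]) > 1e-9):
                raise ValueError(f"joint {j} rotation violates its dof axes")
        for name in ("torso_bend", "hip_bend_l", "hip_bend_r", "knee_bend_l", "knee_bend_r"):
            a = getattr(self, name)
            if not (-180.0 <= a <= 180.0):
                raise ValueError(f"{name} = {a} outside [-180, 180] deg")

    @property
    def hip_bend(self) -> float:
        return max(self.hip_bend_l, self.hip_bend_r)

    @property
    def knee_bend(self) -> float:
        return max(self.knee_bend_l, self.knee_bend_r)


def bends_to_joint_rotvecs(torso, hip_l, hip_r, knee_l, knee_r):
    """Map bend angles [deg] to per-joint rotation vectors [rad].

    All inputs broadcast; returns dict joint -> (..., 3) rotvec.  The inverse
    of :func:`segment_orientations_to_bends` for sagittal postures: the whole
    torso bend is carried by the lumbar joint, the knee hinge flexes about -X,
    and hip pitch is measured relative to the (level) pelvis.
    """
    torso, hip_l, hip_r, knee_l, knee_r = np.broadcast_arrays(
        *(np.deg2rad(np.asarray(a, dtype=float)) for a in (torso, hip_l, hip_r, knee_l, knee_r))
    )
    zeros = np.zeros_like(torso)

    def rx(a):
        return np.stack([a, zeros, zeros], axis=-1)

    return {
        "pelvis": rx(zeros),
        "lumbar": rx(-torso),
        "thoracic": rx(zeros),
        "l_hip": rx(hip_l - torso),
        "r_hip": rx(hip_r - torso),
        "l_knee": rx(-knee_l),
        "r_knee": rx(-knee_r),
        "l_ankle": rx(zeros),
        "r_ankle": rx(zeros),
    }


# ---------------------------------------------------------------------------
# Forward kinematics
# ---------------------------------------------------------------------------

def fk_batch(sk: Skeleton, rotvecs: dict) -> dict:
    """Vectorized FK: per-joint rotation vectors (..., 3) -> (position mm,
    orientation quaternion) per joint, root at origin."""
    shape = np.asarray(rotvecs["pelvis"], dtype=float).shape[:-1]
    out = {}
    for j in JOINTS:
        v = np.asarray(rotvecs.get(j, np.zeros(shape + (3,))), dtype=float)
        qj = quat_from_rotvec(v)
        parent = PARENT[j]
        if parent is None:
            pos = np.zeros(shape + (3,))
            q = qj
        else:
            ppos, pq = out[parent]
            pos = ppos + quat_rotate(pq, sk.bone_vector(j))
            q = quat_mul(pq, qj)
        out[j] = (pos, q)
    return out


def forward_kinematics(sk: Skeleton, frame: PostureFrame) -> dict:
    """Per-joint world position [mm] and orientation for one posture frame."""
    for j, v in frame.joint_angles.items():
        if np.any(~np.isfinite(v)):
            raise ValueError(f"NaN angles at joint {j}")
    return fk_batch(sk, frame.joint_angles)


def tracker_world_pose(sk: Skeleton, fk: dict, tracker: str):
    """World position [mm] and orientation of a tracker riding mid-segment."""
    node = sk.tracker_map[tracker]
    pos, q = fk[node]
    children = [j for j, p in PARENT.items() if p == node]
    if node in sk.end_sites:
        bone = np.asarray(sk.end_sites[node], dtype=float)
    elif children:
        bone = sk.bone_vector(children[0])
    else:
        bone = np.zeros(3)
    return pos + quat_rotate(q, 0.5 * bone), q


# ---------------------------------------------------------------------------
# Calibration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CalibrationResult:
    """Per-tracker mounting quaternion: segment = tracker ⊗ mounting."""

    mounting_q: dict  # tracker -> (4,) quaternion
    captured_at: float = 0.0

    @classmethod
    def identity(cls) -> "CalibrationResult":
        return cls(mounting_q={tr: quat_identity() for tr in TRACKER_IDS})


def _sagittal_inclination_down(q: np.ndarray) -> np.ndarray:
    """Forward inclination [deg] of a down-pointing segment axis."""
    v = quat_rotate(q, np.array([0.0, 1.0, 0.0]))
    return np.degrees(np.arctan2(v[..., 2], v[..., 1]))


def _sagittal_inclination_up(q: np.ndarray) -> np.ndarray:
    """Forward inclination [deg] of an up-pointing segment axis."""
    v = quat_rotate(q, np.array([0.0, -1.0, 0.0]))
    return np.degrees(np.arctan2(v[..., 2], -v[..., 1]))


SKI_PITCH_MIN_DEG = 20.0  # disambiguation predicate for thigh trackers


def calibrate(upright: dict, ski: dict, captured_at: float = 0.0) -> CalibrationResult:
    """Identify mounting quaternions from the two calibration poses.

    In the upright pose every segment frame must coincide with the world
    frame, so ``mounting = upright*``.  The skiing pose (hips and knees
    flexed, torso pitched forward) must then produce a positive pitch on the
    thigh segments; a tracker failing that check is reported as mis-mounted.
    """
    missing = [tr for tr in TRACKER_IDS if tr not in upright or tr not in ski]
    if missing:
        raise ValueError("missing calibration pose for tracker(s): " + ", ".join(missing))
    mounting = {tr: quat_conj(np.asarray(upright[tr], dtype=float)) for tr in TRACKER_IDS}
    bad = []
    for tr in ("l_knee", "r_knee"):  # femur-fixed trackers
        seg_q = quat_mul(np.asarray(ski[tr], dtype=float), mounting[tr])
        if _sagittal_inclination_down(seg_q) <= SKI_PITCH_MIN_DEG:
            bad.append(tr)
    if bad:
        raise MisMountedTrackerError(bad)
    return CalibrationResult(mounting_q=mounting, captured_at=captured_at)


# ---------------------------------------------------------------------------
# Tracker states -> posture
# ---------------------------------------------------------------------------

def segment_orientations_to_bends(seg_q: dict):
    """Derived bend angles [deg] from per-segment orientations.

    ``seg_q`` maps FK node names (pelvis, thoracic, l_hip, l_knee, r_hip,
    r_knee) to world-from-segment quaternions (vectorized over leading axes).
    """
    torso = _sagittal_inclination_up(seg_q["thoracic"])
    out = {"torso_bend": torso}
    for side in ("l", "r"):
        femur = seg_q[f"{side}_hip"]
        tibia = seg_q[f"{side}_knee"]
        out[f"hip_bend_{side}"] = torso + _sagittal_inclination_down(femur)
        rel = quat_mul(quat_conj(femur), tibia)
        out[f"knee_bend_{side}"] = -np.degrees(quat_to_rotvec(rel)[..., 0])
    return out


def states_to_posture(states: dict, cal: CalibrationResult, sk: Skeleton,
                      match_tol: float = 0.010) -> PostureFrame:
    """Reconstruct one posture frame from six simultaneous tracker states.

    ``states`` maps tracker id -> :class:`TrackerState`; timestamps must
    agree within ``match_tol`` seconds.
    """
    missing = [tr for tr in TRACKER_IDS if tr not in states]
    if missing:
        raise ValueError("missing tracker(s): " + ", ".join(missing))
    ts = np.array([states[tr].t for tr in TRACKER_IDS])
    if ts.max() - ts.min() > match_tol:
        raise ValueError("tracker timestamps differ by more than the matching tolerance")

    seg_q = {}
    for tr in TRACKER_IDS:
        node = sk.tracker_map[tr]
        seg_q[node] = quat_mul(states[tr].q, cal.mounting_q[tr])

    pelvis_q = seg_q["pelvis"]
    angles = {j: np.zeros(3) for j in JOINTS}
    angles["pelvis"] = quat_to_rotvec(pelvis_q)
    angles["lumbar"] = quat_to_rotvec(quat_mul(quat_conj(pelvis_q), seg_q["thoracic"]))
    for side in ("l", "r"):
        femur = seg_q[f"{side}_hip"]
        tibia = seg_q[f"{side}_knee"]
        angles[f"{side}_hip"] = quat_to_rotvec(quat_mul(quat_conj(pelvis_q), femur))
        knee_rv = quat_to_rotvec(quat_mul(quat_conj(femur), tibia))
        angles[f"{side}_knee"] = np.array([knee_rv[0], 0.0, 0.0])  # hinge projection

    bends = segment_orientations_to_bends(seg_q)
    return PostureFrame(
        t=float(ts.mean()),
        joint_angles=angles,
        torso_bend=float(bends["torso_bend"]),
        hip_bend_l=float(bends["hip_bend_l"]),
        hip_bend_r=float(bends["hip_bend_r"]),
        knee_bend_l=float(bends["knee_bend_l"]),
        knee_bend_r=float(bends["knee_bend_r"]),
    )


def states_to_bends_batch(states: dict, cal: CalibrationResult, sk: Skeleton) -> dict:
    """Vectorized bend extraction for aligned per-tracker state sequences.

    ``states`` maps tracker id -> :class:`~imupose.core.TrackerStates` of
    equal length on a common clock.  Returns arrays of derived bend angles.
    """
    seg_q = {}
    for tr in TRACKER_IDS:
        node = sk.tracker_map[tr]
        seg_q[node] = quat_mul(states[tr].q, cal.mounting_q[tr][None, :])
    return segment_orientations_to_bends(seg_q)


# ---------------------------------------------------------------------------
# Rule-based posture classification
# ---------------------------------------------------------------------------

def classify_bends(torso, hip, knee):
    """Vectorized Table-of-ranges posture labeling.

    Ranges are closed on the left and open on the right; candidates are
    tried most-specific-first; frames matching no class get
    :data:`UNCLASSIFIED`.
    """
    torso = np.asarray(torso, dtype=float)
    hip = np.asarray(hip, dtype=float)
    knee = np.asarray(knee, dtype=float)
    out = np.full(torso.shape, UNCLASSIFIED, dtype=np.int64)
    unset = np.ones(torso.shape, dtype=bool)
    for label in RULE_PRIORITY:
        (tlo, thi), (hlo, hhi), (klo, khi) = POSTURE_RANGES[label]
        hit = (
            (torso >= tlo) & (torso < thi)
            & (hip >= hlo) & (hip < hhi)
            & (knee >= klo) & (knee < khi)
            & unset
        )
        out[hit] = label
        unset &= ~hit
    return out


def classify_by_rules(frame: PostureFrame) -> int:
    """Posture label 1-7 for one frame, or :data:`UNCLASSIFIED`."""
    return int(classify_bends(frame.torso_bend, frame.hip_bend, frame.knee_bend))


# ---------------------------------------------------------------------------
# BVH export
# ---------------------------------------------------------------------------

_BVH_TREE = {
    "pelvis": ["lumbar", "l_hip", "r_hip"],
    "lumbar": ["thoracic"],
    "thoracic": [],
    "l_hip": ["l_knee"],
    "l_knee": ["l_ankle"],
    "l_ankle": [],
    "r_hip": ["r_knee"],
    "r_knee": ["r_ankle"],
    "r_ankle": [],
}

_BVH_ORDER = ("pelvis", "lumbar", "thoracic", "l_hip", "l_knee", "l_ankle",
              "r_hip", "r_knee", "r_ankle")


def _rotvec_to_euler_yxz(v: np.ndarray) -> np.ndarray:
    """Rotation vector [rad] -> intrinsic Y-X-Z Euler angles [deg]."""
    v = np.atleast_2d(np.asarray(v, dtype=float))
    return Rotation.from_rotvec(v).as_euler("YXZ", degrees=True)


def _euler_yxz_to_rotvec(e: np.ndarray) -> np.ndarray:
    e = np.atleast_2d(np.asarray(e, dtype=float))
    return Rotation.from_euler("YXZ", e, degrees=True).as_rotvec()


def export_bvh(sk: Skeleton, frames, path: str | Path, frame_time: float | None = None) -> None:
    """Write posture frames as a BVH motion file (offsets in cm).

    Channel order is ``Yrotation Xrotation Zrotation`` (intrinsic), matching
    the yaw-pitch-roll decomposition about the down/right/forward axes.
    """
    frames = list(frames)
    if len(frames) == 0:
        raise ValueError("need at least one frame")
    if frame_time is None:
        if len(frames) > 1:
            frame_time = float(frames[1].t - frames[0].t)
        else:
            frame_time = 0.01

    lines = ["HIERARCHY"]

    def emit(joint: str, depth: int):
        pad = "  " * depth
        kw = "ROOT" if PARENT[joint] is None else "JOINT"
        lines.append(f"{pad}{kw} {joint}")
        lines.append(pad + "{")
        off = np.asarray(sk.offsets[joint], dtype=float) / 10.0  # mm -> cm
        lines.append(f"{pad}  OFFSET {off[0]:.6f} {off[1]:.6f} {off[2]:.6f}")
        if PARENT[joint] is None:
            lines.append(
                f"{pad}  CHANNELS 6 Xposition Yposition Zposition "
                "Yrotation Xrotation Zrotation"
            )
        else:
            lines.append(f"{pad}  CHANNELS 3 Yrotation Xrotation Zrotation")
        kids = _BVH_TREE[joint]
        if kids:
            for k in kids:
                emit(k, depth + 1)
        else:
            site = np.asarray(sk.end_sites.get(joint, np.zeros(3)), dtype=float) / 10.0
            lines.append(f"{pad}  End Site")
            lines.append(pad + "  {")
            lines.append(f"{pad}    OFFSET {site[0]:.6f} {site[1]:.6f} {site[2]:.6f}")
            lines.append(pad + "  }")
        lines.append(pad + "}")

    emit("pelvis", 0)
    lines.append("MOTION")
    lines.append(f"Frames: {len(frames)}")
    lines.append(f"Frame Time: {frame_time:.7f}")

    for fr in frames:
        vals = [0.0, 0.0, 0.0]  # root translation (pelvis pinned at origin)
        for j in _BVH_ORDER:
            e = _rotvec_to_euler_yxz(fr.joint_angles[j])[0]
            vals.extend(e)
        lines.append(" ".join(f"{v:.6f}" for v in vals))

    Path(path).write_text("\n".join(lines) + "\n")


def read_bvh(path: str | Path):
    """Minimal BVH reader for round-trip checks.

    Returns ``(offsets_cm, rotvecs, frame_time)`` where ``rotvecs`` maps
    joint name -> (n_frames, 3) rotation vectors [rad].
    """
    text = Path(path).read_text().split("\n")
    offsets = {}
    order = []
    i = 0
    stack = []
    while i < len(text):
        tok = text[i].strip().split()
        if not tok:
            i += 1
            continue
        if tok[0] in ("ROOT", "JOINT"):
            name = tok[1]
            order.append(name)
            stack.append(name)
        elif tok[0] == "OFFSET" and stack and not stack[-1].startswith("__end"):
            offsets[stack[-1]] = np.array([float(x) for x in tok[1:4]])
        elif tok[0] == "End":
            stack.append("__end")
        elif tok[0] == "}":
            if stack:
                stack.pop()
        elif tok[0] == "MOTION":
            break
        i += 1
    n_frames = int(text[i + 1].split(":")[1])
    frame_time = float(text[i + 2].split(":")[1])
    rows = [
        [float(x) for x in text[i + 3 + k].split()] for k in range(n_frames)
    ]
    data = np.asarray(rows)
    rotvecs = {}
    col = 3  # skip root translation
    for j in order:
        e = data[:, col:col + 3]
        rotvecs[j] = _euler_yxz_to_rotvec(e)
        col += 3
    return offsets, rotvecs, frame_time
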