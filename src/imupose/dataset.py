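"""Labeling, sliding-window segmentation, 36-dimensional feature extraction,
and the train/test split.

Per frame, each of the six tracked joints contributes its cumulative world
displacement (m, zeroed at the start of every contiguous label segment) and
its orientation decomposed to yaw-pitch-roll (deg) — 6 joints x 6 = 36
features.  Windows (length 50, stride 5 at 100 Hz) are cut independently
inside each contiguous single-label segment and never cross excluded frames.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .core import TRACKER_IDS, TrackerStates
from .skeleton import UNCLASSIFIED

__all__ = [
    "FEATURE_NAMES",
    "WindowedDataset",
    "extract_features",
    "segment_bounds",
    "sliding_windows",
    "split_dataset",
    "zscore",
]

logger = logging.getLogger(__name__)

_CHANNELS = ("dx", "dy", "dz", "rx", "ry", "rz")

#: The 36 feature names: 6 tracked joints x (3 displacement + 3 rotation).
FEATURE_NAMES = tuple(f"{tr}_{c}" for tr in TRACKER_IDS for c in _CHANNELS)

WINDOW = 50
STRIDE = 5


@dataclass
class WindowedDataset:
    """N x window x 36 feature tensor with one posture label per window."""

    x: np.ndarray  # (N, window, 36) float32
    y: np.ndarray  # (N,) labels in 1..7
    feature_names: tuple = FEATURE_NAMES

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=np.float32)
        self.y = np.asarray(self.y, dtype=np.int64)
        if self.x.ndim != 3 or len(self.x) != len(self.y):
            raise ValueError("x must be (N, window, features) aligned with y")
        if self.x.shape[2] != len(self.feature_names):
            raise ValueError("feature count does not match feature_names")

    def __len__(self) -> int:
        return len(self.y)

    @property
    def n_features(self) -> int:
        return self.x.shape[2]

    def subset(self, idx: np.ndarray) -> "WindowedDataset":
        return WindowedDataset(self.x[idx], self.y[idx], self.feature_names)

    # -- I/O -------------------------------------------------------------

    def save(self, path: str | Path, **attrs) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("x", data=self.x, compression="gzip", compression_opts=4)
            f.create_dataset("y", data=self.y)
            f.create_dataset(
                "feature_names",
                data=np.array(self.feature_names, dtype=h5py.string_dtype()),
            )
            for k, v in attrs.items():
                f.attrs[k] = v

    @classmethod
    def load(cls, path: str | Path) -> "WindowedDataset":
        with h5py.File(path, "r") as f:
            x = f["x"][...]
            y = f["y"][...]
            names = tuple(s.decode() if isinstance(s, bytes) else s
                          for s in f["feature_names"][...])
        return cls(x=x, y=y, feature_names=names)

    def save_csv(self, path: str | Path) -> None:
        """Flattened CSV export: one row per window (features time-major)."""
        n, w, d = self.x.shape
        cols = [f"{name}_t{t}" for t in range(w) for name in self.feature_names]
        df = pd.DataFrame(self.x.reshape(n, w * d), columns=cols)
        df.insert(0, "label", self.y)
        df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Features
# ---------------------------------------------------------------------------

def segment_bounds(labels: np.ndarray) -> list[tuple[int, int, int]]:
    """Contiguous constant-label runs as (start, stop, label) triples."""
    labels = np.asarray(labels)
    if len(labels) == 0:
        return []
    change = np.flatnonzero(np.diff(labels)) + 1
    starts = np.concatenate([[0], change])
    stops = np.concatenate([change, [len(labels)]])
    return [(int(a), int(b), int(labels[a])) for a, b in zip(starts, stops)]


def _quat_wxyz_to_euler_xyz_cols_deg(q: np.ndarray) -> np.ndarray:
    """Scalar-first quaternions -> intrinsic yaw-pitch-roll angles [deg].

    Decomposition order is Y (yaw), X (pitch), Z (roll); the returned columns
    are reordered to (x, y, z) to match the feature layout.
    """
    xyzw = np.concatenate([q[:, 1:], q[:, :1]], axis=1)
    eul = Rotation.from_quat(xyzw).as_euler("YXZ", degrees=True)
    return eul[:, [1, 0, 2]]


def extract_features(states: dict, labels: np.ndarray | None = None) -> np.ndarray:
    """Per-frame 36-feature matrix from aligned per-tracker state sequences.

    ``states`` maps every tracker id to a :class:`TrackerStates` of equal
    length on a common clock.  Displacements are re-zeroed at the start of
    each contiguous label segment when ``labels`` is given (otherwise at the
    first frame only).
    """
    missing = [tr for tr in TRACKER_IDS if tr not in states]
    if missing:
        raise ValueError("missing tracker(s): " + ", ".join(missing))
    n = len(states[TRACKER_IDS[0]].t)
    t0 = states[TRACKER_IDS[0]].t
    for tr in TRACKER_IDS:
        st = states[tr]
        if len(st.t) != n or np.max(np.abs(st.t - t0)) > 0.010:
            raise ValueError(f"tracker {tr} not aligned with the common clock")

    if labels is None:
        segs = [(0, n, 1)]
    else:
        labels = np.asarray(labels)
        if len(labels) != n:
            raise ValueError("labels not aligned with states")
        segs = segment_bounds(labels)

    out = np.empty((n, len(FEATURE_NAMES)), dtype=np.float64)
    for k, tr in enumerate(TRACKER_IDS):
        st = states[tr]
        disp = st.d.copy()
        for a, b, _ in segs:
            disp[a:b] -= st.d[a]
        rot = _quat_wxyz_to_euler_xyz_cols_deg(st.q)
        out[:, 6 * k:6 * k + 3] = disp
        out[:, 6 * k + 3:6 * k + 6] = rot
    return out


# ---------------------------------------------------------------------------
# Windows
# ---------------------------------------------------------------------------

def sliding_windows(
    features: np.ndarray,
    labels: np.ndarray,
    window: int = WINDOW,
    stride: int = STRIDE,
) -> WindowedDataset:
    """Cut label-pure windows inside each contiguous labeled segment.

    Each segment of length L with label > 0 yields ``floor((L - window)/stride)
    + 1`` windows (0 if L < window); excluded segments yield none, so no
    window ever crosses a label boundary or an excluded frame.
    """
    features = np.asarray(features)
    labels = np.asarray(labels)
    if len(features) != len(labels):
        raise ValueError("features/labels length mismatch")
    xs, ys = [], []
    for a, b, lab in segment_bounds(labels):
        if lab == UNCLASSIFIED:
            continue
        length = b - a
        if length < window:
            logger.info("segment of %d frames (label %d) too short for a window",
                        length, lab)
            continue
        n_win = (length - window) // stride + 1
        idx = a + stride * np.arange(n_win)[:, None] + np.arange(window)[None, :]
        xs.append(features[idx])
        ys.append(np.full(n_win, lab, dtype=np.int64))
    if xs:
        x = np.concatenate(xs).astype(np.float32)
        y = np.concatenate(ys)
    else:
        x = np.empty((0, window, features.shape[1]), dtype=np.float32)
        y = np.empty(0, dtype=np.int64)
    if features.shape[1] == len(FEATURE_NAMES):
        names = FEATURE_NAMES
    else:
        names = tuple(f"f{i}" for i in range(features.shape[1]))
    return WindowedDataset(x=x, y=y, feature_names=names)


def split_dataset(
    ds: WindowedDataset,
    ratio: float = 0.2,
    seed: int = 42,
    grouped: bool = False,
    group_block: int = 50,
) -> tuple[WindowedDataset, WindowedDataset]:
    """Uniform random window-level split into (train, test).

    ``|test| = round(N * ratio)``.  With ``grouped=True`` contiguous blocks of
    ``group_block`` windows are kept on the same side, avoiding the overlap
    leakage of adjacent windows (non-default; the window-level split is the
    published protocol).
    """
    n = len(ds)
    if n < 5:
        raise ValueError("need at least 5 windows to split")
    rng = np.random.default_rng(seed)
    n_test = int(round(n * ratio))
    if grouped:
        n_blocks = int(np.ceil(n / group_block))
        block_ids = np.arange(n) // group_block
        perm_blocks = rng.permutation(n_blocks)
        order = np.argsort(np.argsort(perm_blocks)[block_ids], kind="stable")
        test_idx = order[:n_test]
        train_idx = order[n_test:]
    else:
        perm = rng.permutation(n)
        test_idx = perm[:n_test]
        train_idx = perm[n_test:]
    return ds.subset(np.sort(train_idx)), ds.subset(np.sort(test_idx))


def zscore(train: WindowedDataset, *others: WindowedDataset):
    """Per-feature standardization fit on train, applied to all datasets."""
    mu = train.x.reshape(-1, train.n_features).mean(axis=0)
    sd = train.x.reshape(-1, train.n_features).std(axis=0)
    sd[sd == 0] = 1.0
    out = [WindowedDataset((d.x - mu) / sd, d.y, d.feature_names)
           for d in (train, *others)]
    return out if others else out[0]
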