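"""BiLSTM posture recognizer (with a unidirectional LSTM baseline), the
training protocol, and the repeated-evaluation suite.

Architecture: input window (50 x 36) -> forward LSTM(64) [& backward
LSTM(64)] -> concatenated final hidden states -> dropout 0.5 -> dense ->
softmax over the 7 posture classes.  Training: cross-entropy + L2, Adam at
lr 0.001, 10 epochs, batch 32.  Evaluation retrains with independent seeds
(reshuffling both the split and the sample order) and averages accuracy and
per-class precision/recall/F-score over the repeats; confusion counts are
summed.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.metrics import confusion_matrix, precision_recall_fscore_support

from .dataset import WindowedDataset, split_dataset, zscore
from .nn import LstmClassifier

__all__ = [
    "ModelConfig",
    "EvalReport",
    "build_model",
    "train",
    "evaluate",
    "predict_stream",
    "CLASS_LABELS",
]

#: External labels 1..7 map to internal indices 0..6.
CLASS_LABELS = tuple(range(1, 8))


@dataclass(frozen=True)
class ModelConfig:
    hidden_units: int = 64
    dropout: float = 0.5
    learning_rate: float = 0.001
    epochs: int = 10
    batch_size: int = 32
    classes: int = 7
    bidirectional: bool = True
    l2: float = 1e-4
    window: int = 50
    features: int = 36
    val_fraction: float = 0.1

    def __post_init__(self):
        for name in ("hidden_units", "learning_rate", "epochs", "batch_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.classes != 7:
            raise ValueError("the posture taxonomy has exactly 7 classes")


@dataclass
class EvalReport:
    """Averaged metrics over repeated train/test runs."""

    accuracy: float  # mean over repeats, fraction
    per_class: dict  # label -> {"precision", "recall", "f_score"} (means)
    confusion: np.ndarray  # (7, 7) counts summed over repeats
    repeats: list  # per-run accuracies
    final_val_losses: list = field(default_factory=list)
    histories: list = field(default_factory=list)

    def __post_init__(self):
        self.confusion = np.asarray(self.confusion, dtype=np.int64)

    def validate(self) -> None:
        for lab, m in self.per_class.items():
            p, r, f = m["precision"], m["recall"], m["f_score"]
            if p + r > 0 and abs(f - 2 * p * r / (p + r)) > 0.2:
                # repeat-averaged F tracks, but does not equal, F of the
                # averaged P/R; only gross inconsistency is flagged
                raise ValueError(f"inconsistent F-score for class {lab}")

    def min_precision(self) -> float:
        return min(m["precision"] for m in self.per_class.values())

    def min_recall(self) -> float:
        return min(m["recall"] for m in self.per_class.values())

    def min_f_score(self) -> float:
        return min(m["f_score"] for m in self.per_class.values())

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "per_class": {str(k): v for k, v in self.per_class.items()},
            "confusion": self.confusion.tolist(),
            "repeats": self.repeats,
            "final_val_losses": self.final_val_losses,
        }

    def save_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    def save_confusion_csv(self, path: str | Path) -> None:
        import pandas as pd

        df = pd.DataFrame(self.confusion,
                          index=[f"true_{c}" for c in CLASS_LABELS],
                          columns=[f"pred_{c}" for c in CLASS_LABELS])
        df.to_csv(path)


def build_model(cfg: ModelConfig, seed: int = 0) -> LstmClassifier:
    """Instantiate the recognizer for the given configuration."""
    return LstmClassifier(
        input_dim=cfg.features,
        hidden=cfg.hidden_units,
        n_classes=cfg.classes,
        bidirectional=cfg.bidirectional,
        dropout=cfg.dropout,
        l2=cfg.l2,
        seed=seed,
    )


def _to_internal(y: np.ndarray) -> np.ndarray:
    return np.asarray(y, dtype=np.int64) - 1


def train(
    model: LstmClassifier,
    ds_train: WindowedDataset,
    cfg: ModelConfig,
    seed: int = 0,
    ds_val: WindowedDataset | None = None,
) -> dict:
    """Train on a windowed dataset; returns the loss history.

    When no validation set is supplied, ``cfg.val_fraction`` of the training
    windows are carved out (seeded) to track held-out loss per epoch.
    """
    if len(ds_train) == 0:
        raise ValueError("empty dataset")
    if ds_val is None and cfg.val_fraction > 0 and len(ds_train) >= 10:
        ds_train, ds_val = split_dataset(ds_train, ratio=cfg.val_fraction,
                                         seed=seed + 1000)
    x_val = ds_val.x if ds_val is not None else None
    y_val = _to_internal(ds_val.y) if ds_val is not None else None
    return model.fit(
        ds_train.x,
        _to_internal(ds_train.y),
        x_val,
        y_val,
        epochs=cfg.epochs,
        batch_size=cfg.batch_size,
        lr=cfg.learning_rate,
        seed=seed,
    )


def evaluate(
    ds: WindowedDataset,
    cfg: ModelConfig,
    repeats: int = 5,
    seeds: list | None = None,
    split_ratio: float = 0.2,
    standardize: bool = True,
    verbose: bool = False,
) -> EvalReport:
    """Repeated train/test evaluation on a full windowed dataset.

    Each repeat draws its own 4:1 split and training shuffle from its seed,
    trains a fresh model, and scores the held-out windows.
    """
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    if seeds is None:
        seeds = [42 + i for i in range(repeats)]
    if len(seeds) != repeats:
        raise ValueError("need one seed per repeat")

    accs = []
    precs, recs, fscores = [], [], []
    confusion = np.zeros((cfg.classes, cfg.classes), dtype=np.int64)
    val_losses = []
    histories = []
    labels = list(CLASS_LABELS)
    for seed in seeds:
        t0 = time.perf_counter()
        tr, te = split_dataset(ds, ratio=split_ratio, seed=seed)
        if standardize:
            tr, te = zscore(tr, te)
        model = build_model(cfg, seed=seed)
        hist = train(model, tr, cfg, seed=seed)
        y_pred = model.predict(te.x) + 1
        accs.append(float(np.mean(y_pred == te.y)))
        p, r, f, _ = precision_recall_fscore_support(
            te.y, y_pred, labels=labels, zero_division=0
        )
        precs.append(p)
        recs.append(r)
        fscores.append(f)
        confusion += confusion_matrix(te.y, y_pred, labels=labels)
        if hist["val_loss"]:
            val_losses.append(hist["val_loss"][-1])
        histories.append(hist)
        if verbose:
            print(f"repeat seed={seed}: acc={accs[-1]:.4f} "
                  f"({time.perf_counter() - t0:.1f}s)")

    p_mean = np.mean(precs, axis=0)
    r_mean = np.mean(recs, axis=0)
    f_mean = np.mean(fscores, axis=0)
    per_class = {
        lab: {"precision": float(p_mean[i]), "recall": float(r_mean[i]),
              "f_score": float(f_mean[i])}
        for i, lab in enumerate(labels)
    }
    return EvalReport(
        accuracy=float(np.mean(accs)),
        per_class=per_class,
        confusion=confusion,
        repeats=accs,
        final_val_losses=val_losses,
        histories=histories,
    )


def predict_stream(model: LstmClassifier, feature_frames, window: int = 50,
                   stride: int = 5, norm: tuple | None = None):
    """Online prediction over a stream of per-frame feature vectors.

    Yields ``(frame_index, label, probability, latency_s)`` every ``stride``
    frames once ``window`` frames are buffered.  ``norm`` optionally carries
    (mean, std) standardization fitted at training time.
    """
    buffer = []
    since_last = 0
    for i, frame in enumerate(feature_frames):
        buffer.append(np.asarray(frame, dtype=np.float32))
        if len(buffer) > window:
            buffer.pop(0)
        if len(buffer) < window:
            continue  # warm-up
        if len(buffer) == window and since_last == 0:
            pass  # first full window: predict now
        elif since_last < stride:
            since_last += 1
            continue
        t0 = time.perf_counter()
        x = np.stack(buffer)[None, :, :]
        if norm is not None:
            x = (x - norm[0]) / norm[1]
        probs = model.predict_proba(x)[0]
        latency = time.perf_counter() - t0
        since_last = 1
        yield i, int(np.argmax(probs)) + 1, probs, latency
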