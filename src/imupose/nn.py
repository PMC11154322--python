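"""Minimal NumPy recurrent-network engine: (bi)directional LSTM encoder,
dropout, dense softmax head, Adam, and a training loop.

No deep-learning framework is assumed at run time, so the forward and
backward passes are written directly against BLAS.  The two directions of a
bidirectional layer are processed as a stacked leading axis so every
time-step update is a single batched GEMM.  Gates are packed ``[i, f, o, g]``
so the three sigmoids evaluate in one slab.

Gradient flows into the encoder only through the final hidden state of each
direction (the head consumes the concatenated final states), which keeps
backpropagation-through-time compact.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

__all__ = ["LstmClassifier", "Adam"]

F32 = np.float32


def _sigmoid_inplace(x: np.ndarray) -> np.ndarray:
    np.negative(x, out=x)
    np.exp(x, out=x)
    x += 1.0
    np.reciprocal(x, out=x)
    return x


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    np.exp(z, out=z)
    z /= z.sum(axis=1, keepdims=True)
    return z


class Adam:
    """Adaptive moment estimation over a dict of parameter arrays."""

    def __init__(self, params: dict, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for k, g in grads.items():
            m = self.m[k]
            v = self.v[k]
            m *= self.beta1
            m += (1.0 - self.beta1) * g
            v *= self.beta2
            v += (1.0 - self.beta2) * (g * g)
            params[k] -= (self.lr / b1t) * m / (np.sqrt(v / b2t) + self.eps)


class LstmClassifier:
    """(Bi)LSTM sequence classifier with a dense softmax head.

    Input ``(batch, T, input_dim)`` -> per-direction LSTM(hidden) -> final
    hidden states concatenated -> dropout -> dense -> softmax over classes.
    """

    def __init__(self, input_dim: int, hidden: int, n_classes: int,
                 bidirectional: bool = True, dropout: float = 0.5,
                 l2: float = 1e-4, seed: int = 0):
        self.input_dim = input_dim
        self.hidden = hidden
        self.n_classes = n_classes
        self.ndir = 2 if bidirectional else 1
        self.dropout = dropout
        self.l2 = l2
        rng = np.random.default_rng(seed)
        D, H, nd = input_dim, hidden, self.ndir

        def glorot(*shape):
            fan_in, fan_out = shape[-2], shape[-1]
            lim = np.sqrt(6.0 / (fan_in + fan_out))
            return rng.uniform(-lim, lim, size=shape).astype(F32)

        self.params = {
            "W": glorot(nd, D, 4 * H),
            "U": glorot(nd, H, 4 * H),
            "b": np.zeros((nd, 1, 4 * H), dtype=F32),
            "Wd": glorot(nd * H, n_classes),
            "bd": np.zeros(n_classes, dtype=F32),
        }
        # forget-gate bias init at 1 (gate order [i, f, o, g])
        self.params["b"][:, :, H:2 * H] = 1.0
        self._rng = rng

    # -- dimensions ---------------------------------------------------------

    @property
    def bidirectional(self) -> bool:
        return self.ndir == 2

    def parameter_count(self) -> int:
        return int(sum(v.size for v in self.params.values()))

    def recurrent_parameter_count(self) -> int:
        return int(sum(self.params[k].size for k in ("W", "U", "b")))

    # -- forward / backward --------------------------------------------------

    def _encode(self, X: np.ndarray, want_cache: bool):
        """Run the recurrent encoder; returns concatenated final states."""
        nd, H = self.ndir, self.hidden
        B, T, D = X.shape
        W, U, b = self.params["W"], self.params["U"], self.params["b"]
        dt = W.dtype
        Xt = np.ascontiguousarray(X.transpose(1, 0, 2), dtype=dt)  # (T,B,D)
        Xs = np.stack([Xt, Xt[::-1]]) if nd == 2 else Xt[None]  # (nd,T,B,D)
        Z = Xs.reshape(nd, T * B, D) @ W
        Z += b
        Z = np.ascontiguousarray(Z.reshape(nd, T, B, 4 * H).transpose(1, 0, 2, 3))
        G = np.empty((T, nd, B, 4 * H), dt)
        C = np.empty((T, nd, B, H), dt)
        TC = np.empty((T, nd, B, H), dt)
        h = np.zeros((nd, B, H), dt)
        c = np.zeros((nd, B, H), dt)
        hbuf = np.empty((nd, B, 4 * H), dt)
        H3 = 3 * H
        for t in range(T):
            z = Z[t]
            np.matmul(h, U, out=hbuf)
            z += hbuf
            g = G[t]
            g[..., :H3] = z[..., :H3]
            _sigmoid_inplace(g[..., :H3])
            np.tanh(z[..., H3:], out=g[..., H3:])
            c = g[..., H:2 * H] * c
            c += g[..., :H] * g[..., H3:]
            C[t] = c
            tc = np.tanh(c, out=TC[t])
            h = g[..., 2 * H:H3] * tc
        h_cat = np.ascontiguousarray(h.transpose(1, 0, 2)).reshape(B, nd * H)
        if want_cache:
            self._cache = (Xs, G, C, TC)
        return h_cat

    def _encoder_backward(self, dh_cat: np.ndarray) -> dict:
        nd, H = self.ndir, self.hidden
        Xs, G, C, TC = self._cache
        _, T, B, D = Xs.shape
        dt = Xs.dtype
        UT = np.ascontiguousarray(self.params["U"].transpose(0, 2, 1))
        dh = np.ascontiguousarray(dh_cat.reshape(B, nd, H).transpose(1, 0, 2), dtype=dt)
        dc = np.zeros((nd, B, H), dt)
        dZ = np.empty((T, nd, B, 4 * H), dt)
        one = dt.type(1.0)
        H3 = 3 * H
        for t in range(T - 1, -1, -1):
            g = G[t]
            tc = TC[t]
            i_ = g[..., :H]
            f_ = g[..., H:2 * H]
            o_ = g[..., 2 * H:H3]
            gg = g[..., H3:]
            dz = dZ[t]
            dzi = dz[..., :H]
            dzf = dz[..., H:2 * H]
            dzo = dz[..., 2 * H:H3]
            dzg = dz[..., H3:]
            np.multiply(dh, tc, out=dzo)
            dc += dh * o_ * (one - tc * tc)
            dzo *= o_ * (one - o_)
            np.multiply(dc, gg, out=dzi)
            dzi *= i_ * (one - i_)
            np.multiply(dc, i_, out=dzg)
            dzg *= one - gg * gg
            if t > 0:
                np.multiply(dc, C[t - 1], out=dzf)
                dzf *= f_ * (one - f_)
            else:
                dzf[...] = 0.0
            dh = dz @ UT
            dc *= f_
        # weight gradients via batched GEMMs over the whole sequence
        Hprev = np.empty((T, nd, B, H), dt)
        Hprev[0] = 0.0
        np.multiply(G[:-1, ..., 2 * H:H3], TC[:-1], out=Hprev[1:])
        dZf = np.ascontiguousarray(dZ.transpose(1, 0, 2, 3)).reshape(nd, T * B, 4 * H)
        dU = np.ascontiguousarray(Hprev.transpose(1, 0, 2, 3)).reshape(
            nd, T * B, H).transpose(0, 2, 1) @ dZf
        dW = Xs.reshape(nd, T * B, D).transpose(0, 2, 1) @ dZf
        db = dZf.sum(axis=1, keepdims=True)
        return {"W": dW, "U": dU, "b": db}, None

    def forward(self, X: np.ndarray, train: bool = False):
        h = self._encode(np.asarray(X, dtype=F32), want_cache=train)
        if train and self.dropout > 0:
            keep = 1.0 - self.dropout
            mask = (self._rng.random(h.shape) < keep).astype(h.dtype) / h.dtype.type(keep)
            h = h * mask
            self._dropout_mask = mask
        else:
            self._dropout_mask = None
        self._h_dropped = h if train else None
        return h @ self.params["Wd"] + self.params["bd"]

    def loss_and_grads(self, X: np.ndarray, y: np.ndarray):
        """Mean cross-entropy (+ L2 on weights) and parameter gradients."""
        B = len(y)
        logits = self.forward(X, train=True)
        probs = _softmax(logits.astype(np.float64))
        ce = -np.mean(np.log(probs[np.arange(B), y] + 1e-12))
        h = self._h_dropped
        dlogits = probs.astype(h.dtype)
        dlogits[np.arange(B), y] -= 1.0
        dlogits /= h.dtype.type(B)
        grads = {
            "Wd": h.T @ dlogits,
            "bd": dlogits.sum(axis=0),
        }
        dh = dlogits @ self.params["Wd"].T
        if self._dropout_mask is not None:
            dh *= self._dropout_mask
        enc_grads, _ = self._encoder_backward(dh)
        grads.update(enc_grads)
        l2 = self.l2
        reg = 0.0
        if l2 > 0:
            for k in ("W", "U", "Wd"):
                grads[k] += self.params[k].dtype.type(l2) * self.params[k]
                reg += 0.5 * l2 * float(np.sum(self.params[k].astype(np.float64) ** 2))
        return ce + reg, grads

    # -- inference ------------------------------------------------------------

    def predict_proba(self, X: np.ndarray, batch: int = 512) -> np.ndarray:
        out = np.empty((len(X), self.n_classes))
        for a in range(0, len(X), batch):
            logits = self.forward(X[a:a + batch], train=False)
            out[a:a + batch] = _softmax(logits.astype(np.float64))
        return out

    def predict(self, X: np.ndarray, batch: int = 512) -> np.ndarray:
        return np.argmax(self.predict_proba(X, batch), axis=1)

    def eval_loss(self, X: np.ndarray, y: np.ndarray, batch: int = 512) -> float:
        """Cross-entropy without the L2 penalty (held-out loss)."""
        probs = self.predict_proba(X, batch)
        return float(-np.mean(np.log(probs[np.arange(len(y)), y] + 1e-12)))

    # -- training --------------------------------------------------------------

    def fit(
        self,
        x_train: np.ndarray,
        y_train: np.ndarray,
        x_val: np.ndarray | None = None,
        y_val: np.ndarray | None = None,
        epochs: int = 10,
        batch_size: int = 32,
        lr: float = 1e-3,
        seed: int = 0,
        verbose: bool = False,
    ) -> dict:
        """Mini-batch Adam training; returns per-epoch loss history."""
        if len(x_train) == 0:
            raise ValueError("empty training set")
        x_train = np.asarray(x_train, dtype=F32)
        y_train = np.asarray(y_train, dtype=np.int64)
        opt = Adam(self.params, lr=lr)
        shuffle_rng = np.random.default_rng(seed)
        self._rng = np.random.default_rng(seed + 1)  # dropout stream
        history = {"loss": [], "val_loss": []}
        n = len(x_train)
        for epoch in range(epochs):
            order = shuffle_rng.permutation(n)
            total = 0.0
            for a in range(0, n, batch_size):
                idx = order[a:a + batch_size]
                loss, grads = self.loss_and_grads(x_train[idx], y_train[idx])
                opt.step(self.params, grads)
                total += loss * len(idx)
            history["loss"].append(total / n)
            if x_val is not None and len(x_val):
                history["val_loss"].append(self.eval_loss(x_val, y_val))
            if verbose:
                msg = f"epoch {epoch + 1}/{epochs}: loss={history['loss'][-1]:.4f}"
                if history["val_loss"]:
                    msg += f" val_loss={history['val_loss'][-1]:.4f}"
                print(msg)
        return history

    # -- persistence ------------------------------------------------------------

    def save(self, directory: str | Path, **meta) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        np.savez(d / "weights.npz", **self.params)
        cfg = {
            "input_dim": self.input_dim,
            "hidden": self.hidden,
            "n_classes": self.n_classes,
            "bidirectional": self.bidirectional,
            "dropout": self.dropout,
            "l2": self.l2,
            **meta,
        }
        (d / "model.json").write_text(json.dumps(cfg, indent=2))

    @classmethod
    def load(cls, directory: str | Path) -> "LstmClassifier":
        d = Path(directory)
        cfg = json.loads((d / "model.json").read_text())
        model = cls(
            input_dim=cfg["input_dim"],
            hidden=cfg["hidden"],
            n_classes=cfg["n_classes"],
            bidirectional=cfg["bidirectional"],
            dropout=cfg["dropout"],
            l2=cfg["l2"],
        )
        with np.load(d / "weights.npz") as w:
            for k in model.params:
                model.params[k] = w[k].astype(F32)
        model.meta = {k: v for k, v in cfg.items()
                      if k not in ("input_dim", "hidden", "n_classes",
                                   "bidirectional", "dropout", "l2")}
        return model
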