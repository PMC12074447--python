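"""CNN classifier for spectrogram stacks.

Architecture (fixed default): Conv2D 32 filters (3,3) ReLU -> MaxPool (2,2)
-> Conv2D 16 filters (3,3) ReLU -> Flatten -> Dense 16 ReLU -> Dropout 0.25
-> Dense 1 sigmoid.  Valid (no-padding) convolutions; trained with Adam on
binary cross-entropy with early stopping.

Convolutions are computed as nine shifted GEMMs (one per kernel tap), which
keeps the working set small enough for 8 GiB at the (9, 1009, 30) input size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._nn import glorot, sigmoid, train_network

__all__ = ["CNNSpec", "CNNClassifier", "train_cnn"]


@dataclass
class CNNSpec:
    filters1: int = 32
    filters2: int = 16
    kernel: tuple[int, int] = (3, 3)
    pool: tuple[int, int] = (2, 2)
    dense_units: int = 16
    dropout: float = 0.25
    lr: float = 1e-3
    batch_size: int = 64
    max_epochs: int = 50
    patience: int = 5
    clip_norm: float = 5.0


def _conv_forward(X: np.ndarray, W: np.ndarray, b: np.ndarray) -> np.ndarray:
    kh, kw, cin, cout = W.shape
    B, H, Wd, _ = X.shape
    Ho, Wo = H - kh + 1, Wd - kw + 1
    Y = np.zeros((B, Ho, Wo, cout), dtype=X.dtype)
    for di in range(kh):
        for dj in range(kw):
            patch = np.ascontiguousarray(X[:, di : di + Ho, dj : dj + Wo, :])
            Y += (patch.reshape(-1, cin) @ W[di, dj]).reshape(B, Ho, Wo, cout)
    return Y + b


def _conv_backward(X: np.ndarray, W: np.ndarray, dY: np.ndarray):
    kh, kw, cin, cout = W.shape
    B, H, Wd, _ = X.shape
    Ho, Wo = H - kh + 1, Wd - kw + 1
    dX = np.zeros_like(X)
    dW = np.zeros_like(W)
    db = dY.sum(axis=(0, 1, 2))
    dYf = dY.reshape(-1, cout)
    for di in range(kh):
        for dj in range(kw):
            patch = np.ascontiguousarray(X[:, di : di + Ho, dj : dj + Wo, :])
            dW[di, dj] = patch.reshape(-1, cin).T @ dYf
            dX[:, di : di + Ho, dj : dj + Wo, :] += (dYf @ W[di, dj].T).reshape(
                B, Ho, Wo, cin
            )
    return dX, dW, db


def _pool_forward(X: np.ndarray, pool: tuple[int, int]):
    ph, pw = pool
    B, H, Wd, C = X.shape
    Ho, Wo = H // ph, Wd // pw
    blocks = (
        X[:, : Ho * ph, : Wo * pw, :]
        .reshape(B, Ho, ph, Wo, pw, C)
        .transpose(0, 1, 3, 5, 2, 4)
        .reshape(B, Ho, Wo, C, ph * pw)
    )
    arg = blocks.argmax(axis=-1)
    Y = np.take_along_axis(blocks, arg[..., None], axis=-1)[..., 0]
    return Y, arg


def _pool_backward(dY: np.ndarray, arg: np.ndarray, in_shape, pool: tuple[int, int]):
    ph, pw = pool
    B, H, Wd, C = in_shape
    Ho, Wo = H // ph, Wd // pw
    dblocks = np.zeros((B, Ho, Wo, C, ph * pw), dtype=dY.dtype)
    np.put_along_axis(dblocks, arg[..., None], dY[..., None], axis=-1)
    dX = np.zeros(in_shape, dtype=dY.dtype)
    dX[:, : Ho * ph, : Wo * pw, :] = (
        dblocks.reshape(B, Ho, Wo, C, ph, pw)
        .transpose(0, 1, 4, 2, 5, 3)
        .reshape(B, Ho * ph, Wo * pw, C)
    )
    return dX


class CNNClassifier:
    """Numpy 2-conv CNN with hand-written backpropagation."""

    def __init__(
        self,
        input_shape: tuple[int, int, int],
        spec: CNNSpec | None = None,
        seed: int = 0,
        dtype=np.float32,
    ):
        self.spec = spec or CNNSpec()
        self.input_shape = tuple(input_shape)  # (bins, frames, channels)
        self.dtype = dtype
        self._seed = seed
        s = self.spec
        kh, kw = s.kernel
        bins, frames, cin = self.input_shape
        h1, w1 = bins - kh + 1, frames - kw + 1
        hp, wp = h1 // s.pool[0], w1 // s.pool[1]
        h2, w2 = hp - kh + 1, wp - kw + 1
        if min(h1, w1, hp, wp, h2, w2) < 1:
            raise ValueError(f"input shape {input_shape} too small for architecture")
        self._flat = h2 * w2 * s.filters2
        rng = np.random.default_rng(seed)
        self.W1 = glorot(rng, (kh, kw, cin, s.filters1), dtype)
        self.b1 = np.zeros(s.filters1, dtype)
        self.W2 = glorot(rng, (kh, kw, s.filters1, s.filters2), dtype)
        self.b2 = np.zeros(s.filters2, dtype)
        self.Wd = glorot(rng, (self._flat, s.dense_units), dtype)
        self.bd = np.zeros(s.dense_units, dtype)
        # Zero-initialized head: an untrained model scores exactly 0.5.
        self.Wo = np.zeros((s.dense_units, 1), dtype)
        self.bo = np.zeros(1, dtype)

    @property
    def params(self) -> list[np.ndarray]:
        return [self.W1, self.b1, self.W2, self.b2, self.Wd, self.bd, self.Wo, self.bo]

    @property
    def n_params(self) -> int:
        """Deterministic parameter count of the architecture."""
        return int(sum(p.size for p in self.params))

    def forward(self, X, train: bool = False, rng: np.random.Generator | None = None):
        X = np.ascontiguousarray(X, dtype=self.dtype)
        if X.shape[1:] != self.input_shape:
            raise ValueError(
                f"expected spectrograms of shape {self.input_shape}, got {X.shape[1:]}"
            )
        s = self.spec
        a1 = _conv_forward(X, self.W1, self.b1)
        r1 = np.maximum(a1, 0)
        p1, arg = _pool_forward(r1, s.pool)
        a2 = _conv_forward(p1, self.W2, self.b2)
        r2 = np.maximum(a2, 0)
        flat = r2.reshape(len(X), -1)
        d = flat @ self.Wd + self.bd
        rd = np.maximum(d, 0)
        if train and rng is not None and s.dropout > 0:
            mask = ((rng.random(rd.shape) >= s.dropout) / (1 - s.dropout)).astype(
                self.dtype
            )
            rdm = rd * mask
        else:
            mask = None
            rdm = rd
        logits = (rdm @ self.Wo).ravel() + self.bo[0]
        cache = {
            "X": X, "a1": a1, "r1_shape": r1.shape, "arg": arg, "p1": p1,
            "a2": a2, "flat": flat, "d": d, "rdm": rdm, "mask": mask,
        }
        return logits.astype(np.float64), cache

    def backward(self, cache, dlogits):
        s = self.spec
        dz = np.asarray(dlogits, dtype=self.dtype)[:, None]
        dWo = cache["rdm"].T @ dz
        dbo = np.array([dz.sum()], dtype=self.dtype)
        drd = dz @ self.Wo.T
        if cache["mask"] is not None:
            drd = drd * cache["mask"]
        dd = drd * (cache["d"] > 0)
        dWd = cache["flat"].T @ dd
        dbd = dd.sum(axis=0)
        dflat = dd @ self.Wd.T
        da2 = dflat.reshape(cache["a2"].shape) * (cache["a2"] > 0)
        dp1, dW2, db2 = _conv_backward(cache["p1"], self.W2, da2)
        dr1 = _pool_backward(dp1, cache["arg"], cache["r1_shape"], s.pool)
        da1 = dr1 * (cache["a1"] > 0)
        _, dW1, db1 = _conv_backward(cache["X"], self.W1, da1)
        return [dW1, db1, dW2, db2, dWd, dbd, dWo, dbo]

    def predict_scores(
        self, X, batch_size: int = 64, logits: bool = False
    ) -> np.ndarray:
        out = []
        for i0 in range(0, len(X), batch_size):
            z, _ = self.forward(X[i0 : i0 + batch_size], train=False)
            out.append(z)
        z = np.concatenate(out) if out else np.empty(0)
        return z if logits else sigmoid(z)

    def fit(self, X, y, X_val, y_val) -> dict:
        return train_network(
            self, X, y, X_val, y_val,
            lr=self.spec.lr,
            batch_size=self.spec.batch_size,
            max_epochs=self.spec.max_epochs,
            patience=self.spec.patience,
            clip_norm=self.spec.clip_norm,
            seed=self._seed,
        )


def train_cnn(
    spectrograms: np.ndarray,
    labels: np.ndarray,
    val_spectrograms: np.ndarray,
    val_labels: np.ndarray,
    spec: CNNSpec | None = None,
    seed: int = 0,
) -> tuple[CNNClassifier, dict]:
    """Train the CNN on (n_windows, bins, frames, channels) spectrogram stacks."""
    spectrograms = np.asarray(spectrograms)
    if spectrograms.ndim != 4:
        raise ValueError(
            "spectrograms must have shape (n_windows, bins, frames, channels)"
        )
    if val_spectrograms.shape[1:] != spectrograms.shape[1:]:
        raise ValueError("validation spectrograms have inconsistent shape")
    model = CNNClassifier(spectrograms.shape[1:], spec, seed=seed)
    history = model.fit(spectrograms, labels, val_spectrograms, val_labels)
    return model, history
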