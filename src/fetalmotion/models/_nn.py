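"""Minimal numpy neural-network engine (Adam, BCE-with-logits, training loop).

No deep-learning framework is assumed by this package: the two small
architectures used here (a single-layer BiLSTM and a two-conv CNN) are
implemented directly with numpy forward/backward passes.  Everything is
deterministic given the seed; gradients are validated against finite
differences in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = ["sigmoid", "bce_with_logits", "Adam", "train_network", "glorot", "orthogonal"]


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_with_logits(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean binary cross-entropy and its gradient w.r.t. the logits."""
    z = np.asarray(logits, dtype=float)
    y = np.asarray(y, dtype=float)
    # softplus(z) - y*z, computed stably
    loss = float(np.mean(np.logaddexp(0.0, z) - y * z))
    dz = (sigmoid(z) - y) / z.size
    return loss, dz


def glorot(rng: np.random.Generator, shape: tuple[int, ...], dtype=np.float32) -> np.ndarray:
    fan_in, fan_out = shape[-2], shape[-1]
    if len(shape) > 2:  # conv kernels: receptive field enters the fans
        receptive = int(np.prod(shape[:-2]))
        fan_in, fan_out = shape[-2] * receptive, shape[-1] * receptive
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(dtype)


def orthogonal(rng: np.random.Generator, n: int, m: int, dtype=np.float32) -> np.ndarray:
    """(n, m) matrix whose n x n column blocks are orthogonal (m multiple of n)."""
    blocks = []
    for _ in range(m // n):
        q, _ = np.linalg.qr(rng.standard_normal((n, n)))
        blocks.append(q)
    return np.concatenate(blocks, axis=1).astype(dtype)


class Adam:
    def __init__(self, params: list[np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-7):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            g = g.astype(p.dtype, copy=False)
            m *= self.beta1
            m += (1 - self.beta1) * g
            v *= self.beta2
            v += (1 - self.beta2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def _clip_grads(grads: list[np.ndarray], max_norm: float) -> None:
    total = np.sqrt(sum(float(np.sum(g.astype(np.float64) ** 2)) for g in grads))
    if total > max_norm > 0:
        scale = max_norm / total
        for g in grads:
            g *= scale


def train_network(
    model,
    X: np.ndarray,
    y: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    *,
    lr: float = 1e-3,
    batch_size: int = 64,
    max_epochs: int = 50,
    patience: int = 5,
    clip_norm: float = 5.0,
    seed: int = 0,
) -> dict:
    """Adam + mini-batches + early stopping on validation loss.

    Restores the best-validation-loss weights before returning.  A zero
    ``max_epochs`` budget leaves the model at its initialization (whose head
    is zero-initialized, i.e. constant 0.5 scores).
    """
    if len(X_val) == 0:
        raise ValueError("validation set must not be empty")
    y = np.asarray(y, dtype=np.float64)
    rng = np.random.default_rng(seed)
    opt = Adam(model.params, lr=lr)
    best_val = np.inf
    best_params = [p.copy() for p in model.params]
    bad_epochs = 0
    history: dict = {"train_loss": [], "val_loss": []}
    n = len(X)
    for _epoch in range(max_epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for i0 in range(0, n, batch_size):
            idx = order[i0 : i0 + batch_size]
            logits, cache = model.forward(X[idx], train=True, rng=rng)
            loss, dz = bce_with_logits(logits, y[idx])
            grads = model.backward(cache, dz)
            _clip_grads(grads, clip_norm)
            opt.step(grads)
            epoch_loss += loss * len(idx)
        history["train_loss"].append(epoch_loss / n)
        val_scores = model.predict_scores(X_val, logits=True)
        val_loss, _ = bce_with_logits(val_scores, np.asarray(y_val, dtype=np.float64))
        history["val_loss"].append(val_loss)
        if val_loss < best_val - 1e-6:
            best_val = val_loss
            best_params = [p.copy() for p in model.params]
            bad_epochs = 0
        else:
            bad_epochs += 1
            if bad_epochs >= patience:
                break
    for p, b in zip(model.params, best_params):
        p[...] = b
    history["best_val_loss"] = best_val
    return history
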