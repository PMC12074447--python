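"""Bidirectional LSTM classifier for 0.5 s time-series windows.

A single BiLSTM layer (64 units per direction, 0.3 input dropout, 0.3
recurrent dropout) whose final forward and backward hidden states are
concatenated and fed to a dense sigmoid head.  Trained with Adam on binary
cross-entropy, early stopping on validation loss.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._nn import glorot, orthogonal, sigmoid, train_network

__all__ = ["BiLSTMSpec", "BiLSTMClassifier", "train_bilstm"]


@dataclass
class BiLSTMSpec:
    units: int = 64
    dropout: float = 0.3
    recurrent_dropout: float = 0.3
    lr: float = 1e-3
    batch_size: int = 64
    max_epochs: int = 50
    patience: int = 5
    clip_norm: float = 5.0


def _split_gates(z: np.ndarray, H: int):
    return z[:, :H], z[:, H : 2 * H], z[:, 2 * H : 3 * H], z[:, 3 * H :]


class BiLSTMClassifier:
    """Numpy BiLSTM with hand-written backpropagation through time."""

    def __init__(
        self,
        n_channels: int,
        spec: BiLSTMSpec | None = None,
        seed: int = 0,
        dtype=np.float32,
    ):
        self.spec = spec or BiLSTMSpec()
        self.n_channels = n_channels
        self.dtype = dtype
        H, C = self.spec.units, n_channels
        rng = np.random.default_rng(seed)
        self._seed = seed

        def lstm_params():
            Wx = glorot(rng, (C, 4 * H), dtype)
            Wh = orthogonal(rng, H, 4 * H, dtype)
            b = np.zeros(4 * H, dtype)
            b[H : 2 * H] = 1.0  # forget-gate bias
            return Wx, Wh, b

        self.Wx_f, self.Wh_f, self.b_f = lstm_params()
        self.Wx_b, self.Wh_b, self.b_b = lstm_params()
        # Zero-initialized head: an untrained model scores exactly 0.5.
        self.W_out = np.zeros((2 * H, 1), dtype)
        self.b_out = np.zeros(1, dtype)

    @property
    def params(self) -> list[np.ndarray]:
        return [
            self.Wx_f, self.Wh_f, self.b_f,
            self.Wx_b, self.Wh_b, self.b_b,
            self.W_out, self.b_out,
        ]

    @property
    def n_params(self) -> int:
        return int(sum(p.size for p in self.params))

    # ------------------------------------------------------------------
    def _run_dir(self, X, Wx, Wh, b, m_in, m_rec):
        B, T, C = X.shape
        H = self.spec.units
        h = np.zeros((B, H), self.dtype)
        c = np.zeros((B, H), self.dtype)
        cache = {
            "Xt": np.empty((T, B, C), self.dtype),
            "Hp": np.empty((T, B, H), self.dtype),
            "I": np.empty((T, B, H), self.dtype),
            "F": np.empty((T, B, H), self.dtype),
            "G": np.empty((T, B, H), self.dtype),
            "O": np.empty((T, B, H), self.dtype),
            "C": np.empty((T, B, H), self.dtype),
            "Cp": np.empty((T, B, H), self.dtype),
        }
        for t in range(T):
            xt = X[:, t] * m_in if m_in is not None else X[:, t]
            hp = h * m_rec if m_rec is not None else h
            z = xt @ Wx + hp @ Wh + b
            zi, zf, zg, zo = _split_gates(z, H)
            i, f, o = sigmoid(zi), sigmoid(zf), sigmoid(zo)
            g = np.tanh(zg)
            cache["Xt"][t], cache["Hp"][t] = xt, hp
            cache["Cp"][t] = c
            c = f * c + i * g
            h = o * np.tanh(c)
            cache["I"][t], cache["F"][t], cache["G"][t], cache["O"][t] = i, f, g, o
            cache["C"][t] = c
        return h, cache

    def _bptt_dir(self, cache, Wx, Wh, m_rec, dh_final):
        T, B, H = cache["I"].shape
        dWx = np.zeros_like(Wx)
        dWh = np.zeros_like(Wh)
        db = np.zeros(4 * H, Wx.dtype)
        dh = dh_final.astype(Wx.dtype)
        dc = np.zeros_like(dh)
        for t in range(T - 1, -1, -1):
            i, f, g, o = cache["I"][t], cache["F"][t], cache["G"][t], cache["O"][t]
            tc = np.tanh(cache["C"][t])
            do = dh * tc
            dc = dc + dh * o * (1.0 - tc * tc)
            di = dc * g
            df = dc * cache["Cp"][t]
            dg = dc * i
            dz = np.concatenate(
                [
                    di * i * (1 - i),
                    df * f * (1 - f),
                    dg * (1 - g * g),
                    do * o * (1 - o),
                ],
                axis=1,
            )
            dWx += cache["Xt"][t].T @ dz
            dWh += cache["Hp"][t].T @ dz
            db += dz.sum(axis=0)
            dh = dz @ Wh.T
            if m_rec is not None:
                dh = dh * m_rec
            dc = dc * f
        return dWx, dWh, db

    def forward(self, X, train: bool = False, rng: np.random.Generator | None = None):
        X = np.ascontiguousarray(X, dtype=self.dtype)
        B = X.shape[0]
        m = {}
        if train and rng is not None:
            p_in, p_rec = self.spec.dropout, self.spec.recurrent_dropout
            for d in ("f", "b"):
                m[f"in_{d}"] = (
                    (rng.random((B, self.n_channels)) >= p_in) / (1 - p_in)
                ).astype(self.dtype) if p_in > 0 else None
                m[f"rec_{d}"] = (
                    (rng.random((B, self.spec.units)) >= p_rec) / (1 - p_rec)
                ).astype(self.dtype) if p_rec > 0 else None
        else:
            m = {"in_f": None, "rec_f": None, "in_b": None, "rec_b": None}
        h_f, cache_f = self._run_dir(X, self.Wx_f, self.Wh_f, self.b_f, m["in_f"], m["rec_f"])
        Xr = X[:, ::-1]
        h_b, cache_b = self._run_dir(Xr, self.Wx_b, self.Wh_b, self.b_b, m["in_b"], m["rec_b"])
        hcat = np.concatenate([h_f, h_b], axis=1)
        logits = (hcat @ self.W_out).ravel() + self.b_out[0]
        cache = {"f": cache_f, "b": cache_b, "hcat": hcat, "masks": m}
        return logits.astype(np.float64), cache

    def backward(self, cache, dlogits):
        H = self.spec.units
        dz = np.asarray(dlogits, dtype=self.dtype)[:, None]  # (B,1)
        hcat = cache["hcat"]
        dW_out = hcat.T @ dz
        db_out = np.array([dz.sum()], dtype=self.dtype)
        dhcat = dz @ self.W_out.T
        m = cache["masks"]
        dWx_f, dWh_f, db_f = self._bptt_dir(
            cache["f"], self.Wx_f, self.Wh_f, m["rec_f"], dhcat[:, :H]
        )
        dWx_b, dWh_b, db_b = self._bptt_dir(
            cache["b"], self.Wx_b, self.Wh_b, m["rec_b"], dhcat[:, H:]
        )
        return [dWx_f, dWh_f, db_f, dWx_b, dWh_b, db_b, dW_out, db_out]

    # ------------------------------------------------------------------
    def predict_scores(
        self, X, batch_size: int = 512, logits: bool = False
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


def train_bilstm(
    tensors: np.ndarray,
    labels: np.ndarray,
    val_tensors: np.ndarray,
    val_labels: np.ndarray,
    spec: BiLSTMSpec | None = None,
    seed: int = 0,
) -> tuple[BiLSTMClassifier, dict]:
    """Train a BiLSTM on (n_windows, T, channels) standardized tensors."""
    tensors = np.asarray(tensors)
    if tensors.ndim != 3:
        raise ValueError("tensors must have shape (n_windows, T, channels)")
    if val_tensors.shape[1:] != tensors.shape[1:]:
        raise ValueError("validation tensors have inconsistent shape")
    model = BiLSTMClassifier(tensors.shape[-1], spec, seed=seed)
    history = model.fit(tensors, labels, val_tensors, val_labels)
    return model, history
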