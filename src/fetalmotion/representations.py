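"""The three inputs to the classifiers: hand-engineered feature vectors,
raw time-series tensors, and STFT magnitude spectrogram stacks.

Feature vector (75 per modality), canonical decomposition
---------------------------------------------------------
* 45: mean, standard deviation, range per sensor (5) per axis (3);
* 15: within-sensor Pearson correlations of axis pairs (xy, xz, yz) x 5;
* 12: maximum-magnitude normalized cross-correlation (over all lags inside
  the window) between each abdominal axis (4 sensors x 3 axes) and the same
  axis of the chest reference;
* 3:  Pearson correlation between each axis of the abdominal-mean signal and
  the same reference axis.

Degenerate (zero-variance) correlations map to 0, never NaN.

Time-series tensor: (64 samples, channels) for a 0.5 s window at 128 Hz;
channels are sensor-major (s0x, s0y, s0z, ..., s4z), acceleration channels
before gyroscope channels when modalities are combined (15 or 30 channels).

Spectrogram: per channel, a sliding 16-sample Hanning window with stride 1
over the 1024-sample (8 s) window; one-sided magnitudes give a
(9 bins, 1009 frames, channels) stack.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import correlate, get_window

__all__ = [
    "FEATURES_PER_MODALITY",
    "STFT_NPERSEG",
    "feature_names",
    "extract_features",
    "stack_window_tensor",
    "ChannelStandardizer",
    "compute_spectrogram",
    "SpectrogramNormalizer",
]

FEATURES_PER_MODALITY = 75
STFT_NPERSEG = 16
_AXES = ("x", "y", "z")
_AXIS_PAIRS = ((0, 1), (0, 2), (1, 2))


def feature_names(
    modality: str = "acc", n_sensors: int = 5, reference: int = 4
) -> list[str]:
    """Stable, ordered identifiers of the 75 features of one modality."""
    abdominal = [s for s in range(n_sensors) if s != reference]
    names: list[str] = []
    for s in range(n_sensors):
        for ax in _AXES:
            for stat in ("mean", "std", "range"):
                names.append(f"{modality}_s{s}_{ax}_{stat}")
    for s in range(n_sensors):
        for i, j in _AXIS_PAIRS:
            names.append(f"{modality}_s{s}_corr_{_AXES[i]}{_AXES[j]}")
    for s in abdominal:
        for ax in _AXES:
            names.append(f"{modality}_s{s}_{ax}_xcorr_ref")
    for ax in _AXES:
        names.append(f"{modality}_abdmean_{ax}_corr_ref")
    return names


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    sx, sy = x.std(), y.std()
    if sx == 0.0 or sy == 0.0:
        return 0.0
    return float(np.mean((x - x.mean()) * (y - y.mean())) / (sx * sy))


def _max_xcorr(x: np.ndarray, y: np.ndarray) -> float:
    """Signed normalized cross-correlation at the lag of maximum magnitude.

    Both signals are z-scored; the zero-padded full cross-correlation divided
    by the window length is bounded in [-1, 1] (Cauchy-Schwarz), and equals
    1.0 at lag 0 for identical signals.
    """
    sx, sy = x.std(), y.std()
    if sx == 0.0 or sy == 0.0:
        return 0.0
    xz = (x - x.mean()) / sx
    yz = (y - y.mean()) / sy
    c = correlate(xz, yz, mode="full") / x.size
    return float(c[np.argmax(np.abs(c))])


def extract_features(window: np.ndarray, reference: int = 4) -> np.ndarray:
    """75 features for one modality of one window.

    ``window`` has shape (n_sensors, 3, n_samples); ``reference`` indexes the
    chest sensor.  Raises on NaN input or windows of fewer than 2 samples.
    """
    w = np.asarray(window, dtype=float)
    if w.ndim != 3 or w.shape[1] != 3:
        raise ValueError("window must have shape (n_sensors, 3, n_samples)")
    if w.shape[-1] < 2:
        raise ValueError("window must contain at least 2 samples")
    if np.isnan(w).any():
        raise ValueError("window contains NaN")
    n_sensors = w.shape[0]
    abdominal = [s for s in range(n_sensors) if s != reference]

    feats: list[float] = []
    for s in range(n_sensors):
        for ax in range(3):
            x = w[s, ax]
            feats.extend((float(x.mean()), float(x.std()), float(np.ptp(x))))
    for s in range(n_sensors):
        for i, j in _AXIS_PAIRS:
            feats.append(_pearson(w[s, i], w[s, j]))
    for s in abdominal:
        for ax in range(3):
            feats.append(_max_xcorr(w[s, ax], w[reference, ax]))
    abd_mean = w[abdominal].mean(axis=0)  # (3, n)
    for ax in range(3):
        feats.append(_pearson(abd_mean[ax], w[reference, ax]))
    out = np.asarray(feats, dtype=float)
    assert out.size == FEATURES_PER_MODALITY
    return out


def stack_window_tensor(
    acc: np.ndarray | None, gyr: np.ndarray | None = None
) -> np.ndarray:
    """Flatten (n_sensors, 3, L) windows into an (L, channels) tensor.

    Pass one modality for 15 channels or both (acc first) for 30.
    """
    parts = []
    for arr in (acc, gyr):
        if arr is None:
            continue
        a = np.asarray(arr, dtype=float)
        if a.ndim != 3 or a.shape[1] != 3:
            raise ValueError("each modality must have shape (n_sensors, 3, L)")
        parts.append(a.reshape(-1, a.shape[-1]).T)  # (L, n_sensors*3)
    if not parts:
        raise ValueError("at least one modality required")
    if len(parts) == 2 and parts[0].shape[0] != parts[1].shape[0]:
        raise ValueError("modalities have different window lengths")
    return np.concatenate(parts, axis=1)


class ChannelStandardizer:
    """Per-channel standardization with statistics from the training set only."""

    def __init__(self) -> None:
        self.mean_: np.ndarray | None = None
        self.sd_: np.ndarray | None = None

    def fit(self, tensors: np.ndarray) -> "ChannelStandardizer":
        """``tensors``: (n_windows, L, channels) training windows."""
        x = np.asarray(tensors)
        self.mean_ = x.mean(axis=(0, 1))
        sd = x.std(axis=(0, 1))
        sd[sd == 0] = 1.0
        self.sd_ = sd
        return self

    def transform(self, tensors: np.ndarray) -> np.ndarray:
        if self.mean_ is None:
            raise RuntimeError("standardizer not fitted")
        return (np.asarray(tensors) - self.mean_) / self.sd_


def compute_spectrogram(window8s: np.ndarray, fs: float = 128.0) -> np.ndarray:
    """Magnitude spectrogram stack of one 8 s window.

    ``window8s``: (channels, 1024) or (n_sensors, 3, 1024) (flattened
    sensor-major).  A 16-sample periodic Hanning window slides with stride 1:
    1024 - 16 + 1 = 1009 frames, 16/2 + 1 = 9 one-sided bins spaced fs/16 =
    8 Hz apart.  Returns (9, 1009, channels) float32 magnitudes.
    """
    x = np.asarray(window8s, dtype=float)
    if x.ndim == 3:
        if x.shape[1] != 3:
            raise ValueError("expected (n_sensors, 3, n_samples)")
        x = x.reshape(-1, x.shape[-1])
    if x.ndim == 1:
        x = x[None, :]
    if x.ndim != 2:
        raise ValueError("window must be 1D, 2D or (n_sensors, 3, L)")
    expected = int(round(8.0 * fs))
    if x.shape[-1] != expected:
        raise ValueError(
            f"8 s window at fs={fs} must have {expected} samples per channel, "
            f"got {x.shape[-1]}"
        )
    win = get_window("hann", STFT_NPERSEG)  # periodic, standard for STFT
    frames = np.lib.stride_tricks.sliding_window_view(x, STFT_NPERSEG, axis=-1)
    spec = np.abs(np.fft.rfft(frames * win, axis=-1))  # (C, 1009, 9)
    return np.ascontiguousarray(spec.transpose(2, 1, 0)).astype(np.float32)


class SpectrogramNormalizer:
    """Per-channel max-abs scaling with statistics from the training set only."""

    def __init__(self) -> None:
        self.scale_: np.ndarray | None = None

    def fit(self, stacks: np.ndarray) -> "SpectrogramNormalizer":
        """``stacks``: (n_windows, bins, frames, channels) training windows."""
        x = np.asarray(stacks)
        scale = np.abs(x).max(axis=(0, 1, 2))
        scale[scale == 0] = 1.0
        self.scale_ = scale.astype(x.dtype)
        return self

    def transform(self, stacks: np.ndarray) -> np.ndarray:
        if self.scale_ is None:
            raise RuntimeError("normalizer not fitted")
        return np.asarray(stacks) / self.scale_
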