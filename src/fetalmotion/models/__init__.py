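"""The three classifiers (RF, BiLSTM, CNN) and score thresholding."""

from __future__ import annotations

import numpy as np

from .bilstm import BiLSTMClassifier, BiLSTMSpec, train_bilstm
from .cnn import CNNClassifier, CNNSpec, train_cnn
from .rf import RF_SEARCH_SPACE, RFModel, train_rf, vote_fraction

__all__ = [
    "classify",
    "train_rf", "RFModel", "RF_SEARCH_SPACE", "vote_fraction",
    "train_bilstm", "BiLSTMClassifier", "BiLSTMSpec",
    "train_cnn", "CNNClassifier", "CNNSpec",
]


def classify(scores: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Binary labels: 1 iff score >= threshold.

    The predicted-positive set is monotonically non-increasing in the
    threshold, which drives the threshold-sweep trends (sensitivity
    non-increasing, specificity non-decreasing).
    """
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must lie in (0, 1)")
    return (np.asarray(scores) >= threshold).astype(int)
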