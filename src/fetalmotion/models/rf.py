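"""Random forest on hand-engineered features.

Hyperparameters are chosen by random search, scored by F1 on the validation
split (threshold 0.5).  Window scores are the fraction of trees voting
positive, so the downstream thresholding literally tunes the majority vote.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import f1_score

__all__ = ["RF_SEARCH_SPACE", "RFModel", "train_rf", "vote_fraction"]

#: Random-search space (the study does not print one; standard ranges).
RF_SEARCH_SPACE: dict = {
    "n_estimators": (100, 500),        # inclusive integer range
    "max_depth": (None, 5, 30),        # None or integer in [5, 30]
    "min_samples_split": (2, 10),      # inclusive integer range
    "max_features": ("sqrt", "log2"),
}


def _draw_params(rng: np.random.Generator) -> dict:
    lo, hi = RF_SEARCH_SPACE["n_estimators"]
    params = {
        "n_estimators": int(rng.integers(lo, hi + 1)),
        "min_samples_split": int(
            rng.integers(
                RF_SEARCH_SPACE["min_samples_split"][0],
                RF_SEARCH_SPACE["min_samples_split"][1] + 1,
            )
        ),
        "max_features": str(rng.choice(RF_SEARCH_SPACE["max_features"])),
    }
    if rng.random() < 0.5:
        params["max_depth"] = None
    else:
        params["max_depth"] = int(
            rng.integers(RF_SEARCH_SPACE["max_depth"][1], RF_SEARCH_SPACE["max_depth"][2] + 1)
        )
    return params


def vote_fraction(clf: RandomForestClassifier, X: np.ndarray) -> np.ndarray:
    """Fraction of trees voting class 1, in [0, 1]."""
    votes = np.stack([tree.predict(np.asarray(X)) for tree in clf.estimators_])
    return votes.mean(axis=0)


@dataclass
class RFModel:
    classifier: RandomForestClassifier
    best_params: dict
    val_f1: float
    search_history: list = field(default_factory=list, repr=False)

    def predict_scores(self, X: np.ndarray) -> np.ndarray:
        return vote_fraction(self.classifier, X)


def train_rf(
    features: np.ndarray,
    labels: np.ndarray,
    val_features: np.ndarray,
    val_labels: np.ndarray,
    search_budget: int = 25,
    seed: int = 0,
) -> RFModel:
    """Random-search a forest, selecting by validation F1.

    Deterministic given ``seed`` (both the parameter draws and each forest's
    internal randomness derive from it).  Raises when the training labels
    contain a single class.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=int)
    if not np.isfinite(X).all():
        raise ValueError("features must be finite")
    if np.unique(y).size < 2:
        raise ValueError("training labels contain a single class")
    if search_budget < 1:
        raise ValueError("search_budget must be >= 1")
    rng = np.random.default_rng(seed)
    best: RFModel | None = None
    history = []
    for _ in range(search_budget):
        params = _draw_params(rng)
        clf = RandomForestClassifier(
            **params, random_state=int(rng.integers(2**31)), n_jobs=1
        )
        clf.fit(X, y)
        scores = vote_fraction(clf, val_features)
        f1 = float(f1_score(val_labels, (scores >= 0.5).astype(int), zero_division=0))
        history.append({**params, "val_f1": f1})
        if best is None or f1 > best.val_f1:
            best = RFModel(clf, params, f1)
    assert best is not None
    best.search_history = history
    return best
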