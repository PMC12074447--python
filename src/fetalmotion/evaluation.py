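"""Trial-level Monte Carlo cross-validation, metrics, paired tests, sweeps.

Splits are drawn at the trial level (subjects are never shared between
partitions), pre-selected before any training, and reused across all data
representations so the comparisons are paired.  AUROC is the Mann-Whitney
rank statistic with midrank tie handling (identical to the trapezoidal area
under the empirical ROC).  Ratio metrics with empty denominators are reported
as 0 and flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SplitPlan",
    "MetricsReport",
    "make_splits",
    "auroc",
    "compute_metrics",
    "paired_test",
    "threshold_sweep",
    "training_size_sweep",
    "DEFAULT_THRESHOLDS",
    "DEFAULT_FRACTIONS",
]

DEFAULT_THRESHOLDS = tuple(np.round(np.arange(0.1, 0.95, 0.1), 10))
DEFAULT_FRACTIONS = (0.25, 0.5, 0.75, 1.0)


@dataclass(frozen=True)
class SplitPlan:
    """One Monte Carlo split: disjoint test / validation / training trials."""

    split_id: int
    test_trials: tuple
    validation_trials: tuple
    training_trials: tuple

    def __post_init__(self):
        a = set(self.test_trials) | set(self.validation_trials) | set(self.training_trials)
        if len(a) != len(self.test_trials) + len(self.validation_trials) + len(
            self.training_trials
        ):
            raise ValueError("split partitions must be disjoint")


def make_splits(
    trial_ids,
    n_splits: int = 10,
    n_test: int = 6,
    n_val: int = 6,
    seed: int = 0,
) -> list[SplitPlan]:
    """Pre-select ``n_splits`` independent random splits.

    Within each split, trials are sampled without replacement: ``n_test`` for
    testing, ``n_val`` for validation, the remainder for training.
    """
    ids = list(trial_ids)
    if len(ids) < n_test + n_val + 1:
        raise ValueError(
            f"need at least {n_test + n_val + 1} trials, got {len(ids)}"
        )
    rng = np.random.default_rng(seed)
    plans = []
    for k in range(n_splits):
        perm = rng.permutation(len(ids))
        test = tuple(ids[i] for i in perm[:n_test])
        val = tuple(ids[i] for i in perm[n_test : n_test + n_val])
        train = tuple(ids[i] for i in perm[n_test + n_val :])
        plans.append(
            SplitPlan(
                split_id=k + 1,
                test_trials=test,
                validation_trials=val,
                training_trials=train,
            )
        )
    return plans


@dataclass
class MetricsReport:
    """The six metrics plus confusion counts.

    ``undefined`` names ratio metrics whose denominator was zero (reported
    as 0), e.g. PPV when no positives were predicted.
    """

    accuracy: float
    sensitivity: float
    specificity: float
    ppv: float
    f1: float
    auroc: float
    tp: int
    fp: int
    fn: int
    tn: int
    undefined: tuple[str, ...] = field(default_factory=tuple)

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def confusion_percent(self) -> dict[str, str]:
        """Cells formatted as percent of total with the raw count in
        parentheses, the study's confusion-matrix format."""
        out = {}
        for name in ("tp", "fp", "fn", "tn"):
            count = getattr(self, name)
            out[name] = f"{100.0 * count / self.total:.1f}% ({count})"
        return out

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy, "sensitivity": self.sensitivity,
            "specificity": self.specificity, "ppv": self.ppv, "f1": self.f1,
            "auroc": self.auroc, "tp": self.tp, "fp": self.fp,
            "fn": self.fn, "tn": self.tn, "undefined": list(self.undefined),
        }


def auroc(labels: np.ndarray, scores: np.ndarray) -> tuple[float, bool]:
    """Mann-Whitney rank AUROC with midrank ties.

    Returns (value, defined).  With a single class present the statistic is
    undefined; (0.5, False) is returned.
    """
    y = np.asarray(labels).astype(int)
    s = np.asarray(scores, dtype=float)
    n_pos = int(y.sum())
    n_neg = y.size - n_pos
    if n_pos == 0 or n_neg == 0:
        return 0.5, False
    ranks = stats.rankdata(s, method="average")
    u = ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg)), True


def compute_metrics(
    labels: np.ndarray, scores: np.ndarray, threshold: float = 0.5
) -> MetricsReport:
    """All metrics at one threshold; AUROC threshold-free."""
    y = np.asarray(labels).astype(int)
    s = np.asarray(scores, dtype=float)
    if y.size == 0:
        raise ValueError("empty input")
    if y.size != s.size:
        raise ValueError("labels and scores must have equal length")
    pred = (s >= threshold).astype(int)
    tp = int(np.sum((pred == 1) & (y == 1)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    fn = int(np.sum((pred == 0) & (y == 1)))
    tn = int(np.sum((pred == 0) & (y == 0)))
    undefined = []

    def ratio(num, den, name):
        if den == 0:
            undefined.append(name)
            return 0.0
        return num / den

    sens = ratio(tp, tp + fn, "sensitivity")
    spec = ratio(tn, tn + fp, "specificity")
    ppv = ratio(tp, tp + fp, "ppv")
    f1 = ratio(2 * ppv * sens, ppv + sens, "f1")
    acc = (tp + tn) / y.size
    au, defined = auroc(y, s)
    if not defined:
        undefined.append("auroc")
    return MetricsReport(
        accuracy=acc, sensitivity=sens, specificity=spec, ppv=ppv, f1=f1,
        auroc=au, tp=tp, fp=fp, fn=fn, tn=tn, undefined=tuple(undefined),
    )


def paired_test(
    metric_a: np.ndarray, metric_b: np.ndarray, kind: str = "t"
) -> float:
    """Two-sided paired test across splits.

    ``kind``: "t" (paired t-test, default) or "wilcoxon" (signed-rank).
    All-zero differences give p = 1.0; constant non-zero differences give
    p = 0.0 (the t statistic diverges).
    """
    a = np.asarray(metric_a, dtype=float)
    b = np.asarray(metric_b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("need two equal-length vectors of length >= 2")
    d = a - b
    if np.all(d == 0):
        return 1.0
    if np.std(d) <= 1e-12 * max(abs(d.mean()), 1e-300):
        return 0.0
    if kind == "t":
        return float(stats.ttest_rel(a, b).pvalue)
    if kind == "wilcoxon":
        return float(stats.wilcoxon(a, b, zero_method="wilcox").pvalue)
    raise ValueError(f"unknown test kind {kind!r}")


def threshold_sweep(
    scores: np.ndarray,
    labels: np.ndarray,
    thresholds=DEFAULT_THRESHOLDS,
) -> pd.DataFrame:
    """One metrics row per threshold (default grid 0.1..0.9 step 0.1)."""
    rows = []
    for th in thresholds:
        rep = compute_metrics(labels, scores, threshold=float(th))
        rows.append({"threshold": float(th), **rep.to_dict()})
    return pd.DataFrame(rows)


def training_size_sweep(
    run_fn,
    training_trials,
    fractions=DEFAULT_FRACTIONS,
    seed: int = 0,
) -> pd.DataFrame:
    """Re-run a pipeline at reduced training-set sizes.

    ``run_fn(train_subset)`` must train on exactly the given trials and
    return a :class:`MetricsReport` (or a mapping) on a FIXED test set.
    Subsampling is at the trial level; fraction 1.0 passes the full list
    unchanged, so it reproduces the full-data run exactly.
    """
    ids = list(training_trials)
    rng = np.random.default_rng(seed)
    perm = [ids[i] for i in rng.permutation(len(ids))]
    rows = []
    for frac in fractions:
        if not (0.0 < frac <= 1.0):
            raise ValueError("fractions must lie in (0, 1]")
        if frac == 1.0:
            subset = ids
        else:
            k = int(round(frac * len(ids)))
            if k == 0:
                raise ValueError(f"fraction {frac} yields zero training trials")
            subset = perm[:k]
        result = run_fn(subset)
        if isinstance(result, MetricsReport):
            result = result.to_dict()
        rows.append({"fraction": frac, "n_train_trials": len(subset), **dict(result)})
    return pd.DataFrame(rows)
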