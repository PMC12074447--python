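"""Splits, metrics, paired tests and sweeps."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import roc_auc_score

from fetalmotion.evaluation import (
    MetricsReport,
    auroc,
    compute_metrics,
    make_splits,
    paired_test,
    threshold_sweep,
    training_size_sweep,
)


class TestMakeSplits:
    def test_study_geometry(self):
        splits = make_splits(range(49), n_splits=10, seed=0)
        assert len(splits) == 10
        for sp in splits:
            assert len(sp.test_trials) == 6
            assert len(sp.validation_trials) == 6
            assert len(sp.training_trials) == 37
            all_ids = set(sp.test_trials) | set(sp.validation_trials) | set(
                sp.training_trials
            )
            assert all_ids == set(range(49))

    def test_deterministic(self):
        a = make_splits(range(49), n_splits=1, seed=3)
        b = make_splits(range(49), n_splits=1, seed=3)
        assert a[0] == b[0]

    def test_test_membership_roughly_uniform(self):
        counts = np.zeros(49)
        for seed in range(300):
            (sp,) = make_splits(range(49), n_splits=1, seed=seed)
            for t in sp.test_trials:
                counts[t] += 1
        expected = 300 * 6 / 49
        assert np.all(counts > expected * 0.5)
        assert np.all(counts < expected * 1.6)

    def test_too_few_trials(self):
        with pytest.raises(ValueError):
            make_splits(range(10), n_splits=1, n_test=6, n_val=6, seed=0)


class TestComputeMetrics:
    def test_perfect_scores(self):
        y = np.array([0, 1, 0, 1, 1])
        rep = compute_metrics(y, y.astype(float), 0.5)
        for name in ("accuracy", "sensitivity", "specificity", "ppv", "f1", "auroc"):
            assert getattr(rep, name) == 1.0

    def test_hand_computed_confusion_ratios(self):
        """TP=80 FP=53 FN=20 TN=247 reproduced to machine precision."""
        y = np.r_[np.ones(80), np.ones(20), np.zeros(53), np.zeros(247)]
        s = np.r_[np.full(80, 0.9), np.full(20, 0.1), np.full(53, 0.9), np.full(247, 0.1)]
        rep = compute_metrics(y, s, 0.5)
        assert (rep.tp, rep.fp, rep.fn, rep.tn) == (80, 53, 20, 247)
        assert abs(rep.sensitivity - 0.8) < 1e-12
        assert abs(rep.specificity - 247 / 300) < 1e-12
        assert abs(rep.ppv - 80 / 133) < 1e-12
        f1 = 2 * (80 / 133) * 0.8 / (80 / 133 + 0.8)
        assert abs(rep.f1 - f1) < 1e-12
        assert abs(rep.accuracy - 327 / 400) < 1e-12

    def test_constant_scores_auroc_half(self):
        rep = compute_metrics(np.array([0, 1, 1, 0]), np.full(4, 0.3), 0.5)
        assert rep.auroc == 0.5

    def test_zero_denominator_flagged(self):
        rep = compute_metrics(np.array([1, 1, 0]), np.zeros(3), 0.5)
        assert rep.sensitivity == 0.0
        assert "ppv" in rep.undefined

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            compute_metrics(np.array([]), np.array([]), 0.5)

    def test_confusion_percent_format(self):
        rep = compute_metrics(
            np.array([1, 0, 0, 0]), np.array([0.9, 0.9, 0.1, 0.1]), 0.5
        )
        cells = rep.confusion_percent()
        assert cells["tp"] == "25.0% (1)"
        total = sum(float(v.split("%")[0]) for v in cells.values())
        assert total == pytest.approx(100.0)

    def test_rank_auroc_equals_trapezoidal(self, rng):
        """Mann-Whitney midrank AUROC agrees with the trapezoidal ROC area
        (independent oracle: sklearn), including tied scores."""
        for _ in range(50):
            n = rng.integers(10, 200)
            y = rng.integers(0, 2, n)
            if y.min() == y.max():
                continue
            s = np.round(rng.random(n), 2)  # coarse grid forces ties
            assert abs(auroc(y, s)[0] - roc_auc_score(y, s)) < 1e-9

    def test_order_invariance(self, rng):
        y = rng.integers(0, 2, 100)
        s = rng.random(100)
        perm = rng.permutation(100)
        a = compute_metrics(y, s, 0.4)
        b = compute_metrics(y[perm], s[perm], 0.4)
        assert a == b


class TestPairedTest:
    def test_identical_gives_one(self):
        a = np.linspace(0.5, 0.9, 10)
        assert paired_test(a, a.copy()) == 1.0

    def test_constant_shift_significant(self):
        a = np.linspace(0.5, 0.6, 10)
        assert paired_test(a + 0.3, a) < 0.001

    def test_noisy_shift_significant(self, rng):
        a = 0.6 + 0.02 * rng.standard_normal(10)
        b = a + 0.1 + 0.005 * rng.standard_normal(10)
        assert paired_test(a, b) < 0.001

    def test_symmetry(self, rng):
        a, b = rng.random(10), rng.random(10)
        assert paired_test(a, b) == pytest.approx(paired_test(b, a))

    def test_wilcoxon_option(self, rng):
        a = rng.random(12)
        shift = 0.2 + 0.01 * rng.standard_normal(12)
        p = paired_test(a, a + shift, kind="wilcoxon")
        assert 0 < p < 0.01


class TestThresholdSweep:
    def test_nine_rows(self, rng):
        df = threshold_sweep(rng.random(50), rng.integers(0, 2, 50))
        assert len(df) == 9
        np.testing.assert_allclose(df["threshold"], np.arange(0.1, 0.95, 0.1))

    def test_monotone_sensitivity_specificity(self, rng):
        for _ in range(100):
            n = rng.integers(20, 100)
            y = rng.integers(0, 2, n)
            s = rng.random(n)
            df = threshold_sweep(s, y)
            assert np.all(np.diff(df["sensitivity"]) <= 1e-12)
            assert np.all(np.diff(df["specificity"]) >= -1e-12)

    def test_perfect_scores_all_rows_perfect(self):
        y = np.array([0, 1, 1, 0, 1])
        df = threshold_sweep(y.astype(float), y)
        assert np.all(df["f1"] == 1.0)
        assert df[["accuracy", "sensitivity", "specificity"]].nunique().max() == 1


class TestTrainingSizeSweep:
    def _run_fn_factory(self, calls):
        def run_fn(subset):
            calls.append(tuple(subset))
            return {"auroc": 0.5 + 0.01 * len(subset)}

        return run_fn

    def test_fraction_one_uses_full_set_unchanged(self):
        calls = []
        training = list(range(12))
        training_size_sweep(self._run_fn_factory(calls), training, (1.0,), seed=0)
        assert calls == [tuple(training)]

    def test_grid_shape(self):
        calls = []
        df = training_size_sweep(
            self._run_fn_factory(calls), list(range(12)), seed=0
        )
        assert len(df) == 4
        assert list(df["n_train_trials"]) == [3, 6, 9, 12]

    def test_zero_trial_fraction_rejected(self):
        with pytest.raises(ValueError):
            training_size_sweep(lambda s: {}, [1], (0.25,), seed=0)

    def test_subsets_nested_per_seed(self):
        calls = []
        training_size_sweep(
            self._run_fn_factory(calls), list(range(8)), (0.25, 0.5), seed=1
        )
        assert set(calls[0]) <= set(calls[1])


def test_metrics_report_roundtrip_dict():
    rep = compute_metrics(np.array([1, 0]), np.array([0.8, 0.1]), 0.5)
    d = rep.to_dict()
    assert d["tp"] == 1 and d["tn"] == 1
    assert isinstance(d["undefined"], list)
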