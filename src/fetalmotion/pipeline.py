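"""End-to-end orchestration: simulate -> preprocess -> label -> represent ->
train -> evaluate.

`run_experiment` is the in-memory driver used by the tests and the CLI: it
simulates a cohort, preprocesses every trial, builds the representations each
requested model needs, and evaluates every (model, modality, split)
combination on pre-selected Monte Carlo splits shared across representations.

`run_pipeline` is the cached, file-backed variant behind `fetalmotion all`:
each stage writes its outputs (HDF5 signals, CSV labels/metrics, JSON
configs/splits) stamped with the config hash, and a stage whose outputs
already exist for the same hash is skipped.

Memory note: spectrogram stacks are (9, 1009, channels) float32 per 8 s
window, so cohort size x trial duration is the knob that controls the
footprint; see docs/methods.md for desk-scale guidance.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as fio
from .evaluation import (
    DEFAULT_THRESHOLDS,
    SplitPlan,
    compute_metrics,
    make_splits,
    threshold_sweep,
    training_size_sweep,
)
from .labeling import (
    label_windows,
    presses_to_events,
    rebalance_indices,
    segment,
    windows_to_frame,
)
from .models import BiLSTMSpec, CNNSpec, train_bilstm, train_cnn, train_rf
from .preprocessing import FilterSpec, preprocess_trial
from .representations import (
    ChannelStandardizer,
    SpectrogramNormalizer,
    compute_spectrogram,
    extract_features,
    stack_window_tensor,
)
from .synthetic import CalibrationRecording, SimConfig, TrialRecording, make_cohort

__all__ = [
    "RunConfig",
    "TrialDataset",
    "build_trial_dataset",
    "run_experiment",
    "run_training_size_sweep",
    "run_pipeline",
]

SHORT_WINDOW = 0.5   # s, RF + BiLSTM windows, no overlap
LONG_WINDOW = 8.0    # s, CNN windows
LONG_STRIDE = 1.0    # s


@dataclass
class RunConfig:
    """Everything needed to reproduce a run (fully serializable)."""

    sim: SimConfig = field(default_factory=SimConfig)
    filter: FilterSpec = field(default_factory=FilterSpec)
    n_trials: int = 49
    seed: int = 0
    overlap_frac: float = 0.1
    drop_fraction: float = 2.0 / 3.0
    n_splits: int = 10
    n_test: int = 6
    n_val: int = 6
    modalities: tuple = ("acc", "gyr", "combined")
    models: tuple = ("rf", "bilstm", "cnn")
    rf_search_budget: int = 25
    bilstm: BiLSTMSpec = field(default_factory=BiLSTMSpec)
    cnn: CNNSpec = field(default_factory=CNNSpec)
    threshold: float = 0.5
    thresholds: tuple = DEFAULT_THRESHOLDS

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(fio._jsonable(self)))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw)
        if "sim" in raw:
            sim = dict(raw["sim"])
            if sim.get("mounting_rotations") is not None:
                sim["mounting_rotations"] = np.asarray(sim["mounting_rotations"])
            if "event_band" in sim:
                sim["event_band"] = tuple(sim["event_band"])
            raw["sim"] = SimConfig(**sim)
        if "filter" in raw:
            raw["filter"] = FilterSpec(**raw["filter"])
        if "bilstm" in raw:
            raw["bilstm"] = BiLSTMSpec(**raw["bilstm"])
        if "cnn" in raw:
            raw["cnn"] = CNNSpec(**raw["cnn"])
        for key in ("modalities", "models", "thresholds"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    @property
    def digest(self) -> str:
        return fio.config_hash(self)


@dataclass
class TrialDataset:
    """All representations of one preprocessed trial."""

    trial_id: int
    short_labels: np.ndarray           # (n_short,)
    long_labels: np.ndarray            # (n_long,)
    features: np.ndarray | None        # (n_short, 150) acc block then gyr block
    tensors: np.ndarray | None         # (n_short, 64, 30) acc channels then gyr
    spectrograms: np.ndarray | None    # (n_long, 9, 1009, 30) float32
    short_frame: pd.DataFrame = field(repr=False, default=None)
    long_frame: pd.DataFrame = field(repr=False, default=None)


def _window_slices(trial: TrialRecording, grid) -> list[slice]:
    n_win = int(round(grid.window_len * trial.fs))
    out = []
    for s in grid.starts:
        i0 = int(round(s * trial.fs))
        out.append(slice(i0, i0 + n_win))
    return out


def build_trial_dataset(
    trial: TrialRecording,
    calib: CalibrationRecording,
    trial_id: int,
    filter_spec: FilterSpec | None = None,
    overlap_frac: float = 0.1,
    need_features: bool = True,
    need_tensors: bool = True,
    need_spectrograms: bool = True,
) -> TrialDataset:
    """Preprocess one trial and materialize the requested representations."""
    proc = preprocess_trial(trial, calib, filter_spec)
    events = presses_to_events(proc.press_times)

    short_grid = segment(proc, SHORT_WINDOW, SHORT_WINDOW)
    long_grid = segment(proc, LONG_WINDOW, LONG_STRIDE)
    short_labels = label_windows(
        short_grid, events, overlap_frac, proc.fs, proc.duration
    )
    long_labels = label_windows(long_grid, events, overlap_frac, proc.fs, proc.duration)

    features = tensors = spectrograms = None
    ref = proc.reference_index
    if need_features or need_tensors:
        slices = _window_slices(proc, short_grid)
        if need_features:
            features = np.stack(
                [
                    np.concatenate(
                        [
                            extract_features(proc.acc[:, :, sl], ref),
                            extract_features(proc.gyr[:, :, sl], ref),
                        ]
                    )
                    for sl in slices
                ]
            )
        if need_tensors:
            tensors = np.stack(
                [
                    stack_window_tensor(proc.acc[:, :, sl], proc.gyr[:, :, sl])
                    for sl in slices
                ]
            )
    if need_spectrograms:
        slices = _window_slices(proc, long_grid)
        spectrograms = np.stack(
            [
                np.concatenate(
                    [
                        compute_spectrogram(proc.acc[:, :, sl], proc.fs),
                        compute_spectrogram(proc.gyr[:, :, sl], proc.fs),
                    ],
                    axis=-1,
                )
                for sl in slices
            ]
        )
    return TrialDataset(
        trial_id=trial_id,
        short_labels=short_labels,
        long_labels=long_labels,
        features=features,
        tensors=tensors,
        spectrograms=spectrograms,
        short_frame=windows_to_frame(short_grid, short_labels, trial_id),
        long_frame=windows_to_frame(long_grid, long_labels, trial_id),
    )


# ---------------------------------------------------------------------------
# modality slicing

_N_SHORT_FEATS = 75
_N_CHANNELS = 15  # per modality: 5 sensors x 3 axes


def _slice_modality(X: np.ndarray, modality: str, kind: str) -> np.ndarray:
    if modality == "combined":
        return X
    if kind == "features":
        return X[:, :_N_SHORT_FEATS] if modality == "acc" else X[:, _N_SHORT_FEATS:]
    # tensors: (n, T, 30); spectrograms: (n, 9, 1009, 30) -- channels last
    return X[..., :_N_CHANNELS] if modality == "acc" else X[..., _N_CHANNELS:]


def _gather(datasets: dict[int, TrialDataset], ids, attr: str) -> np.ndarray:
    return np.concatenate([getattr(datasets[i], attr) for i in ids])


# ---------------------------------------------------------------------------
# experiment driver

def _train_score_one(
    datasets: dict[int, TrialDataset],
    split: SplitPlan,
    model: str,
    modality: str,
    *,
    drop_fraction: float,
    rebalance_seed: int,
    model_seed: int,
    rf_search_budget: int,
    bilstm_spec: BiLSTMSpec | None,
    cnn_spec: CNNSpec | None,
) -> np.ndarray:
    """Train one model on one modality for one split; return test scores."""
    long = model == "cnn"
    label_attr = "long_labels" if long else "short_labels"
    data_attr = {"rf": "features", "bilstm": "tensors", "cnn": "spectrograms"}[model]
    kind = {"rf": "features", "bilstm": "tensors", "cnn": "spectrograms"}[model]

    y_tr = _gather(datasets, split.training_trials, label_attr)
    y_va = _gather(datasets, split.validation_trials, label_attr)
    y_te = _gather(datasets, split.test_trials, label_attr)
    X_tr = _slice_modality(_gather(datasets, split.training_trials, data_attr), modality, kind)
    X_va = _slice_modality(_gather(datasets, split.validation_trials, data_attr), modality, kind)
    X_te = _slice_modality(_gather(datasets, split.test_trials, data_attr), modality, kind)

    keep = rebalance_indices(y_tr, drop_fraction, seed=rebalance_seed)
    X_tr, y_tr = X_tr[keep], y_tr[keep]

    if model == "rf":
        rf = train_rf(X_tr, y_tr, X_va, y_va, search_budget=rf_search_budget, seed=model_seed)
        return rf.predict_scores(X_te)
    if model == "bilstm":
        std = ChannelStandardizer().fit(X_tr)
        net, _ = train_bilstm(
            std.transform(X_tr), y_tr, std.transform(X_va), y_va,
            spec=bilstm_spec, seed=model_seed,
        )
        return net.predict_scores(std.transform(X_te))
    if model == "cnn":
        norm = SpectrogramNormalizer().fit(X_tr)
        net, _ = train_cnn(
            norm.transform(X_tr), y_tr, norm.transform(X_va), y_va,
            spec=cnn_spec, seed=model_seed,
        )
        return net.predict_scores(norm.transform(X_te))
    raise ValueError(f"unknown model {model!r}")


def run_experiment(
    config: RunConfig,
    return_scores: bool = False,
    datasets: dict[int, TrialDataset] | None = None,
    splits: list[SplitPlan] | None = None,
):
    """Full comparative experiment on a simulated cohort.

    Returns a tidy DataFrame with one row per (model, modality, split) and
    the six metrics at ``config.threshold``; with ``return_scores`` also a
    dict (model, modality, split_id) -> (test labels, scores).
    """
    ss = np.random.SeedSequence(config.seed).generate_state(4)
    if datasets is None:
        cohort = make_cohort(config.n_trials, config.sim, config.seed)
        datasets = {
            i: build_trial_dataset(
                trial, calib, i,
                filter_spec=config.filter,
                overlap_frac=config.overlap_frac,
                need_features="rf" in config.models,
                need_tensors="bilstm" in config.models,
                need_spectrograms="cnn" in config.models,
            )
            for i, (trial, truth, calib) in enumerate(cohort)
        }
    if splits is None:
        splits = make_splits(
            sorted(datasets), config.n_splits, config.n_test, config.n_val,
            seed=int(ss[1]),
        )
    rows = []
    scores_out = {}
    for split in splits:
        for model in config.models:
            for modality in config.modalities:
                scores = _train_score_one(
                    datasets, split, model, modality,
                    drop_fraction=config.drop_fraction,
                    rebalance_seed=int((ss[2] + split.split_id) % 2**31),
                    model_seed=int((ss[3] + split.split_id) % 2**31),
                    rf_search_budget=config.rf_search_budget,
                    bilstm_spec=config.bilstm,
                    cnn_spec=config.cnn,
                )
                label_attr = "long_labels" if model == "cnn" else "short_labels"
                y_te = _gather(datasets, split.test_trials, label_attr)
                rep = compute_metrics(y_te, scores, config.threshold)
                rows.append(
                    {
                        "model": model, "modality": modality,
                        "split_id": split.split_id, **rep.to_dict(),
                    }
                )
                if return_scores:
                    scores_out[(model, modality, split.split_id)] = (y_te, scores)
    df = pd.DataFrame(rows)
    if return_scores:
        return df, scores_out, splits
    return df


def run_training_size_sweep(
    config: RunConfig,
    datasets: dict[int, TrialDataset],
    split: SplitPlan,
    model: str,
    modality: str = "combined",
    fractions=(0.25, 0.5, 0.75, 1.0),
) -> pd.DataFrame:
    """Training-size sweep for one model on one split (fixed test set)."""
    ss = np.random.SeedSequence(config.seed).generate_state(4)

    def run_fn(train_subset):
        sub = SplitPlan(
            split_id=split.split_id,
            test_trials=split.test_trials,
            validation_trials=split.validation_trials,
            training_trials=tuple(train_subset),
        )
        scores = _train_score_one(
            datasets, sub, model, modality,
            drop_fraction=config.drop_fraction,
            rebalance_seed=int((ss[2] + split.split_id) % 2**31),
            model_seed=int((ss[3] + split.split_id) % 2**31),
            rf_search_budget=config.rf_search_budget,
            bilstm_spec=config.bilstm,
            cnn_spec=config.cnn,
        )
        label_attr = "long_labels" if model == "cnn" else "short_labels"
        y_te = _gather(datasets, sub.test_trials, label_attr)
        return compute_metrics(y_te, scores, config.threshold)

    df = training_size_sweep(
        run_fn, split.training_trials, fractions, seed=int(ss[2])
    )
    df.insert(0, "modality", modality)
    df.insert(0, "model", model)
    return df


# ---------------------------------------------------------------------------
# file-backed pipeline (CLI `all`)

def _stage_fresh(stage_dir: Path, digest: str) -> bool:
    manifest = stage_dir / "manifest.json"
    if not manifest.exists():
        return False
    return fio.read_json(manifest).get("config_hash") == digest


def _write_manifest(stage_dir: Path, digest: str, stage: str, extra: dict | None = None) -> None:
    payload = {"config_hash": digest, "stage": stage}
    if extra:
        payload.update(extra)
    fio.write_json(stage_dir / "manifest.json", payload)


def run_pipeline(config: RunConfig, out_dir) -> dict:
    """Run every stage, writing provenance-stamped artifacts under ``out_dir``.

    Re-running with the same config reuses the cached simulation stage and
    reproduces bit-identical label CSVs and split plans.
    """
    out = Path(out_dir)
    digest = config.digest
    (out / "trials").mkdir(parents=True, exist_ok=True)
    (out / "labels").mkdir(exist_ok=True)
    (out / "results").mkdir(exist_ok=True)
    config.to_yaml(out / "config.yaml")

    # --- stage 1: simulate -------------------------------------------------
    trials_dir = out / "trials"
    if not _stage_fresh(trials_dir, digest):
        cohort = make_cohort(config.n_trials, config.sim, config.seed)
        for i, (trial, truth, calib) in enumerate(cohort):
            fio.write_trial(trials_dir / f"trial_{i:03d}.h5", trial, digest)
            fio.write_calibration(trials_dir / f"calib_{i:03d}.h5", calib, digest)
            fio.write_ground_truth(trials_dir / f"truth_{i:03d}.json", truth)
        _write_manifest(trials_dir, digest, "simulate", {"n_trials": config.n_trials})

    # --- stage 2: preprocess + label + represent ---------------------------
    datasets: dict[int, TrialDataset] = {}
    for i in range(config.n_trials):
        trial_path = trials_dir / f"trial_{i:03d}.h5"
        calib_path = trials_dir / f"calib_{i:03d}.h5"
        if not calib_path.exists():
            raise FileNotFoundError(
                f"stage preprocess: missing calibration file for trial {i} "
                f"({calib_path})"
            )
        trial = fio.read_trial(trial_path, expect_hash=digest)
        calib = fio.read_calibration(calib_path, expect_hash=digest)
        datasets[i] = build_trial_dataset(
            trial, calib, i,
            filter_spec=config.filter,
            overlap_frac=config.overlap_frac,
            need_features="rf" in config.models,
            need_tensors="bilstm" in config.models,
            need_spectrograms="cnn" in config.models,
        )
    labels_dir = out / "labels"
    pd.concat([d.short_frame for d in datasets.values()]).to_csv(
        labels_dir / "windows_short.csv", index=False
    )
    pd.concat([d.long_frame for d in datasets.values()]).to_csv(
        labels_dir / "windows_long.csv", index=False
    )
    _write_manifest(labels_dir, digest, "label")

    # --- stage 3: train + evaluate -----------------------------------------
    results_dir = out / "results"
    df, scores, splits = run_experiment(
        config, return_scores=True, datasets=datasets
    )
    df.to_csv(results_dir / "metrics.csv", index=False)
    fio.write_json(
        results_dir / "splits.json",
        {
            "config_hash": digest,
            "splits": [
                {
                    "split_id": s.split_id,
                    "test_trials": list(s.test_trials),
                    "validation_trials": list(s.validation_trials),
                    "training_trials": list(s.training_trials),
                }
                for s in splits
            ],
        },
    )
    summary = (
        df.groupby(["model", "modality"])[
            ["accuracy", "sensitivity", "specificity", "ppv", "f1", "auroc"]
        ]
        .median()
        .reset_index()
    )
    summary.to_csv(results_dir / "summary.csv", index=False)

    # threshold sweep on the first split's combined-modality scores
    sweeps = []
    for model in config.models:
        key = (model, "combined" if "combined" in config.modalities else config.modalities[0], splits[0].split_id)
        if key in scores:
            y, s = scores[key]
            sw = threshold_sweep(s, y, config.thresholds)
            sw.insert(0, "model", model)
            sweeps.append(sw)
    if sweeps:
        pd.concat(sweeps).to_csv(results_dir / "threshold_sweep.csv", index=False)
    _write_manifest(results_dir, digest, "evaluate")
    return {
        "out_dir": str(out),
        "config_hash": digest,
        "metrics": df,
        "summary": summary,
    }
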