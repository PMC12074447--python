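"""File formats: HDF5 containers for signals, JSON sidecars for ground truth
and configuration, with bit-exact round trips and config-hash provenance."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import h5py
import numpy as np

from .synthetic import CalibrationRecording, GroundTruth, TrialRecording

__all__ = [
    "write_trial", "read_trial",
    "write_calibration", "read_calibration",
    "write_ground_truth", "read_ground_truth",
    "config_hash", "write_json", "read_json",
]

_FORMAT_VERSION = "1"


def write_trial(path, trial: TrialRecording, config_digest: str | None = None) -> None:
    """One self-describing HDF5 file per trial (acc/gyr datasets + metadata)."""
    with h5py.File(path, "w") as f:
        f.attrs["format_version"] = _FORMAT_VERSION
        f.attrs["kind"] = "trial"
        f.attrs["fs"] = trial.fs
        f.attrs["abdominal_indices"] = list(trial.abdominal_indices)
        f.attrs["reference_index"] = trial.reference_index
        if config_digest is not None:
            f.attrs["config_hash"] = config_digest
        f.create_dataset("acc", data=trial.acc)
        f.create_dataset("gyr", data=trial.gyr)
        f.create_dataset("press_times", data=np.asarray(trial.press_times, dtype=float))


def read_trial(path, expect_hash: str | None = None) -> TrialRecording:
    with h5py.File(path, "r") as f:
        _check_hash(f, path, expect_hash)
        if f.attrs.get("kind") != "trial":
            raise ValueError(f"{path} is not a trial file")
        return TrialRecording(
            acc=f["acc"][...],
            gyr=f["gyr"][...],
            fs=float(f.attrs["fs"]),
            press_times=f["press_times"][...],
            abdominal_indices=tuple(int(i) for i in f.attrs["abdominal_indices"]),
            reference_index=int(f.attrs["reference_index"]),
        )


def write_calibration(
    path, calib: CalibrationRecording, config_digest: str | None = None
) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["format_version"] = _FORMAT_VERSION
        f.attrs["kind"] = "calibration"
        f.attrs["fs"] = calib.fs
        if config_digest is not None:
            f.attrs["config_hash"] = config_digest
        f.create_dataset("acc", data=calib.acc)
        f.create_dataset("gyr", data=calib.gyr)
        f.create_dataset("phase_bounds", data=np.asarray(calib.phase_bounds, dtype=int))


def read_calibration(path, expect_hash: str | None = None) -> CalibrationRecording:
    with h5py.File(path, "r") as f:
        _check_hash(f, path, expect_hash)
        if f.attrs.get("kind") != "calibration":
            raise ValueError(f"{path} is not a calibration file")
        return CalibrationRecording(
            acc=f["acc"][...],
            gyr=f["gyr"][...],
            fs=float(f.attrs["fs"]),
            phase_bounds=f["phase_bounds"][...],
        )


def _check_hash(f: h5py.File, path, expect_hash: str | None) -> None:
    if expect_hash is not None:
        found = f.attrs.get("config_hash")
        if found != expect_hash:
            raise ValueError(
                f"{path}: config hash mismatch (file {found!r}, expected "
                f"{expect_hash!r}); refusing to mix artifacts across configs"
            )


def write_ground_truth(path, truth: GroundTruth) -> None:
    payload = {
        "event_onsets": list(map(float, truth.event_onsets)),
        "event_durations": list(map(float, truth.event_durations)),
        "event_sensors": [list(map(int, s)) for s in truth.event_sensors],
        "press_times": list(map(float, truth.press_times)),
    }
    write_json(path, payload)


def read_ground_truth(path) -> GroundTruth:
    d = read_json(path)
    return GroundTruth(
        event_onsets=np.asarray(d["event_onsets"], dtype=float),
        event_durations=np.asarray(d["event_durations"], dtype=float),
        event_sensors=[list(s) for s in d["event_sensors"]],
        press_times=np.asarray(d["press_times"], dtype=float),
    )


def write_json(path, payload: dict) -> None:
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def read_json(path) -> dict:
    return json.loads(Path(path).read_text())


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def config_hash(config) -> str:
    """Stable digest of a configuration (dataclass or mapping)."""
    canonical = json.dumps(_jsonable(config), sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()[:16]
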