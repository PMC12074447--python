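"""Zero-phase bandpass filtering and functional axis alignment.

All signals pass through a 1-20 Hz zero-phase Butterworth bandpass (drift and
high-frequency noise removal without group delay).  Gyroscope axes are then
rotated into a common anatomical frame estimated from the calibration
recording: the x-axis from the static gravity vector, the y-axis from the
dominant rotation axis of the hip hinges (the frontal axis), the z-axis
(sagittal) as their cross product.  Acceleration axes are deliberately left
unaligned so that tangential abdominal-deformation components survive.
Alignment is estimated from RAW calibration data: bandpassing first would
destroy the DC gravity component the gravity axis is read from.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, sosfiltfilt

from .synthetic import GRAVITY, CalibrationRecording, TrialRecording

__all__ = [
    "FilterSpec",
    "AlignmentTransform",
    "bandpass_zero_phase",
    "estimate_alignment",
    "apply_alignment",
    "preprocess_trial",
]


@dataclass(frozen=True)
class FilterSpec:
    """Bandpass design: 4th-order Butterworth, applied forward-backward
    (effective 8th order, zero phase)."""

    low_cut: float = 1.0
    high_cut: float = 20.0
    order: int = 4
    design: str = "butter"

    def validate(self, fs: float) -> None:
        if not (0.0 < self.low_cut < self.high_cut < fs / 2.0):
            raise ValueError(
                f"require 0 < low_cut < high_cut < fs/2, got "
                f"({self.low_cut}, {self.high_cut}) at fs={fs}"
            )
        if self.design != "butter":
            raise ValueError(f"unsupported filter design {self.design!r}")


@dataclass
class AlignmentTransform:
    """Per-sensor rotation, columns = anatomical axes in sensor coordinates.

    Column 1: unit gravity direction (anatomical x); column 2: frontal axis;
    column 3: sagittal axis.  Applying ``R.T`` to a sensor-frame vector gives
    its anatomical-frame components.
    """

    rotations: np.ndarray  # (n_sensors, 3, 3)

    def __post_init__(self) -> None:
        R = np.asarray(self.rotations, dtype=float)
        if R.ndim != 3 or R.shape[1:] != (3, 3):
            raise ValueError("rotations must have shape (n_sensors, 3, 3)")
        for i, r in enumerate(R):
            if not np.allclose(r.T @ r, np.eye(3), atol=1e-6):
                raise ValueError(f"alignment rotation {i} is not orthonormal")
            if np.linalg.det(r) < 0:
                raise ValueError(f"alignment rotation {i} is left-handed")
        self.rotations = R

    @property
    def n_sensors(self) -> int:
        return self.rotations.shape[0]


def _min_signal_length(spec: FilterSpec) -> int:
    # sosfiltfilt needs strictly more samples than the pad length; with
    # odd-reflection padding of 3x the effective (doubled) order:
    return 3 * 2 * spec.order + 1


def bandpass_zero_phase(
    signal: np.ndarray, fs: float, spec: FilterSpec | None = None
) -> np.ndarray:
    """Zero-phase bandpass along the last axis.

    Same length as the input, no phase distortion, DC rejected.  Raises for
    signals shorter than the odd-reflection padding.
    """
    spec = spec or FilterSpec()
    spec.validate(fs)
    x = np.asarray(signal, dtype=float)
    padlen = _min_signal_length(spec) - 1
    if x.shape[-1] <= padlen:
        raise ValueError(
            f"signal too short for zero-phase filtering: need at least "
            f"{padlen + 1} samples, got {x.shape[-1]}"
        )
    sos = butter(
        spec.order, [spec.low_cut, spec.high_cut], btype="bandpass", output="sos", fs=fs
    )
    return sosfiltfilt(sos, x, axis=-1, padtype="odd", padlen=padlen)


def estimate_alignment(calib: CalibrationRecording) -> AlignmentTransform:
    """Estimate each sensor's anatomical orientation from raw calibration data.

    Gravity axis: mean static-phase accelerometer direction (errors if its
    magnitude is >20% off g -- the sensor was not static).  Frontal axis:
    principal axis of the hinge-phase gyroscope covariance, orthogonalized
    against gravity, signed so the first-half hinge rotation (the forward
    lean) is positive.  Sagittal axis: right-handed cross product.
    """
    n_sensors = calib.acc.shape[0]
    hinge = np.concatenate(
        [calib.gyr[:, :, calib.hinge_slice(k)] for k in range(3)], axis=-1
    )
    first_half = np.concatenate(
        [
            calib.gyr[
                :,
                :,
                calib.hinge_slice(k).start : (
                    calib.hinge_slice(k).start + calib.hinge_slice(k).stop
                )
                // 2,
            ]
            for k in range(3)
        ],
        axis=-1,
    )
    rotations = np.empty((n_sensors, 3, 3))
    for s in range(n_sensors):
        g_vec = calib.acc[s, :, calib.static_slice].mean(axis=-1)
        g_mag = np.linalg.norm(g_vec)
        if abs(g_mag - GRAVITY) > 0.2 * GRAVITY:
            raise ValueError(
                f"sensor {s} not static during calibration: mean accelerometer "
                f"magnitude {g_mag:.2f} m/s^2 deviates >20% from g"
            )
        x_axis = g_vec / g_mag

        w = hinge[s]
        rms = np.sqrt(np.mean(w**2))
        if rms < 1e-3:
            raise ValueError(
                f"sensor {s}: degenerate hinge rotation (angular rate RMS "
                f"{rms:.2e} rad/s)"
            )
        cov = w @ w.T / w.shape[-1]
        eigval, eigvec = np.linalg.eigh(cov)
        y_axis = eigvec[:, -1]
        # Gram-Schmidt against gravity.
        y_axis = y_axis - (y_axis @ x_axis) * x_axis
        n_y = np.linalg.norm(y_axis)
        if n_y < 1e-6:
            raise ValueError(f"sensor {s}: hinge axis parallel to gravity")
        y_axis /= n_y
        # Forward lean positive: integral of the first half of each hinge.
        if np.sum(first_half[s].T @ y_axis) < 0:
            y_axis = -y_axis
        z_axis = np.cross(x_axis, y_axis)
        rotations[s] = np.column_stack([x_axis, y_axis, z_axis])
    return AlignmentTransform(rotations=rotations)


def apply_alignment(gyr: np.ndarray, transform: AlignmentTransform) -> np.ndarray:
    """Rotate per-sensor gyroscope signals into the anatomical frame.

    ``gyr`` has shape (n_sensors, 3, n_samples); a sample-wise isometry, so
    per-sample norms are preserved.
    """
    gyr = np.asarray(gyr, dtype=float)
    if gyr.ndim != 3 or gyr.shape[1] != 3:
        raise ValueError("gyr must have shape (n_sensors, 3, n_samples)")
    if gyr.shape[0] != transform.n_sensors:
        raise ValueError(
            f"missing alignment transform: {gyr.shape[0]} sensors but "
            f"{transform.n_sensors} transforms"
        )
    # aligned = R^T @ v for each sensor and sample
    return np.einsum("sji,sjn->sin", transform.rotations, gyr)


def preprocess_trial(
    trial: TrialRecording,
    calib: CalibrationRecording | AlignmentTransform,
    filter_spec: FilterSpec | None = None,
) -> TrialRecording:
    """Full preprocessing of one trial: bandpass both modalities, then align
    the (filtered) gyroscope axes.  Acceleration axes stay unaligned."""
    transform = (
        calib if isinstance(calib, AlignmentTransform) else estimate_alignment(calib)
    )
    acc = bandpass_zero_phase(trial.acc, trial.fs, filter_spec)
    gyr = bandpass_zero_phase(trial.gyr, trial.fs, filter_spec)
    gyr = apply_alignment(gyr, transform)
    return dataclasses.replace(trial, acc=acc, gyr=gyr)
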