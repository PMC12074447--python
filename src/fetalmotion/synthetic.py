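"""Synthetic multi-IMU maternal-abdomen recordings with ground-truth fetal events.

The generator reproduces the statistical structure the downstream analysis
relies on, not fetal physiology:

* five tri-axial IMUs (four abdominal, one chest reference) sampled
  synchronously at 128 Hz, each reporting linear acceleration (m/s^2) and
  angular rate (rad/s) in its own mounting frame;
* maternal torso motion modelled as a single rigid body: one shared global
  angular-rate signal, rotated into every sensor frame, plus gravity
  re-projected through the (small-angle) torso orientation;
* fetal movements as short band-limited damped bursts added only to the
  abdominal sensors in each event's footprint -- the localized deformation
  that breaks the rigid-body assumption and carries the discriminative signal;
* maternal perception as a thinned, delayed point process: each true event
  produces a button press with probability ``p_perceive`` (default 0.4) after
  a truncated-normal reaction delay;
* a functional-calibration segment: static standing followed by three hip
  hinges (forward lean about the frontal axis).

Randomness is split into independent named streams spawned from the seed so
that, e.g., disabling fetal events leaves the maternal motion and the noise
bit-identical (the locality property tested in the suite).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

__all__ = [
    "GRAVITY",
    "G_GLOBAL",
    "SimConfig",
    "GroundTruth",
    "TrialRecording",
    "CalibrationRecording",
    "simulate_trial",
    "simulate_calibration",
    "make_cohort",
    "random_rotation",
]

GRAVITY = 9.81
#: Global gravity direction: the anatomical x-axis is aligned with gravity.
G_GLOBAL = np.array([GRAVITY, 0.0, 0.0])

_N_SENSORS = 5
#: Default spread of random mounting rotations (rad) when none are supplied.
#: Sensors are deliberately aligned at mounting (x along gravity, z
#: perpendicular to the abdomen), so only a small placement error remains.
_DEFAULT_MOUNT_ANGLE = 0.1

# Calibration phase durations (s): static standing, then three hip hinges.
_STATIC_DUR = 5.0
_HINGE_DUR = 4.0
_HINGE_ANGLE = 0.7  # peak forward-lean angle (rad), ~40 degrees

#: Shortest trial the pipeline can window (the 8 s spectrogram window).
MIN_TRIAL_DURATION = 8.0


@dataclass
class SimConfig:
    """Parameters of the simulated world.

    Defaults follow the study protocol where it states a value (128 Hz
    sampling, ~40% maternal perception, 10-15 min seated trials) and otherwise
    sit at magnitudes realistic for a seated pregnant participant wearing
    consumer-grade IMUs; see docs/methods.md for the reasoning.
    """

    fs: float = 128.0
    trial_duration: float = 600.0
    n_abdominal: int = 4
    event_rate: float = 0.05                 # fetal events per second
    event_cluster_factor: float = 2.0        # mean events per perceived cluster
    event_amplitude_acc: float = 0.25        # m/s^2
    event_amplitude_gyr: float = 0.08        # rad/s
    event_band: tuple[float, float] = (2.0, 10.0)  # Hz
    event_footprint: int = 2                 # max abdominal sensors per burst
    maternal_burst_rate: float = 0.1         # shared torso movements per second
    maternal_amplitude: float = 0.4          # rad/s angular, m/s^2 linear scale
    p_perceive: float = 0.4
    reaction_delay_mean: float = 0.6         # s
    reaction_delay_sd: float = 0.3           # s, truncated to [0, 3.5]
    noise_sd_acc: float = 0.03               # m/s^2 white noise
    noise_sd_gyr: float = 0.01               # rad/s white noise
    drift_scale: float = 0.05                # m/s^2 low-frequency drift
    mounting_rotations: np.ndarray | None = None  # (5, 3, 3) sensor<-global

    @property
    def n_sensors(self) -> int:
        return self.n_abdominal + 1

    @property
    def reference_index(self) -> int:
        """Index of the chest reference sensor (last)."""
        return self.n_abdominal

    @property
    def n_samples(self) -> int:
        return int(round(self.fs * self.trial_duration))

    def validate(self) -> None:
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.trial_duration < MIN_TRIAL_DURATION:
            raise ValueError(
                f"trial_duration {self.trial_duration} s is too short to contain "
                f"one {MIN_TRIAL_DURATION} s analysis window"
            )
        if not (0.0 <= self.p_perceive <= 1.0):
            raise ValueError("p_perceive must lie in [0, 1]")
        lo, hi = self.event_band
        if not (0.0 < lo < hi < self.fs / 2.0):
            raise ValueError(
                f"event_band {self.event_band} must lie inside (0, fs/2)="
                f"(0, {self.fs / 2.0})"
            )
        if self.n_abdominal < 1:
            raise ValueError("need at least one abdominal sensor")
        if not (1 <= self.event_footprint <= self.n_abdominal):
            raise ValueError("event_footprint must be in [1, n_abdominal]")
        if self.mounting_rotations is not None:
            R = np.asarray(self.mounting_rotations, dtype=float)
            if R.shape != (self.n_sensors, 3, 3):
                raise ValueError(
                    f"mounting_rotations must have shape ({self.n_sensors}, 3, 3)"
                )
            for i, r in enumerate(R):
                if not np.allclose(r.T @ r, np.eye(3), atol=1e-9):
                    raise ValueError(f"mounting rotation {i} is not orthonormal")


@dataclass
class GroundTruth:
    """True fetal events of one simulated trial (simulation-only knowledge)."""

    event_onsets: np.ndarray       # (n_events,) s
    event_durations: np.ndarray    # (n_events,) s
    event_sensors: list[list[int]]  # per-event affected abdominal sensor indices
    press_times: np.ndarray        # (n_presses,) s, perceived events + delay


@dataclass
class TrialRecording:
    """Synchronized 5-sensor x 3-axis x 2-modality recording."""

    acc: np.ndarray          # (n_sensors, 3, n_samples) m/s^2
    gyr: np.ndarray          # (n_sensors, 3, n_samples) rad/s
    fs: float
    press_times: np.ndarray  # (n_presses,) s
    abdominal_indices: tuple[int, ...] = (0, 1, 2, 3)
    reference_index: int = 4

    @property
    def n_samples(self) -> int:
        return self.acc.shape[-1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs


@dataclass
class CalibrationRecording:
    """Static standing + three hip hinges, same signal layout as a trial.

    ``phase_bounds`` holds five sample indices delimiting the four phases:
    [static_start, hinge1_start, hinge2_start, hinge3_start, end].
    """

    acc: np.ndarray
    gyr: np.ndarray
    fs: float
    phase_bounds: np.ndarray  # (5,) int

    @property
    def static_slice(self) -> slice:
        return slice(int(self.phase_bounds[0]), int(self.phase_bounds[1]))

    def hinge_slice(self, k: int) -> slice:
        if not 0 <= k < 3:
            raise IndexError("hinge index must be 0, 1 or 2")
        return slice(int(self.phase_bounds[1 + k]), int(self.phase_bounds[2 + k]))


def random_rotation(rng: np.random.Generator, max_angle: float = np.pi) -> np.ndarray:
    """Rotation matrix about a uniformly random axis by angle ~ U(0, max_angle)."""
    axis = rng.standard_normal(3)
    axis /= np.linalg.norm(axis)
    angle = rng.uniform(0.0, max_angle)
    return _axis_angle(axis, angle)


def _axis_angle(axis: np.ndarray, angle: float) -> np.ndarray:
    """Rodrigues rotation matrix."""
    k = np.asarray(axis, dtype=float)
    k = k / np.linalg.norm(k)
    K = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    return np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)


def _streams(seed: int, names: tuple[str, ...]) -> dict[str, np.random.Generator]:
    """Independent named substreams of a single seed."""
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


def _mounting(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    if config.mounting_rotations is not None:
        return np.asarray(config.mounting_rotations, dtype=float)
    return np.stack(
        [random_rotation(rng, _DEFAULT_MOUNT_ANGLE) for _ in range(config.n_sensors)]
    )


def _maternal_motion(
    config: SimConfig, rng: np.random.Generator, n: int
) -> tuple[np.ndarray, np.ndarray]:
    """Shared torso angular rate (rad/s) and linear acceleration (m/s^2).

    Occasional smooth low-frequency (<= 2 Hz) movement bursts: seated
    participants shift posture, rub the abdomen, reach for a snack.  Each
    burst rotates the torso about a random axis and pushes it along a random
    direction with a Hann envelope.

    The angular-rate amplitude of a burst scales with its carrier frequency
    (constant angular excursion): a seated torso sways by a few degrees
    regardless of how fast, so slow bursts must not integrate into large
    tilts.  ``maternal_amplitude`` is the peak angular rate (rad/s) of a
    2 Hz burst and the peak linear acceleration (m/s^2) of any burst.
    """
    fs = config.fs
    omega = np.zeros((3, n))
    lin = np.zeros((3, n))
    duration = n / fs
    n_bursts = rng.poisson(config.maternal_burst_rate * duration)
    for _ in range(n_bursts):
        t0 = rng.uniform(0.0, duration)
        dur = rng.uniform(1.0, 4.0)
        f = rng.uniform(0.3, 2.0)
        scale = rng.uniform(0.5, 1.0)
        amp_rot = config.maternal_amplitude * scale * (f / 2.0)
        amp_lin = config.maternal_amplitude * scale
        i0 = int(round(t0 * fs))
        i1 = min(n, i0 + int(round(dur * fs)))
        if i1 <= i0:
            continue
        tt = np.arange(i1 - i0) / fs
        envelope = np.sin(np.pi * tt / dur) ** 2
        carrier = np.sin(2 * np.pi * f * tt + rng.uniform(0, 2 * np.pi))
        rot_axis = rng.standard_normal(3)
        rot_axis /= np.linalg.norm(rot_axis)
        lin_axis = rng.standard_normal(3)
        lin_axis /= np.linalg.norm(lin_axis)
        omega[:, i0:i1] += amp_rot * np.outer(rot_axis, envelope * carrier)
        lin[:, i0:i1] += amp_lin * np.outer(lin_axis, envelope * carrier)
    return omega, lin


def _leaky_integral(x: np.ndarray, fs: float, tau: float = 5.0) -> np.ndarray:
    """Leaky cumulative integral along the last axis (keeps drift bounded)."""
    from scipy.signal import lfilter

    a = np.exp(-1.0 / (tau * fs))
    return lfilter([1.0 / fs], [1.0, -a], x, axis=-1)


def _sample_events(
    config: SimConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Onsets and durations of fetal events.

    A Neyman-Scott cluster process: parent "activity episodes" arrive as a
    Poisson process of rate ``event_rate / event_cluster_factor``; each parent
    spawns Poisson(``event_cluster_factor``) events jittered within ~10 s.
    The marginal mean rate is exactly ``event_rate``, while the counts are
    over-dispersed -- fetal movements tend to occur in clusters.
    """
    T = config.trial_duration
    m = max(config.event_cluster_factor, 1e-9)
    n_parents = rng.poisson(config.event_rate / m * T)
    onsets = []
    for _ in range(n_parents):
        center = rng.uniform(0.0, T)
        for _ in range(rng.poisson(m)):
            t = center + rng.uniform(0.0, 10.0)
            if 0.0 <= t <= T:
                onsets.append(t)
    onsets = np.sort(np.asarray(onsets, dtype=float))
    durations = rng.uniform(0.3, 1.5, size=onsets.size)
    return onsets, durations


def _burst_waveform(
    duration: float, freq: float, fs: float, phase: float
) -> np.ndarray:
    """Exponentially damped sinusoid, the canonical short transient."""
    n = int(round(duration * fs))
    tt = np.arange(n) / fs
    tau = duration / 3.0
    return np.exp(-tt / tau) * np.sin(2 * np.pi * freq * tt + phase)


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, low: float, high: float
) -> float:
    if sd <= 0:
        return float(np.clip(mean, low, high))
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if low <= x <= high:
            return float(x)
    return float(np.clip(mean, low, high))


def simulate_trial(config: SimConfig, seed: int) -> tuple[TrialRecording, GroundTruth]:
    """Simulate one seated trial.

    Returns the recording (what a real session would yield, including press
    timestamps) and the ground truth (what only the simulation knows).
    """
    config.validate()
    streams = _streams(
        int(seed), ("mounting", "maternal", "events", "noise", "perception")
    )
    n = config.n_samples
    fs = config.fs
    R = _mounting(config, streams["mounting"])

    # --- shared rigid-body maternal motion -------------------------------
    omega_g, lin_g = _maternal_motion(config, streams["maternal"], n)
    # Small-angle torso orientation; gravity seen by the torso tilts with it.
    theta = _leaky_integral(omega_g, fs)
    g_torso = G_GLOBAL[:, None] - np.cross(theta.T, G_GLOBAL).T
    base_acc = g_torso + lin_g     # (3, n), torso frame ~ global frame
    base_gyr = omega_g

    # Rotate the single shared torso signal into each sensor's mounting frame.
    acc = np.einsum("sij,jn->sin", R, base_acc)
    gyr = np.einsum("sij,jn->sin", R, base_gyr)

    # --- fetal events: localized bursts on footprint sensors only --------
    ev_rng = streams["events"]
    onsets, durations = _sample_events(config, ev_rng)
    event_sensors: list[list[int]] = []
    for onset, dur in zip(onsets, durations):
        k = int(ev_rng.integers(1, config.event_footprint + 1))
        sensors = sorted(
            int(s)
            for s in ev_rng.choice(config.n_abdominal, size=k, replace=False)
        )
        event_sensors.append(sensors)
        i0 = int(round(onset * fs))
        freq = ev_rng.uniform(*config.event_band)
        scale = ev_rng.uniform(0.5, 1.5)
        # Movements differ in character: a kick is acceleration-dominant, a
        # roll rotation-dominant.  The mixing angle keeps the mean-square
        # burst energy constant while making the modalities complementary.
        phi = ev_rng.uniform(0.0, np.pi / 2.0)
        acc_w = np.sqrt(2.0) * np.sin(phi)
        gyr_w = np.sqrt(2.0) * np.cos(phi)
        for s in sensors:
            w = _burst_waveform(dur, freq, fs, ev_rng.uniform(0, 2 * np.pi))
            i1 = min(n, i0 + w.size)
            if i1 <= i0:
                continue
            dir_acc = ev_rng.standard_normal(3)
            dir_acc /= np.linalg.norm(dir_acc)
            dir_gyr = ev_rng.standard_normal(3)
            dir_gyr /= np.linalg.norm(dir_gyr)
            seg = w[: i1 - i0]
            acc[s, :, i0:i1] += (
                config.event_amplitude_acc * scale * acc_w * np.outer(dir_acc, seg)
            )
            gyr[s, :, i0:i1] += (
                config.event_amplitude_gyr * scale * gyr_w * np.outer(dir_gyr, seg)
            )

    # --- drift and white noise ------------------------------------------
    nz = streams["noise"]
    if config.drift_scale > 0:
        t = np.arange(n) / fs
        for arr, scale in ((acc, config.drift_scale), (gyr, config.drift_scale / 10)):
            for s in range(config.n_sensors):
                for ax in range(3):
                    f1, f2 = nz.uniform(0.01, 0.2, size=2)
                    p1, p2 = nz.uniform(0, 2 * np.pi, size=2)
                    arr[s, ax] += scale * (
                        np.sin(2 * np.pi * f1 * t + p1)
                        + 0.5 * np.sin(2 * np.pi * f2 * t + p2)
                    )
    if config.noise_sd_acc > 0:
        acc += nz.normal(0.0, config.noise_sd_acc, size=acc.shape)
    if config.noise_sd_gyr > 0:
        gyr += nz.normal(0.0, config.noise_sd_gyr, size=gyr.shape)

    # --- maternal perception --------------------------------------------
    p_rng = streams["perception"]
    presses = []
    for onset in onsets:
        if p_rng.random() < config.p_perceive:
            delay = _truncated_normal(
                p_rng,
                config.reaction_delay_mean,
                config.reaction_delay_sd,
                0.0,
                3.5,
            )
            press = onset + delay
            if press <= config.trial_duration:
                presses.append(press)
    press_times = np.asarray(presses, dtype=float)

    trial = TrialRecording(
        acc=acc,
        gyr=gyr,
        fs=fs,
        press_times=press_times,
        abdominal_indices=tuple(range(config.n_abdominal)),
        reference_index=config.reference_index,
    )
    truth = GroundTruth(
        event_onsets=onsets,
        event_durations=durations,
        event_sensors=event_sensors,
        press_times=press_times,
    )
    return trial, truth


def simulate_calibration(config: SimConfig, seed: int) -> CalibrationRecording:
    """Simulate the functional-calibration segment.

    Static standing (gravity only) followed by three hip hinges: the torso
    rotates about the global frontal (y) axis by up to ~40 degrees, forward
    then back, so the hinge angular velocity integrates to a positive forward
    lean over each first half-repetition.
    """
    config.validate()
    streams = _streams(int(seed), ("mounting", "maternal", "events", "noise", "perception"))
    fs = config.fs
    R = _mounting(config, streams["mounting"])

    n_static = int(round(_STATIC_DUR * fs))
    n_hinge = int(round(_HINGE_DUR * fs))
    n = n_static + 3 * n_hinge
    phase_bounds = np.array(
        [0, n_static, n_static + n_hinge, n_static + 2 * n_hinge, n], dtype=int
    )

    theta = np.zeros(n)
    for k in range(3):
        i0 = n_static + k * n_hinge
        tt = np.arange(n_hinge) / fs
        theta[i0 : i0 + n_hinge] = _HINGE_ANGLE / 2 * (1 - np.cos(2 * np.pi * tt / _HINGE_DUR))
    theta_dot = np.gradient(theta) * fs

    omega_g = np.zeros((3, n))
    omega_g[1] = theta_dot  # rotation about the global frontal (y) axis

    # Gravity in the torso frame: rotate the global gravity by -theta about y.
    cos_t, sin_t = np.cos(theta), np.sin(theta)
    g_torso = np.zeros((3, n))
    g_torso[0] = GRAVITY * cos_t
    g_torso[2] = -GRAVITY * sin_t

    acc = np.einsum("sij,jn->sin", R, g_torso)
    gyr = np.einsum("sij,jn->sin", R, omega_g)

    nz = streams["noise"]
    if config.noise_sd_acc > 0:
        acc += nz.normal(0.0, config.noise_sd_acc, size=acc.shape)
    if config.noise_sd_gyr > 0:
        gyr += nz.normal(0.0, config.noise_sd_gyr, size=gyr.shape)

    return CalibrationRecording(acc=acc, gyr=gyr, fs=fs, phase_bounds=phase_bounds)


def make_cohort(
    n_trials: int, config: SimConfig, seed: int
) -> list[tuple[TrialRecording, GroundTruth, CalibrationRecording]]:
    """Generate ``n_trials`` independent trials with per-trial calibration.

    Per-trial seeds are spawned deterministically from the master seed.  When
    the config leaves mounting rotations unspecified, each trial draws its own
    (shared between its calibration and its recording, as for a re-mounted
    session).
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    config.validate()
    cohort = []
    for child in np.random.SeedSequence(int(seed)).spawn(n_trials):
        mount_seed, calib_seed, trial_seed = child.generate_state(3, dtype=np.uint32)
        cfg = config
        if config.mounting_rotations is None:
            rng = np.random.default_rng(int(mount_seed))
            R = np.stack(
                [random_rotation(rng, _DEFAULT_MOUNT_ANGLE) for _ in range(config.n_sensors)]
            )
            cfg = dataclasses.replace(config, mounting_rotations=R)
        calib = simulate_calibration(cfg, int(calib_seed))
        trial, truth = simulate_trial(cfg, int(trial_seed))
        cohort.append((trial, truth, calib))
    return cohort
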