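"""Press-to-event conversion, window segmentation, overlap labeling,
and training-set rebalancing.

A fetal-movement event is the interval from 3.5 s before to 1.5 s after each
button press (reaction time before, movement duration after).  Trials are cut
into fixed windows on a grid anchored at t=0; a window is positive iff its
overlap with the union of event intervals exceeds 10% of the window length,
measured at exact sample resolution with a strict inequality.  Training
partitions are rebalanced by discarding two-thirds of negative windows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "PRE_PRESS",
    "POST_PRESS",
    "EventInterval",
    "WindowGrid",
    "presses_to_events",
    "union_intervals",
    "segment",
    "label_windows",
    "windows_to_frame",
    "rebalance_training",
    "rebalance_indices",
]

PRE_PRESS = 3.5   # s before a press included in the event
POST_PRESS = 1.5  # s after a press included in the event


@dataclass(frozen=True)
class EventInterval:
    """One fetal-movement event, [start, end) in trial seconds."""

    start: float
    end: float

    @property
    def length(self) -> float:
        return self.end - self.start


@dataclass(frozen=True)
class WindowGrid:
    """Fixed-size windows on a regular grid anchored at t=0.

    ``starts[i] = i * stride``; the final partial window is dropped.
    """

    starts: np.ndarray  # (n_windows,) s
    window_len: float   # s
    stride: float       # s

    @property
    def n_windows(self) -> int:
        return self.starts.size


def presses_to_events(press_times: np.ndarray) -> list[EventInterval]:
    """One interval [t - 3.5, t + 1.5] per press; overlaps are kept as-is."""
    return [EventInterval(float(t) - PRE_PRESS, float(t) + POST_PRESS) for t in np.asarray(press_times, dtype=float)]


def union_intervals(events: list[EventInterval]) -> list[EventInterval]:
    """Union of possibly overlapping intervals, sorted and disjoint."""
    if not events:
        return []
    ordered = sorted(events, key=lambda e: e.start)
    merged = [[ordered[0].start, ordered[0].end]]
    for e in ordered[1:]:
        if e.start <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e.end)
        else:
            merged.append([e.start, e.end])
    return [EventInterval(a, b) for a, b in merged]


def segment(duration: "float | object", window_len: float, stride: float) -> WindowGrid:
    """Window grid for a trial (pass the trial object or its duration in s).

    Windows start at 0 and advance by ``stride``; the last window must fit
    entirely inside the trial.
    """
    if stride <= 0:
        raise ValueError("stride must be positive")
    if hasattr(duration, "duration"):
        duration = duration.duration
    duration = float(duration)
    if window_len > duration:
        raise ValueError(
            f"window_len {window_len} s exceeds trial duration {duration} s"
        )
    n = int(np.floor((duration - window_len) / stride + 1e-9)) + 1
    starts = np.arange(n) * stride
    return WindowGrid(starts=starts, window_len=float(window_len), stride=float(stride))


def label_windows(
    grid: WindowGrid,
    events: list[EventInterval],
    overlap_frac: float = 0.1,
    fs: float = 128.0,
    trial_duration: float | None = None,
) -> np.ndarray:
    """Binary labels: 1 iff the window's event overlap strictly exceeds
    ``overlap_frac`` of the window length.

    Overlap is counted on the sampling grid: sample i (at time i/fs) belongs
    to an event iff it falls in [start, end) of the union of event intervals
    clipped to the trial.  The window holds samples
    [round(start*fs), round(start*fs) + round(window_len*fs)).
    """
    if not (0.0 < overlap_frac < 1.0):
        raise ValueError("overlap_frac must lie in (0, 1)")
    n_windows = grid.n_windows
    labels = np.zeros(n_windows, dtype=np.int8)
    if not events:
        return labels
    window_samples = int(round(grid.window_len * fs))
    if trial_duration is None:
        trial_duration = float(grid.starts[-1] + grid.window_len)
    n_samples = int(round(trial_duration * fs)) + 1
    times = np.arange(n_samples) / fs
    mask = np.zeros(n_samples, dtype=bool)
    for e in union_intervals(events):
        a = max(e.start, 0.0)
        b = min(e.end, trial_duration)
        if b > a:
            mask |= (times >= a) & (times < b)
    csum = np.concatenate([[0], np.cumsum(mask)])
    starts = np.round(grid.starts * fs).astype(int)
    ends = np.minimum(starts + window_samples, n_samples)
    counts = csum[ends] - csum[starts]
    labels[:] = counts > overlap_frac * window_samples
    return labels


def windows_to_frame(
    grid: WindowGrid, labels: np.ndarray, trial_id: "int | str"
) -> pd.DataFrame:
    """Tabulate labeled windows with provenance (one row per window)."""
    return pd.DataFrame(
        {
            "trial_id": trial_id,
            "window_start_s": grid.starts,
            "window_len_s": grid.window_len,
            "label": np.asarray(labels, dtype=int),
            "grid_index": np.arange(grid.n_windows),
        }
    )


def rebalance_indices(
    labels: np.ndarray, drop_fraction: float = 2.0 / 3.0, seed: int = 0
) -> np.ndarray:
    """Indices kept after discarding ``drop_fraction`` of negatives uniformly
    at random.  All positives are retained; order is preserved."""
    if not (0.0 <= drop_fraction < 1.0):
        raise ValueError("drop_fraction must lie in [0, 1)")
    labels = np.asarray(labels)
    pos = np.flatnonzero(labels == 1)
    neg = np.flatnonzero(labels == 0)
    if pos.size == 0:
        warnings.warn("no positive windows; returning the set unchanged")
        return np.arange(labels.size)
    n_remove = int(np.rint(drop_fraction * neg.size))
    rng = np.random.default_rng(seed)
    removed = rng.choice(neg, size=n_remove, replace=False)
    keep = np.setdiff1d(np.arange(labels.size), removed)
    return keep


def rebalance_training(
    windows: pd.DataFrame, drop_fraction: float = 2.0 / 3.0, seed: int = 0
) -> pd.DataFrame:
    """Rebalance a TRAINING window table (as from :func:`windows_to_frame`).

    Discards round(drop_fraction * n_negatives) negative rows uniformly at
    random; never touches positives or labels.  Deterministic under ``seed``.
    """
    keep = rebalance_indices(windows["label"].to_numpy(), drop_fraction, seed)
    return windows.iloc[keep].reset_index(drop=True)
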