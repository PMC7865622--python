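"""Repetition segmentation and per-set fatigue summaries.

A concentration-curl repetition runs trough to trough on a motion channel:
troughs mark the release position, the single peak in between marks full
contraction.  Within each set boundary the smoothed channel is scanned for
prominent peaks; the boundary between two repetitions is placed at the
centre of the low plateau (release hold) separating consecutive peaks.

Segmentation defaults to the total acceleration (the Euclidean norm of the
accelerometer triad) rather than a single axis: the norm is invariant to how
the device is mounted on the wrist, whereas any one axis mixes with the
others under an orientation change and can develop spurious local maxima.

Two per-set summaries quantify fatigue accumulation: completion time (mean
repetition duration per set, as a percentage increase over the first main
set) and muscular endurance (mean peak-to-trough amplitude of a gyroscope
channel, as a percentage change over the first main set).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .signals import total_acceleration
from .simulate import SessionRecording

__all__ = [
    "Repetition",
    "detect_repetitions",
    "completion_time_table",
    "endurance_change_table",
    "average_change",
]

logger = logging.getLogger(__name__)

DEFAULT_CHANNEL = "total_acceleration"
DEFAULT_SMOOTHING_WINDOW = 0.3    # s, moving average before extrema detection
DEFAULT_MIN_SEPARATION = 1.0      # s, minimum peak-to-peak distance
DEFAULT_PROMINENCE_FRACTION = 0.05  # of the set's signal range
_PLATEAU_FRACTION = 0.05          # of local relief; defines the trough plateau


@dataclass(frozen=True)
class Repetition:
    """One detected curl: a half-open sample slice of a session."""

    subject_id: str
    arm: str
    set_index: int       # 0 = warm-up
    rep_index: int       # 0-based within the set
    start: int           # inclusive sample index
    end: int             # exclusive sample index
    duration: float      # s, (end - start) / sampling_rate

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)


def _moving_average(x: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return x.astype(float)
    kernel = np.ones(window) / window
    # reflect-pad so the smoothed trace keeps the array length without edge bias
    pad = window // 2
    padded = np.concatenate([x[pad:0:-1], x, x[-2:-2 - pad:-1]])
    sm = np.convolve(padded, kernel, mode="same")
    return sm[pad:pad + len(x)]


def _plateau_trough(xs: np.ndarray, p1: int, p2: int) -> int:
    """Centre of the low plateau between two peaks of the smoothed signal.

    The raw minimum of a noisy flat valley is an arbitrary sample; taking
    the median index of all samples within a small fraction of the local
    relief localizes the boundary at the middle of the release hold.
    """
    seg = xs[p1:p2 + 1]
    lo = seg.min()
    relief = min(xs[p1], xs[p2]) - lo
    eps = lo + _PLATEAU_FRACTION * relief
    idx = np.flatnonzero(seg <= eps)
    return p1 + int(np.median(idx))


def detect_repetitions(
    session: SessionRecording,
    channel: str = DEFAULT_CHANNEL,
    smoothing_window: float = DEFAULT_SMOOTHING_WINDOW,
    min_separation: float = DEFAULT_MIN_SEPARATION,
    prominence_fraction: float = DEFAULT_PROMINENCE_FRACTION,
) -> list[Repetition]:
    """Segment every set of a session into trough-to-trough repetitions.

    Each set boundary is processed independently; a set whose channel is
    flat (no prominent peak) contributes zero repetitions and a warning
    rather than an error.
    """
    if session.n_samples == 0:
        raise ValueError("session has no samples")
    fs = session.sampling_rate
    window = max(1, int(round(smoothing_window * fs)))
    distance = max(1, int(round(min_separation * fs)))
    if channel == "total_acceleration" and channel not in session.samples.columns:
        values = total_acceleration(
            session.samples["acc_x"], session.samples["acc_y"], session.samples["acc_z"]
        )
    elif channel in session.samples.columns:
        values = session.samples[channel].to_numpy(dtype=float)
    else:
        raise ValueError(f"channel {channel!r} not in session samples")

    reps: list[Repetition] = []
    for set_index, (s0, s1) in enumerate(session.set_boundaries):
        xs = _moving_average(values[s0:s1], window)
        relief = xs.max() - xs.min() if len(xs) else 0.0
        if relief <= 0:
            logger.warning(
                "set %d of %s/%s: flat channel %s, no repetitions detected",
                set_index, session.subject_id, session.arm, channel,
            )
            continue
        peaks, _ = find_peaks(xs, prominence=prominence_fraction * relief,
                              distance=distance)
        if len(peaks) == 0:
            logger.warning(
                "set %d of %s/%s: no prominent peaks on channel %s",
                set_index, session.subject_id, session.arm, channel,
            )
            continue
        bounds = [0]
        bounds.extend(
            _plateau_trough(xs, peaks[i], peaks[i + 1])
            for i in range(len(peaks) - 1)
        )
        bounds.append(len(xs))
        for r in range(len(peaks)):
            start, end = s0 + bounds[r], s0 + bounds[r + 1]
            reps.append(Repetition(
                subject_id=session.subject_id,
                arm=session.arm,
                set_index=set_index,
                rep_index=r,
                start=start,
                end=end,
                duration=(end - start) / fs,
            ))
    return reps


def average_change(per_set_changes: Sequence[float]) -> float:
    """Across-set average of per-set percentage changes (the Avg. cell)."""
    arr = np.asarray(list(per_set_changes), dtype=float)
    return float(np.nanmean(arr))


def _per_set_table(per_set_values: dict[int, float]) -> pd.DataFrame:
    """Percent change of each main set relative to the first main set."""
    sets = sorted(k for k in per_set_values if k >= 1)
    if 1 not in per_set_values or not np.isfinite(per_set_values[1]):
        raise ValueError("first main set has no repetitions; no reference value")
    ref = per_set_values[1]
    rows = []
    for k in sets:
        v = per_set_values[k]
        pct = 100.0 * (v - ref) / ref if np.isfinite(v) else np.nan
        rows.append({"set": k, "value": v, "pct_change": pct})
    table = pd.DataFrame(rows).set_index("set")
    later = table.loc[table.index >= 2, "pct_change"]
    table.loc["avg", "pct_change"] = average_change(later) if len(later) else np.nan
    return table


def completion_time_table(reps: Sequence[Repetition]) -> pd.DataFrame:
    """Per-main-set mean repetition duration and its % increase over set 1.

    Returns a table indexed by main-set number (1-based, warm-up excluded)
    with columns ``value`` (mean duration, s) and ``pct_change``; the final
    ``avg`` row averages the increases of sets 2 onward.
    """
    durations: dict[int, list[float]] = {}
    for rep in reps:
        if rep.set_index >= 1:
            durations.setdefault(rep.set_index, []).append(rep.duration)
    per_set = {k: float(np.mean(v)) if v else np.nan for k, v in durations.items()}
    missing = [k for k, v in per_set.items() if not np.isfinite(v)]
    if missing:
        logger.warning("sets %s have no repetitions; entries reported missing", missing)
    return _per_set_table(per_set)


def endurance_change_table(
    session: SessionRecording,
    reps: Sequence[Repetition],
    channel: str = "gyr_x",
    smoothing_window: float = 0.0,
) -> pd.DataFrame:
    """Per-main-set mean peak-to-trough amplitude of ``channel`` and its
    % change over set 1 (angular-velocity proxy for muscular endurance).

    Amplitudes are taken on the raw channel by default: smoothing attenuates
    sharp (fatigued) contraction peaks more than broad ones and would bias
    the between-set comparison.
    """
    if channel not in session.samples.columns:
        raise ValueError(f"channel {channel!r} not in session samples")
    fs = session.sampling_rate
    window = max(1, int(round(smoothing_window * fs)))
    xs = _moving_average(session.samples[channel].to_numpy(dtype=float), window)
    amplitudes: dict[int, list[float]] = {}
    for rep in reps:
        if rep.set_index < 1:
            continue
        seg = xs[rep.start:rep.end]
        if len(seg) == 0:
            continue
        amplitudes.setdefault(rep.set_index, []).append(float(seg.max() - seg.min()))
    per_set = {k: float(np.mean(v)) if v else np.nan for k, v in amplitudes.items()}
    return _per_set_table(per_set)
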