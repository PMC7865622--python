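"""Fusing Borg RPE reports with heart rate into per-repetition fatigue labels.

Subjects report one Borg RPE (6-20) per set, which is subjective; heart
rate provides an objective cross-check because Borg x 10 approximates heart
rate in bpm.  When the reported rating and the measured heart rate diverge
by more than a tolerance (default +/-10 bpm on the heart-rate scale), the
two are averaged (heart rate converted to the Borg scale first) and rounded
half-up.  The fused integer rating is then min-max normalized against the
post-warm-up report and binarized: Borg 17-20 is fatigue, 6-16 is not.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .segment import Repetition
from .simulate import BORG_MAX, BORG_MIN, SessionRecording

__all__ = [
    "LabeledRepetition",
    "hr_to_rpe",
    "is_divergent",
    "fuse_rpe",
    "normalize_rpe",
    "binarize",
    "label_repetitions",
]

DEFAULT_HR_TOLERANCE = 10.0  # bpm
FATIGUE_THRESHOLD = 17       # Borg; fatigue band is [17, 20]


@dataclass(frozen=True)
class LabeledRepetition:
    repetition: Repetition
    reported_rpe: int        # set-level Borg report
    mean_hr: float           # bpm over the repetition interval
    fused_rpe: int           # integer Borg in [6, 20] after fusion
    normalized_rpe: float    # min-max normalized, in [0, 1]
    is_fatigued: bool


def hr_to_rpe(hr: float) -> float:
    """Convert heart rate (bpm) to the Borg scale: hr / 10, unrounded."""
    if hr <= 0:
        raise ValueError(f"heart rate must be positive, got {hr}")
    return hr / 10.0


def is_divergent(
    reported_rpe: float, mean_hr: float, tolerance: float = DEFAULT_HR_TOLERANCE
) -> bool:
    """Whether the report and the measured heart rate disagree by more than
    ``tolerance`` bpm (strict: exactly at tolerance still converges)."""
    return abs(reported_rpe * 10.0 - mean_hr) > tolerance


def _round_half_up(x: float) -> int:
    return math.floor(x + 0.5)


def fuse_rpe(
    reported_rpe: int, mean_hr: float, tolerance: float = DEFAULT_HR_TOLERANCE
) -> int:
    """Fused integer Borg rating for one repetition.

    Convergent reports pass through unchanged; divergent ones are replaced
    by the half-up-rounded average of the report and the heart rate
    converted to the Borg scale, clamped to [6, 20].
    """
    if not is_divergent(reported_rpe, mean_hr, tolerance):
        return int(reported_rpe)
    fused = _round_half_up((reported_rpe + hr_to_rpe(mean_hr)) / 2.0)
    return int(np.clip(fused, BORG_MIN, BORG_MAX))


def normalize_rpe(fused_rpe: float, set_min: float) -> float:
    """Min-max normalization of a Borg rating.

    The maximum is fixed at 20 (top of the Borg scale); the minimum is the
    rating reported after the warm-up, so the scale adapts to each
    subject's baseline exertion.  Clipped to [0, 1].
    """
    if set_min >= BORG_MAX:
        raise ValueError(f"set_min must be < {BORG_MAX}, got {set_min}")
    return float(np.clip((fused_rpe - set_min) / (BORG_MAX - set_min), 0.0, 1.0))


def binarize(fused_rpe: int) -> bool:
    """True (fatigue) iff the fused Borg rating is in [17, 20]."""
    if not (BORG_MIN <= fused_rpe <= BORG_MAX):
        raise ValueError(f"fused_rpe must be in [6, 20], got {fused_rpe}")
    return fused_rpe >= FATIGUE_THRESHOLD


def label_repetitions(
    session: SessionRecording,
    reps: Sequence[Repetition],
    tolerance: float = DEFAULT_HR_TOLERANCE,
) -> list[LabeledRepetition]:
    """Attach fused, normalized and binary fatigue labels to detected reps.

    Every repetition inherits its set's reported RPE; the heart rate fused
    with it is the mean over the repetition's sample interval.  The
    normalization minimum is the warm-up set's report.
    """
    hr = session.samples["heart_rate"].to_numpy(dtype=float)
    set_min = session.reported_rpe[0]
    out = []
    for rep in reps:
        reported = session.reported_rpe[rep.set_index]
        mean_hr = float(hr[rep.start:rep.end].mean())
        fused = fuse_rpe(reported, mean_hr, tolerance)
        out.append(LabeledRepetition(
            repetition=rep,
            reported_rpe=reported,
            mean_hr=mean_hr,
            fused_rpe=fused,
            normalized_rpe=normalize_rpe(fused, set_min),
            is_fatigued=binarize(fused),
        ))
    return out


def labels_frame(labeled: Sequence[LabeledRepetition]) -> pd.DataFrame:
    """Tabular view of labeled repetitions (one row each)."""
    return pd.DataFrame([
        {
            "subject_id": lr.repetition.subject_id,
            "arm": lr.repetition.arm,
            "set_index": lr.repetition.set_index,
            "rep_index": lr.repetition.rep_index,
            "start": lr.repetition.start,
            "end": lr.repetition.end,
            "duration": lr.repetition.duration,
            "reported_rpe": lr.reported_rpe,
            "mean_hr": lr.mean_hr,
            "fused_rpe": lr.fused_rpe,
            "normalized_rpe": lr.normalized_rpe,
            "is_fatigued": lr.is_fatigued,
        }
        for lr in labeled
    ])
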