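"""Per-repetition window statistics: the 33-column feature matrix.

Each repetition is summarized by three statistics — mean, population
standard deviation, and average absolute deviation about the mean (AAD) —
of each of 11 signals: the nine raw IMU channels plus total acceleration
and exerted force.  3 x 11 = 33 features per repetition.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd

from .label import LabeledRepetition
from .signals import DERIVED_SIGNALS, add_derived_signals
from .simulate import IMU_CHANNELS, SessionRecording

__all__ = [
    "SIGNALS",
    "STATS",
    "FEATURE_COLUMNS",
    "ID_COLUMNS",
    "LABEL_COLUMNS",
    "mean",
    "sd",
    "aad",
    "extract_features",
    "build_feature_matrix",
]

logger = logging.getLogger(__name__)

SIGNALS = tuple(IMU_CHANNELS) + DERIVED_SIGNALS        # 11 signals
STATS = ("mean", "sd", "aad")
FEATURE_COLUMNS = tuple(f"{sig}_{stat}" for sig in SIGNALS for stat in STATS)
ID_COLUMNS = ("subject_id", "arm", "set_index", "rep_index")
LABEL_COLUMNS = ("fused_rpe", "normalized_rpe", "is_fatigued")


def mean(x) -> float:
    """Arithmetic mean."""
    arr = np.asarray(x, dtype=float)
    if arr.size == 0:
        raise ValueError("mean of an empty window is undefined")
    return float(arr.mean())


def sd(x) -> float:
    """Population standard deviation (divisor N)."""
    arr = np.asarray(x, dtype=float)
    if arr.size < 2:
        raise ValueError("sd needs at least 2 samples")
    return float(arr.std(ddof=0))


def aad(x) -> float:
    """Average absolute deviation of samples about their mean."""
    arr = np.asarray(x, dtype=float)
    if arr.size == 0:
        raise ValueError("aad of an empty window is undefined")
    return float(np.abs(arr - arr.mean()).mean())


_STAT_FUNCS = {"mean": mean, "sd": sd, "aad": aad}


def extract_features(
    samples: pd.DataFrame, labeled_rep: LabeledRepetition
) -> dict[str, float] | None:
    """The 33 window statistics over one repetition's half-open slice.

    ``samples`` must already carry the derived signal columns.  Returns
    ``None`` (with a warning) for degenerate repetitions shorter than two
    samples.
    """
    rep = labeled_rep.repetition
    if rep.end - rep.start < 2:
        logger.warning(
            "repetition %s/%s set %d rep %d shorter than 2 samples; skipped",
            rep.subject_id, rep.arm, rep.set_index, rep.rep_index,
        )
        return None
    window = samples.iloc[rep.start:rep.end]
    row: dict[str, float] = {}
    for sig in SIGNALS:
        values = window[sig].to_numpy(dtype=float)
        for stat in STATS:
            row[f"{sig}_{stat}"] = _STAT_FUNCS[stat](values)
    return row


def build_feature_matrix(
    items: Sequence[tuple[SessionRecording, Sequence[LabeledRepetition]]],
) -> pd.DataFrame:
    """One row per labeled repetition across sessions, stable column order.

    Columns: identifiers, the 33 features, then labels.  Raises on duplicate
    (subject, arm, set, rep) keys.  Derived signal columns are appended to
    each session's samples if absent.
    """
    rows = []
    for session, labeled in items:
        samples = session.samples
        if not set(DERIVED_SIGNALS) <= set(samples.columns):
            samples = add_derived_signals(samples, session.dumbbell_mass)
        for lr in labeled:
            feats = extract_features(samples, lr)
            if feats is None:
                continue
            rep = lr.repetition
            row = {
                "subject_id": rep.subject_id,
                "arm": rep.arm,
                "set_index": rep.set_index,
                "rep_index": rep.rep_index,
            }
            row.update(feats)
            row.update({
                "fused_rpe": lr.fused_rpe,
                "normalized_rpe": lr.normalized_rpe,
                "is_fatigued": lr.is_fatigued,
            })
            rows.append(row)
    if not rows:
        raise ValueError("no labeled repetitions to build a feature matrix from")
    matrix = pd.DataFrame(rows, columns=list(ID_COLUMNS + FEATURE_COLUMNS + LABEL_COLUMNS))
    dupes = matrix.duplicated(subset=list(ID_COLUMNS))
    if dupes.any():
        raise ValueError(
            f"duplicate repetition keys in feature matrix: "
            f"{matrix.loc[dupes, list(ID_COLUMNS)].to_dict('records')[:3]}"
        )
    return matrix
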