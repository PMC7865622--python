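"""Validation protocols and confusion-matrix metrics.

Two protocols mirror how a fatigue detector would be deployed:

* subject-specific — a personalized model: stratified k-fold (default 5)
  within each subject's own repetitions (both arms pooled), metrics averaged
  over folds and then subjects;
* cross-subject — one model for everyone: leave-one-subject-out
  cross-validation with exactly one fold per subject, so no subject ever
  appears in both train and test.

Metrics treat fatigue as the positive class: accuracy, precision, recall
and F1 from the fold's confusion matrix.  Folds with an undefined metric
(zero denominator) are excluded from that metric's average rather than
imputed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .models import ModelSpec, predict, train

__all__ = [
    "ConfusionMatrix",
    "metrics",
    "EvalReport",
    "subject_specific_eval",
    "loocv_cross_subject",
]

logger = logging.getLogger(__name__)

METRIC_NAMES = ("precision", "recall", "accuracy", "f1")


@dataclass(frozen=True)
class ConfusionMatrix:
    """Counts with fatigue as the positive class."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @classmethod
    def from_labels(cls, y_true, y_pred) -> "ConfusionMatrix":
        t = np.asarray(y_true).astype(bool)
        p = np.asarray(y_pred).astype(bool)
        if t.shape != p.shape:
            raise ValueError("label arrays must have equal length")
        return cls(
            tp=int(np.sum(t & p)),
            fp=int(np.sum(~t & p)),
            fn=int(np.sum(t & ~p)),
            tn=int(np.sum(~t & ~p)),
        )


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else float("nan")


def metrics(cm: ConfusionMatrix) -> dict[str, float]:
    """Accuracy, precision, recall and F1 as fractions in [0, 1].

    Undefined ratios (zero denominator) are returned as NaN.
    """
    precision = _ratio(cm.tp, cm.tp + cm.fp)
    recall = _ratio(cm.tp, cm.tp + cm.fn)
    accuracy = _ratio(cm.tp + cm.tn, cm.total)
    if np.isfinite(precision) and np.isfinite(recall) and (precision + recall) > 0:
        f1 = 2.0 * precision * recall / (precision + recall)
    else:
        f1 = float("nan")
    return {"precision": precision, "recall": recall, "accuracy": accuracy, "f1": f1}


@dataclass
class EvalReport:
    """Per-model metrics under one protocol, with the per-fold breakdown."""

    protocol: str
    per_model: dict[str, dict[str, float]]
    per_fold: pd.DataFrame
    config: dict[str, Any] = field(default_factory=dict)

    def to_table(self) -> pd.DataFrame:
        """Rows = models, columns = metrics in percent."""
        rows = {
            fam: {m: 100.0 * v for m, v in vals.items()}
            for fam, vals in self.per_model.items()
        }
        return pd.DataFrame.from_dict(rows, orient="index")[list(METRIC_NAMES)]

    def to_json(self) -> str:
        payload = {
            "protocol": self.protocol,
            "per_model": self.per_model,
            "per_fold": self.per_fold.to_dict(orient="records"),
            "config": self.config,
        }
        return json.dumps(payload, indent=2, default=float)


def _nanmean(values: Sequence[float]) -> float:
    arr = np.asarray(list(values), dtype=float)
    if np.all(np.isnan(arr)):
        return float("nan")
    return float(np.nanmean(arr))


def _aggregate(per_fold: pd.DataFrame, by: str | None = None) -> dict[str, dict[str, float]]:
    """Unweighted nan-aware mean of fold metrics per model (optionally
    averaging within ``by`` groups first)."""
    out: dict[str, dict[str, float]] = {}
    for fam, group in per_fold.groupby("model", sort=False):
        if by is not None:
            group = group.groupby(by)[list(METRIC_NAMES)].mean()
        out[fam] = {m: _nanmean(group[m]) for m in METRIC_NAMES}
    return out


def subject_specific_eval(
    matrix: pd.DataFrame,
    selected_features: Sequence[str],
    model_specs: Sequence[ModelSpec],
    k_folds: int = 5,
    seed: int = 0,
) -> EvalReport:
    """Personalized protocol: stratified k-fold within each subject.

    Subjects with fewer than ``k_folds`` repetitions of either class cannot
    be stratified and are skipped with a warning.  Per-model metrics are the
    unweighted mean over folds within a subject, then over subjects.
    """
    feats = list(selected_features)
    records = []
    eligible = 0
    for subject, rows in matrix.groupby("subject_id", sort=True):
        y = rows["is_fatigued"].to_numpy(dtype=bool)
        n_pos, n_neg = int(y.sum()), int((~y).sum())
        if min(n_pos, n_neg) < k_folds:
            logger.warning(
                "subject %s skipped: %d fatigue / %d non-fatigue reps "
                "(< %d per class needed for stratified folds)",
                subject, n_pos, n_neg, k_folds,
            )
            continue
        eligible += 1
        skf = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed)
        X = rows[feats]
        for fold, (tr, te) in enumerate(skf.split(np.zeros(len(y)), y)):
            for spec in model_specs:
                model = train(spec, X.iloc[tr], y[tr], feats)
                pred, _ = predict(model, X.iloc[te])
                cm = ConfusionMatrix.from_labels(y[te], pred)
                rec = {"model": spec.family, "subject": subject, "fold": fold,
                       "n_test": cm.total}
                rec.update(metrics(cm))
                records.append(rec)
    if eligible == 0:
        raise ValueError("no subject has enough repetitions of both classes")
    per_fold = pd.DataFrame(records)
    return EvalReport(
        protocol="subject_specific",
        per_model=_aggregate(per_fold, by="subject"),
        per_fold=per_fold,
        config={"k_folds": k_folds, "seed": seed, "features": feats,
                "n_subjects": eligible},
    )


def loocv_cross_subject(
    matrix: pd.DataFrame,
    selected_features: Sequence[str],
    model_specs: Sequence[ModelSpec],
) -> EvalReport:
    """Leave-one-subject-out: one fold per subject, no subject leakage.

    Both arms of a subject stay together on the test side of their fold.
    Folds where a metric is undefined (e.g. the held-out subject has a
    single class) contribute their defined metrics only.
    """
    subjects = sorted(matrix["subject_id"].unique())
    if len(subjects) < 2:
        raise ValueError("cross-subject evaluation needs at least 2 subjects")
    feats = list(selected_features)
    y_all = matrix["is_fatigued"].to_numpy(dtype=bool)
    records = []
    for fold, subject in enumerate(subjects):
        test_mask = (matrix["subject_id"] == subject).to_numpy()
        X_train, y_train = matrix.loc[~test_mask, feats], y_all[~test_mask]
        X_test, y_test = matrix.loc[test_mask, feats], y_all[test_mask]
        for spec in model_specs:
            model = train(spec, X_train, y_train, feats)
            pred, _ = predict(model, X_test)
            cm = ConfusionMatrix.from_labels(y_test, pred)
            rec = {"model": spec.family, "subject": subject, "fold": fold,
                   "n_test": cm.total}
            rec.update(metrics(cm))
            records.append(rec)
    per_fold = pd.DataFrame(records)
    return EvalReport(
        protocol="cross_subject",
        per_model=_aggregate(per_fold),
        per_fold=per_fold,
        config={"n_folds": len(subjects), "features": feats},
    )
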