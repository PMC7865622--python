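import numpy as np
import pandas as pd
import pytest

import curlfatigue.evaluate as ev
from curlfatigue.evaluate import (
    ConfusionMatrix,
    loocv_cross_subject,
    metrics,
    subject_specific_eval,
)
from curlfatigue.models import ModelSpec


def test_confusion_matrix_from_labels():
    # [TRIVIAL] hand-counted example
    y_true = [True, True, False, False, True]
    y_pred = [True, False, True, False, True]
    cm = ConfusionMatrix.from_labels(y_true, y_pred)
    assert (cm.tp, cm.fp, cm.fn, cm.tn) == (2, 1, 1, 1)
    assert cm.total == 5


def test_confusion_matrix_rejects_negative_counts():
    with pytest.raises(ValueError):
        ConfusionMatrix(tp=-1, fp=0, fn=0, tn=0)


def test_confusion_matrix_rejects_length_mismatch():
    with pytest.raises(ValueError):
        ConfusionMatrix.from_labels([True], [True, False])


def test_metrics_worked_example():
    # [DERIVED] tp=8, fp=2, fn=4, tn=6
    m = metrics(ConfusionMatrix(tp=8, fp=2, fn=4, tn=6))
    assert m["precision"] == pytest.approx(0.8)
    assert m["recall"] == pytest.approx(8 / 12)
    assert m["accuracy"] == pytest.approx(0.7)
    assert m["f1"] == pytest.approx(2 * 0.8 * (8 / 12) / (0.8 + 8 / 12))


def test_metrics_undefined_ratios_are_nan():
    m = metrics(ConfusionMatrix(tp=0, fp=0, fn=0, tn=10))
    assert np.isnan(m["precision"])
    assert np.isnan(m["recall"])
    assert np.isnan(m["f1"])
    assert m["accuracy"] == pytest.approx(1.0)


def _toy_matrix(n_subjects=4, per_class=12, seed=0):
    """Small learnable matrix: one informative feature, two arms each."""
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_subjects):
        for arm in ("right", "left"):
            for k in range(per_class * 2):
                fatigued = k % 2 == 0
                rows.append({
                    "subject_id": f"S{i + 1:02d}",
                    "arm": arm,
                    "set_index": 1 + k % 5,
                    "rep_index": k,
                    "x1": rng.normal(3.0 if fatigued else -3.0, 1.0),
                    "x2": rng.normal(0.0, 1.0),
                    "fused_rpe": 18 if fatigued else 12,
                    "is_fatigued": fatigued,
                })
    return pd.DataFrame(rows)


def test_loocv_partitions_by_subject(monkeypatch):
    """No test subject's rows may ever reach training: spy on train()."""
    matrix = _toy_matrix()
    seen = []
    real_train = ev.train

    def spy(spec, features, labels, names=None):
        seen.append(set(matrix.loc[features.index, "subject_id"]))
        return real_train(spec, features, labels, names)

    monkeypatch.setattr(ev, "train", spy)
    report = loocv_cross_subject(matrix, ["x1", "x2"], [ModelSpec(family="DT")])
    subjects = sorted(matrix["subject_id"].unique())
    assert report.per_fold["subject"].tolist() == subjects  # one fold each
    for held_out, train_subjects in zip(subjects, seen):
        assert held_out not in train_subjects
        assert train_subjects == set(subjects) - {held_out}


def test_loocv_folds_cover_every_row_once():
    matrix = _toy_matrix()
    report = loocv_cross_subject(matrix, ["x1", "x2"], [ModelSpec(family="DT")])
    assert report.per_fold["n_test"].sum() == len(matrix)


def test_loocv_needs_two_subjects():
    matrix = _toy_matrix(n_subjects=1)
    with pytest.raises(ValueError, match="at least 2"):
        loocv_cross_subject(matrix, ["x1"], [ModelSpec(family="DT")])


def test_loocv_learnable_signal_is_found():
    report = loocv_cross_subject(_toy_matrix(), ["x1", "x2"],
                                 [ModelSpec(family="LR")])
    assert report.per_model["LR"]["accuracy"] > 0.9


def test_subject_specific_stratified_folds():
    matrix = _toy_matrix()
    report = subject_specific_eval(matrix, ["x1", "x2"],
                                   [ModelSpec(family="LR")], k_folds=5)
    per_fold = report.per_fold
    assert set(per_fold["subject"]) == set(matrix["subject_id"])
    assert per_fold.groupby("subject")["fold"].nunique().eq(5).all()
    assert report.per_model["LR"]["accuracy"] > 0.9


def test_subject_specific_skips_ineligible(caplog):
    import logging
    matrix = _toy_matrix()
    # make one subject all-fatigue so it cannot be stratified
    mask = matrix["subject_id"] == "S01"
    matrix.loc[mask, "is_fatigued"] = True
    with caplog.at_level(logging.WARNING, logger="curlfatigue.evaluate"):
        report = subject_specific_eval(matrix, ["x1"], [ModelSpec(family="DT")])
    assert "skipped" in caplog.text
    assert "S01" not in set(report.per_fold["subject"])


def test_subject_specific_errors_when_none_eligible():
    matrix = _toy_matrix(n_subjects=1, per_class=2)
    matrix["is_fatigued"] = True
    matrix["fused_rpe"] = 18
    with pytest.raises(ValueError, match="no subject"):
        subject_specific_eval(matrix, ["x1"], [ModelSpec(family="DT")])


def test_aggregation_is_unweighted_mean_over_folds_then_subjects():
    per_fold = pd.DataFrame([
        {"model": "DT", "subject": "A", "fold": 0, "n_test": 10,
         "precision": 1.0, "recall": 1.0, "accuracy": 1.0, "f1": 1.0},
        {"model": "DT", "subject": "A", "fold": 1, "n_test": 10,
         "precision": 0.0, "recall": 0.0, "accuracy": 0.0, "f1": 0.0},
        {"model": "DT", "subject": "B", "fold": 0, "n_test": 100,
         "precision": 1.0, "recall": 1.0, "accuracy": 1.0, "f1": 1.0},
    ])
    agg = ev._aggregate(per_fold, by="subject")
    # subject A averages to 0.5, subject B to 1.0 -> overall 0.75 regardless
    # of the very different test sizes
    assert agg["DT"]["accuracy"] == pytest.approx(0.75)


def test_report_table_is_in_percent():
    report = loocv_cross_subject(_toy_matrix(), ["x1"], [ModelSpec(family="LR")])
    table = report.to_table()
    assert table.loc["LR", "accuracy"] > 50.0
    assert list(table.columns) == ["precision", "recall", "accuracy", "f1"]
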