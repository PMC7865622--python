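import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from curlfatigue.features import (
    FEATURE_COLUMNS,
    ID_COLUMNS,
    LABEL_COLUMNS,
    SIGNALS,
    STATS,
    aad,
    build_feature_matrix,
    extract_features,
    mean,
    sd,
)
from curlfatigue.label import LabeledRepetition
from curlfatigue.segment import Repetition
from curlfatigue.signals import add_derived_signals


def test_feature_universe_is_33():
    # 11 signals (9 IMU + total acceleration + exerted force) x 3 statistics
    assert len(SIGNALS) == 11
    assert len(STATS) == 3
    assert len(FEATURE_COLUMNS) == 33
    assert len(set(FEATURE_COLUMNS)) == 33


def test_statistics_on_small_example():
    # [TRIVIAL] x = [1, 2, 3]: mean 2, population sd sqrt(2/3), aad 2/3
    x = [1.0, 2.0, 3.0]
    assert mean(x) == pytest.approx(2.0)
    assert sd(x) == pytest.approx(np.sqrt(2.0 / 3.0))
    assert aad(x) == pytest.approx(2.0 / 3.0)


def test_sd_is_population_not_sample():
    x = np.array([1.0, 5.0])
    assert sd(x) == pytest.approx(np.std(x, ddof=0))
    assert sd(x) != pytest.approx(np.std(x, ddof=1))


def test_degenerate_windows_raise():
    with pytest.raises(ValueError):
        mean([])
    with pytest.raises(ValueError):
        sd([1.0])
    with pytest.raises(ValueError):
        aad([])


@settings(max_examples=100, deadline=None)
@given(st.lists(st.floats(-1e6, 1e6), min_size=2, max_size=200))
def test_aad_never_exceeds_sd(xs):
    """Mean absolute deviation is bounded by the RMS deviation."""
    assert aad(xs) <= sd(xs) + 1e-9


def _one_rep_fixture():
    n = 20
    rng = np.random.default_rng(0)
    samples = pd.DataFrame({
        ch: rng.normal(0.0, 1.0, n)
        for ch in ("acc_x", "acc_y", "acc_z", "gyr_x", "gyr_y", "gyr_z",
                   "mag_x", "mag_y", "mag_z")
    })
    samples = add_derived_signals(samples, dumbbell_mass=4.5)
    rep = Repetition(subject_id="S01", arm="right", set_index=1, rep_index=0,
                     start=0, end=n, duration=n / 50.0)
    labeled = LabeledRepetition(repetition=rep, reported_rpe=12, mean_hr=120.0,
                                fused_rpe=12, normalized_rpe=0.1,
                                is_fatigued=False)
    return samples, labeled


def test_extract_features_yields_exactly_33():
    samples, labeled = _one_rep_fixture()
    feats = extract_features(samples, labeled)
    assert feats is not None
    assert sorted(feats) == sorted(FEATURE_COLUMNS)
    # spot check one value against the window statistics directly
    window = samples["acc_y"].to_numpy()[0:20]
    assert feats["acc_y_mean"] == pytest.approx(window.mean())
    assert feats["acc_y_sd"] == pytest.approx(window.std(ddof=0))


def test_extract_features_short_window_returns_none(caplog):
    samples, labeled = _one_rep_fixture()
    short = LabeledRepetition(
        repetition=Repetition(subject_id="S01", arm="right", set_index=1,
                              rep_index=1, start=0, end=1, duration=0.02),
        reported_rpe=12, mean_hr=120.0, fused_rpe=12,
        normalized_rpe=0.1, is_fatigued=False,
    )
    import logging
    with caplog.at_level(logging.WARNING, logger="curlfatigue.features"):
        assert extract_features(samples, short) is None
    assert "shorter than 2 samples" in caplog.text


def test_build_feature_matrix_shape_and_columns(small_matrix, small_cohort):
    n_reps = sum(len(truth) for _, truth in small_cohort)
    assert small_matrix.shape[0] == n_reps
    expected = list(ID_COLUMNS) + list(FEATURE_COLUMNS) + list(LABEL_COLUMNS)
    assert list(small_matrix.columns) == expected
    assert not small_matrix[list(FEATURE_COLUMNS)].isna().any().any()


def test_build_feature_matrix_rejects_duplicates(small_cohort):
    from curlfatigue.label import label_repetitions
    from curlfatigue.segment import detect_repetitions

    session, _ = small_cohort[0]
    labeled = label_repetitions(session, detect_repetitions(session))
    with pytest.raises(ValueError, match="duplicate"):
        build_feature_matrix([(session, labeled), (session, labeled)])
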