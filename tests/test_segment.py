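import numpy as np
import pandas as pd
import pytest

from curlfatigue.segment import (
    Repetition,
    average_change,
    completion_time_table,
    detect_repetitions,
    endurance_change_table,
)
from curlfatigue.simulate import GeneratorConfig, SessionRecording, generate_session


def _make_session(values, fs=50.0, sets=None):
    n = len(values)
    samples = pd.DataFrame({
        "t": np.arange(n) / fs,
        "acc_x": np.zeros(n), "acc_y": np.asarray(values, float), "acc_z": np.zeros(n),
        "gyr_x": np.asarray(values, float), "gyr_y": np.zeros(n), "gyr_z": np.zeros(n),
        "mag_x": np.zeros(n), "mag_y": np.zeros(n), "mag_z": np.zeros(n),
        "heart_rate": np.full(n, 120.0),
    })
    return SessionRecording(
        subject_id="T01", arm="right", sampling_rate=fs, samples=samples,
        set_boundaries=sets or [(0, n)], reported_rpe=[12] * len(sets or [(0, n)]),
        dumbbell_mass=4.5,
    )


def _pulse_train(n_reps, rep_len=100, fs=50.0):
    """Clean raised-cosine pulses separated by flat holds."""
    out = []
    for _ in range(n_reps):
        hold = np.zeros(rep_len // 8)
        active = np.sin(np.pi * np.linspace(0, 1, rep_len - 2 * len(hold))) ** 2
        out.extend([hold, active, hold])
    return np.concatenate(out)


def test_detects_known_pulse_train():
    values = _pulse_train(5)
    session = _make_session(values)
    reps = detect_repetitions(session)
    assert len(reps) == 5
    # trough-to-trough: consecutive, covering the whole set
    assert reps[0].start == 0
    assert reps[-1].end == len(values)
    for a, b in zip(reps, reps[1:]):
        assert a.end == b.start


def test_boundaries_fall_in_holds():
    rep_len = 100
    values = _pulse_train(4, rep_len=rep_len)
    session = _make_session(values)
    reps = detect_repetitions(session)
    for rep in reps[1:]:
        # each interior boundary must sit within +/-5 samples of a rep edge
        assert min(rep.start % rep_len, rep_len - rep.start % rep_len) <= 5


def test_boundary_accuracy_on_generated_session(session_and_truth):
    """>= 95% of interior boundaries within +/-5 samples of ground truth."""
    session, truth = session_and_truth
    reps = detect_repetitions(session)
    errors = []
    for set_index, group in truth.groupby("set_index"):
        detected = sorted(
            (r for r in reps if r.set_index == set_index), key=lambda r: r.start
        )
        assert len(detected) == len(group)
        starts = group["start_sample"].sort_values().to_numpy()
        for d, true_start in list(zip(detected, starts))[1:]:
            errors.append(abs(d.start - true_start))
    errors = np.asarray(errors)
    assert np.mean(errors <= 5) >= 0.95


def test_detects_all_reps_in_generated_session(session_and_truth, default_config):
    session, _ = session_and_truth
    reps = detect_repetitions(session)
    expected = default_config.warmup_reps + default_config.n_sets * default_config.reps_per_set
    assert len(reps) == expected


def test_flat_channel_warns_and_skips(caplog):
    import logging
    session = _make_session(np.zeros(500))
    with caplog.at_level(logging.WARNING, logger="curlfatigue.segment"):
        reps = detect_repetitions(session)
    assert reps == []
    assert "flat channel" in caplog.text or "no prominent peaks" in caplog.text


def test_unknown_channel_rejected():
    session = _make_session(_pulse_train(3))
    with pytest.raises(ValueError, match="channel"):
        detect_repetitions(session, channel="emg")


def _rep(set_index, duration):
    return Repetition(subject_id="T01", arm="right", set_index=set_index,
                      rep_index=0, start=0, end=int(duration * 50),
                      duration=duration)


def test_completion_time_table_arithmetic():
    # [DERIVED] set 1 at 2.0 s, set 2 at 2.2 s -> +10%; avg over later sets
    reps = [_rep(1, 2.0), _rep(1, 2.0), _rep(2, 2.2), _rep(2, 2.2),
            _rep(3, 2.4), _rep(3, 2.4)]
    table = completion_time_table(reps)
    assert table.loc[1, "pct_change"] == pytest.approx(0.0)
    assert table.loc[2, "pct_change"] == pytest.approx(10.0)
    assert table.loc[3, "pct_change"] == pytest.approx(20.0)
    assert table.loc["avg", "pct_change"] == pytest.approx(15.0)


def test_completion_time_requires_reference_set():
    with pytest.raises(ValueError, match="first main set"):
        completion_time_table([_rep(2, 2.0)])


def test_warmup_excluded_from_tables():
    reps = [_rep(0, 5.0), _rep(1, 2.0), _rep(2, 2.2)]
    table = completion_time_table(reps)
    assert 0 not in table.index


def test_average_change_of_published_completion_row():
    # reference X-gyroscope completion-time row: +2.0, +6.0, +17.0, +33.0 -> +14.5%
    assert average_change([2.0, 6.0, 17.0, 33.0]) == pytest.approx(14.5)


def test_average_change_of_published_endurance_row():
    # reference Z-gyroscope endurance row: +0.5, +1.7, -10.4, -7.5 -> -3.9%
    assert average_change([0.5, 1.7, -10.4, -7.5]) == pytest.approx(-3.925)


def test_endurance_change_table_on_generated_session(session_and_truth):
    session, _ = session_and_truth
    reps = detect_repetitions(session)
    table = endurance_change_table(session, reps)
    assert table.loc[1, "pct_change"] == pytest.approx(0.0)
    assert set(table.index) == {1, 2, 3, 4, 5, "avg"}
    assert np.isfinite(table["pct_change"].astype(float)).all()
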