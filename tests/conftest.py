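"""Shared fixtures: one small cohort and its derived artifacts, built once."""

import warnings

import pytest

from curlfatigue.features import build_feature_matrix
from curlfatigue.label import label_repetitions
from curlfatigue.segment import detect_repetitions
from curlfatigue.simulate import GeneratorConfig, generate_cohort, generate_session


@pytest.fixture(scope="session")
def default_config():
    return GeneratorConfig(seed=7)


@pytest.fixture(scope="session")
def small_config():
    """Cohort small enough for fast end-to-end tests."""
    return GeneratorConfig(n_subjects=4, seed=7)


@pytest.fixture(scope="session")
def session_and_truth(default_config):
    return generate_session(default_config, "S01", "right")


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return generate_cohort(small_config)


@pytest.fixture(scope="session")
def small_matrix(small_cohort):
    items = []
    for session, _ in small_cohort:
        reps = detect_repetitions(session)
        items.append((session, label_repetitions(session, reps)))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return build_feature_matrix(items)
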