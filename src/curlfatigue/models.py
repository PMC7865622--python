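"""The five fatigue classifiers.

All families predict the binary fatigue label (Borg 17-20 vs 6-16) from the
selected window features:

* GLM — binomial generalized linear model with a probit link, fit by
  unregularized maximum likelihood (statsmodels);
* LR  — logistic regression with L2 regularization (strength 1.0);
* RF  — random forest, 100 trees, sqrt(p) features per split;
* DT  — single CART decision tree, no pruning;
* FNN — feedforward neural network with two hidden layers (32, 16),
  rectified-linear activations, logistic output, early stopping on a 10%
  validation split, at most 500 epochs.

Features are standardized with training-set statistics by default; the tree
families are invariant to this.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.linear_model import LogisticRegression
from sklearn.ensemble import RandomForestClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.tree import DecisionTreeClassifier

__all__ = ["MODEL_FAMILIES", "ModelSpec", "TrainedModel", "train", "predict", "default_specs"]

MODEL_FAMILIES = ("GLM", "LR", "RF", "DT", "FNN")


class TrainingError(RuntimeError):
    pass


@dataclass(frozen=True)
class ModelSpec:
    family: str
    hyperparameters: dict[str, Any] = field(default_factory=dict)
    seed: int = 0
    standardize: bool = True

    def __post_init__(self) -> None:
        if self.family not in MODEL_FAMILIES:
            raise ValueError(f"family must be one of {MODEL_FAMILIES}, got {self.family!r}")


def default_specs(seed: int = 0) -> list[ModelSpec]:
    """One spec per family with the package's default hyperparameters."""
    return [ModelSpec(family=f, seed=seed) for f in MODEL_FAMILIES]


class _ProbitGLM:
    """Unregularized binomial GLM with a probit link.

    Thin wrapper giving the statsmodels fit a predict-proba surface; on
    (near-)separable data the IRLS estimates drift to large magnitudes but
    the fitted probabilities remain usable, so convergence warnings are
    suppressed rather than raised.
    """

    def __init__(self) -> None:
        self._params = None

    def fit(self, X: np.ndarray, y: np.ndarray) -> "_ProbitGLM":
        design = sm.add_constant(X, has_constant="add")
        model = sm.GLM(y, design, family=sm.families.Binomial(sm.families.links.Probit()))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            result = model.fit(maxiter=200)
        self._params = np.asarray(result.params, dtype=float)
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        from scipy.stats import norm

        design = sm.add_constant(X, has_constant="add")
        eta = np.clip(design @ self._params, -30, 30)
        p1 = norm.cdf(eta)
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X: np.ndarray) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)


def _make_estimator(spec: ModelSpec):
    hp = dict(spec.hyperparameters)
    if spec.family == "GLM":
        return _ProbitGLM()
    if spec.family == "LR":
        hp.setdefault("C", 1.0)
        hp.setdefault("max_iter", 1000)
        return LogisticRegression(random_state=spec.seed, **hp)
    if spec.family == "RF":
        hp.setdefault("n_estimators", 100)
        hp.setdefault("max_features", "sqrt")
        return RandomForestClassifier(random_state=spec.seed, **hp)
    if spec.family == "DT":
        return DecisionTreeClassifier(random_state=spec.seed, **hp)
    if spec.family == "FNN":
        hp.setdefault("hidden_layer_sizes", (32, 16))
        hp.setdefault("activation", "relu")
        hp.setdefault("early_stopping", True)
        hp.setdefault("validation_fraction", 0.1)
        hp.setdefault("max_iter", 500)
        # folds are small (a subject contributes ~160 reps), so full-batch
        # adam needs a faster learning rate and more patience than the
        # sklearn defaults to converge before early stopping triggers
        hp.setdefault("learning_rate_init", 0.01)
        hp.setdefault("n_iter_no_change", 50)
        # modest weight decay: cross-subject folds punish boundaries fit to
        # individual training subjects
        hp.setdefault("alpha", 1.0)
        return MLPClassifier(random_state=spec.seed, **hp)
    raise ValueError(spec.family)


@dataclass
class TrainedModel:
    spec: ModelSpec
    feature_names: tuple[str, ...]
    estimator: Any
    scaler: StandardScaler | None
    n_train: int


def _as_matrix(features: pd.DataFrame, names: Sequence[str]) -> np.ndarray:
    missing = [n for n in names if n not in features.columns]
    if missing:
        raise ValueError(f"feature columns missing: {missing}")
    X = features[list(names)].to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("feature matrix contains missing values")
    return X


def train(
    spec: ModelSpec,
    features: pd.DataFrame,
    labels: Sequence[bool] | np.ndarray,
    feature_names: Sequence[str] | None = None,
) -> TrainedModel:
    """Fit one classifier; deterministic for a fixed spec seed and data."""
    names = tuple(feature_names) if feature_names is not None else tuple(features.columns)
    X = _as_matrix(features, names)
    y = np.asarray(labels).astype(int)
    if len(np.unique(y)) < 2:
        raise TrainingError(
            "training set contains a single class; both fatigue and "
            "non-fatigue repetitions are required"
        )
    scaler = None
    if spec.standardize:
        scaler = StandardScaler().fit(X)
        X = scaler.transform(X)
    estimator = _make_estimator(spec)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        estimator.fit(X, y)
    return TrainedModel(
        spec=spec, feature_names=names, estimator=estimator,
        scaler=scaler, n_train=len(y),
    )


def predict(
    model: TrainedModel, features: pd.DataFrame
) -> tuple[np.ndarray, np.ndarray]:
    """Binary fatigue predictions and positive-class scores in [0, 1]."""
    X = _as_matrix(features, model.feature_names)
    if model.scaler is not None:
        X = model.scaler.transform(X)
    labels = np.asarray(model.estimator.predict(X)).astype(bool)
    if hasattr(model.estimator, "predict_proba"):
        scores = model.estimator.predict_proba(X)[:, 1]
    else:
        scores = labels.astype(float)
    return labels, scores
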