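"""Training-and-testing-phase learners: a feed-forward network and an SVM.

The feed-forward classifier reproduces the six-layer architecture used for
the date-fruit task — hidden layers of 500, 250, 125 and 50 neurons between
the selected-feature input and a softmax output of one neuron per class —
with ReLU activations, cross-entropy loss, Adam updates and early stopping
on a 10% validation slice.  The SVM alternative is a linear-kernel machine
in a one-vs-rest multiclass scheme.  Both standardize features (z-score
fitted on the training data) internally by default.

Both are scikit-learn estimators; :func:`train` / :func:`predict` wrap them
behind a single table-level contract and record wall times.
"""

from __future__ import annotations

import time
import warnings
from dataclasses import dataclass
from pathlib import Path

import joblib
import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.multiclass import OneVsRestClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted, validate_data

from .data import FeatureTable

__all__ = [
    "ClassifierSpec",
    "AnnClassifier",
    "SvmClassifier",
    "TrainedModel",
    "train",
    "predict",
    "save_model",
    "load_model",
]

DEFAULT_HIDDEN_SIZES = (500, 250, 125, 50)


@dataclass
class ClassifierSpec:
    """Which learner to build and with what hyperparameters."""

    kind: str = "ANN"
    hidden_sizes: tuple[int, ...] = DEFAULT_HIDDEN_SIZES
    activation: str = "relu"
    epochs: int = 200
    learning_rate: float = 1e-3
    batch_size: int | str = "auto"
    patience: int = 10
    validation_fraction: float = 0.1
    kernel: str = "linear"
    C: float = 1.0
    multiclass: str = "ovr"
    standardize: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("ANN", "SVM"):
            raise ValueError(f"kind must be 'ANN' or 'SVM', got {self.kind!r}")

    def build(self) -> BaseEstimator:
        if self.kind == "ANN":
            return AnnClassifier(
                hidden_sizes=self.hidden_sizes,
                activation=self.activation,
                epochs=self.epochs,
                learning_rate=self.learning_rate,
                batch_size=self.batch_size,
                patience=self.patience,
                validation_fraction=self.validation_fraction,
                standardize=self.standardize,
                random_state=self.seed,
            )
        return SvmClassifier(
            kernel=self.kernel,
            C=self.C,
            multiclass=self.multiclass,
            standardize=self.standardize,
            random_state=self.seed,
        )


class _TableClassifierBase(ClassifierMixin, BaseEstimator):
    """Shared fit plumbing: validation, optional z-scoring, label bookkeeping."""

    def _pre_fit(self, X, y):
        X, y = validate_data(self, X, y, dtype=float)
        y = np.asarray(y).astype(str)
        self.classes_ = np.unique(y)
        if len(self.classes_) < 2:
            raise ValueError("training requires at least 2 classes")
        return X, y

    def _check_predict(self, X):
        check_is_fitted(self, "pipeline_")
        return validate_data(self, X, reset=False, dtype=float)


class AnnClassifier(_TableClassifierBase):
    """Feed-forward network classifier (ReLU hidden layers, softmax output).

    Default hidden widths (500, 250, 125, 50); with the input and the
    per-class output that is six layers.  Trained with cross-entropy loss and
    Adam, capped at ``epochs`` passes with patience-based early stopping on a
    held-out validation fraction.  Deterministic under ``random_state``.
    """

    def __init__(
        self,
        hidden_sizes: tuple[int, ...] = DEFAULT_HIDDEN_SIZES,
        activation: str = "relu",
        epochs: int = 200,
        learning_rate: float = 1e-3,
        batch_size: int | str = "auto",
        patience: int = 10,
        validation_fraction: float = 0.1,
        standardize: bool = True,
        random_state: int = 0,
    ):
        self.hidden_sizes = hidden_sizes
        self.activation = activation
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.patience = patience
        self.validation_fraction = validation_fraction
        self.standardize = standardize
        self.random_state = random_state

    def fit(self, X, y):
        X, y = self._pre_fit(X, y)
        mlp = MLPClassifier(
            hidden_layer_sizes=tuple(self.hidden_sizes),
            activation=self.activation,
            solver="adam",
            learning_rate_init=self.learning_rate,
            batch_size=self.batch_size,
            max_iter=self.epochs,
            early_stopping=True,
            validation_fraction=self.validation_fraction,
            n_iter_no_change=self.patience,
            random_state=int(self.random_state),
        )
        steps = []
        if self.standardize:
            steps.append(("scale", StandardScaler()))
        steps.append(("mlp", mlp))
        self.pipeline_ = Pipeline(steps)
        with warnings.catch_warnings():
            warnings.filterwarnings("ignore", message=".*Maximum iterations.*")
            self.pipeline_.fit(X, y)
        return self

    @property
    def layer_widths_(self) -> tuple[int, ...]:
        """Realized network widths (input, hidden..., output)."""
        check_is_fitted(self, "pipeline_")
        coefs = self.pipeline_.named_steps["mlp"].coefs_
        return tuple([coefs[0].shape[0]] + [w.shape[1] for w in coefs])

    def predict(self, X):
        return self.pipeline_.predict(self._check_predict(X))

    def predict_proba(self, X):
        return self.pipeline_.predict_proba(self._check_predict(X))


class SvmClassifier(_TableClassifierBase):
    """Support-vector classifier, linear kernel and one-vs-rest by default."""

    def __init__(
        self,
        kernel: str = "linear",
        C: float = 1.0,
        multiclass: str = "ovr",
        standardize: bool = True,
        random_state: int = 0,
    ):
        self.kernel = kernel
        self.C = C
        self.multiclass = multiclass
        self.standardize = standardize
        self.random_state = random_state

    def fit(self, X, y):
        X, y = self._pre_fit(X, y)
        svc = SVC(kernel=self.kernel, C=self.C, random_state=int(self.random_state))
        est: BaseEstimator = OneVsRestClassifier(svc) if self.multiclass == "ovr" else svc
        steps = []
        if self.standardize:
            steps.append(("scale", StandardScaler()))
        steps.append(("svm", est))
        self.pipeline_ = Pipeline(steps)
        self.pipeline_.fit(X, y)
        return self

    def predict(self, X):
        return self.pipeline_.predict(self._check_predict(X))

    def decision_function(self, X):
        return self.pipeline_.decision_function(self._check_predict(X))


@dataclass
class TrainedModel:
    """A fitted learner plus the bookkeeping needed to use it safely."""

    spec: ClassifierSpec
    estimator: BaseEstimator
    classes: np.ndarray
    input_width: int
    feature_names: np.ndarray
    train_time_s: float = 0.0

    def supports_proba(self) -> bool:
        return hasattr(self.estimator, "predict_proba")


def train(table: FeatureTable, spec: ClassifierSpec | None = None) -> TrainedModel:
    """Fit the learner described by ``spec`` on a feature table."""
    spec = spec or ClassifierSpec()
    if len(set(table.labels)) < 2:
        raise ValueError("training requires a table with at least 2 classes")
    est = spec.build()
    t0 = time.perf_counter()
    est.fit(table.values, table.labels.astype(str))
    elapsed = time.perf_counter() - t0
    return TrainedModel(
        spec=spec,
        estimator=est,
        classes=est.classes_,
        input_width=table.n_features,
        feature_names=table.feature_names.copy(),
        train_time_s=elapsed,
    )


def predict(
    model: TrainedModel, table: FeatureTable
) -> tuple[np.ndarray, np.ndarray | None]:
    """Predict labels (and class probabilities where supported) for a table.

    The table must have the training width; differing feature *names* at the
    same width trigger a warning and a positional fallback.
    """
    if table.n_features != model.input_width:
        raise ValueError(
            f"table width {table.n_features} != model input width {model.input_width}"
        )
    if not np.array_equal(
        table.feature_names.astype(str), model.feature_names.astype(str)
    ):
        warnings.warn(
            "feature names differ from training; columns are matched by position",
            stacklevel=2,
        )
    labels = model.estimator.predict(table.values)
    proba = (
        model.estimator.predict_proba(table.values) if model.supports_proba() else None
    )
    return np.asarray(labels, dtype=object), proba


def save_model(model: TrainedModel, path: str | Path) -> None:
    """Persist a trained model to a single-file archive."""
    joblib.dump(model, path)


def load_model(path: str | Path) -> TrainedModel:
    model = joblib.load(path)
    if not isinstance(model, TrainedModel):
        raise TypeError(f"{path} does not contain a TrainedModel")
    return model
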