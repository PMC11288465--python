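"""The wrapper feature-selection objective.

A candidate mask is scored by how badly a K-nearest-neighbour classifier
(K = 5 by default) performs on held-out rows when restricted to the masked
columns, plus a small penalty on subset size:

    fitness(S) = w * err_KNN(S) + (1 - w) * |S| / D,      w = 0.99

Lower is better.  The error term is measured on an internal validation
scheme — a seeded stratified holdout of the data handed to the optimizer
(80/20 by default) or k-fold cross-validation.  The split is drawn once per
evaluator, so a given mask always maps to the same fitness within a run.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from sklearn.neighbors import KNeighborsClassifier

from .data import FeatureMask, FeatureTable, SplitSpec, apply_mask, stratified_split

__all__ = ["FitnessSpec", "knn_error", "fitness", "FitnessEvaluator"]


@dataclass
class FitnessSpec:
    """Parameters of the wrapper objective.

    ``error_weight`` (w) trades classification error against subset size;
    w = 1 ignores size entirely.  ``validation`` is ``("holdout", train_frac)``
    or ``("kfold", k)``.
    """

    k_neighbors: int = 5
    error_weight: float = 0.99
    validation: tuple = ("holdout", 0.8)
    standardize: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")
        if not 0.0 <= self.error_weight <= 1.0:
            raise ValueError("error_weight must lie in [0, 1]")
        kind = self.validation[0]
        if kind not in ("holdout", "kfold"):
            raise ValueError(f"unknown validation scheme {kind!r}")


def knn_error(
    train: FeatureTable,
    val: FeatureTable,
    mask: FeatureMask,
    k_neighbors: int = 5,
    standardize: bool = False,
) -> float:
    """Fraction of ``val`` rows misclassified by K-NN majority vote.

    Neighbours are the ``k_neighbors`` Euclidean-nearest rows of ``train``
    restricted to the mask's columns; distances are on raw feature values
    unless ``standardize`` z-scores them with train-fitted statistics.  Vote
    ties break toward the lexicographically smallest label (scikit-learn's
    convention for uniform weights over sorted classes).
    """
    if k_neighbors > train.n_samples:
        raise ValueError(
            f"k_neighbors={k_neighbors} exceeds the {train.n_samples} training rows"
        )
    unseen = set(val.labels) - set(train.labels)
    if unseen:
        raise ValueError(f"validation labels absent from training data: {sorted(unseen)}")
    x_train = apply_mask(train, mask).values
    x_val = apply_mask(val, mask).values
    if standardize:
        mu = x_train.mean(axis=0)
        sd = x_train.std(axis=0)
        sd[sd == 0] = 1.0
        x_train = (x_train - mu) / sd
        x_val = (x_val - mu) / sd
    clf = KNeighborsClassifier(
        n_neighbors=k_neighbors, algorithm="brute", metric="euclidean"
    )
    clf.fit(x_train, train.labels.astype(str))
    pred = clf.predict(x_val)
    return float(np.mean(pred != val.labels.astype(str)))


class FitnessEvaluator:
    """Callable scoring masks on a fixed table under a :class:`FitnessSpec`.

    Precomputes the validation split(s) once so the objective is a pure
    function of the mask within a run.  Tracks the evaluation count and,
    through ``audit_hook``, reports the sample ids of every row the objective
    touches — the hook is how the no-leakage audit proves the test partition
    never reaches fitness evaluation.
    """

    def __init__(
        self,
        data: FeatureTable,
        spec: FitnessSpec,
        audit_hook: Callable[[Sequence[str]], None] | None = None,
    ):
        self.data = data
        self.spec = spec
        self.audit_hook = audit_hook
        self.n_evaluations = 0
        kind = spec.validation[0]
        if kind == "holdout":
            frac = float(spec.validation[1])
            tr, va = stratified_split(
                data, SplitSpec(train_fraction=frac, stratified=True, seed=spec.seed)
            )
            self._folds = [(tr, va)]
        else:
            k = int(spec.validation[1])
            self._folds = self._kfold(data, k, spec.seed)

    @staticmethod
    def _kfold(data: FeatureTable, k: int, seed: int) -> list[tuple[FeatureTable, FeatureTable]]:
        from sklearn.model_selection import StratifiedKFold

        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        folds = []
        for tr_idx, va_idx in skf.split(data.values, data.labels.astype(str)):
            folds.append((data.take(tr_idx), data.take(va_idx)))
        return folds

    def error(self, mask: FeatureMask) -> float:
        errs = [
            knn_error(tr, va, mask, self.spec.k_neighbors, self.spec.standardize)
            for tr, va in self._folds
        ]
        return float(np.mean(errs))

    def __call__(self, mask: FeatureMask) -> float:
        self.n_evaluations += 1
        if self.audit_hook is not None:
            self.audit_hook(list(self.data.sample_ids))
        err = self.error(mask)
        w = self.spec.error_weight
        return w * err + (1.0 - w) * (mask.n_selected / self.data.n_features)


def fitness(mask: FeatureMask, data: FeatureTable, spec: FitnessSpec | None = None) -> float:
    """Score one mask: ``w * KNN-error + (1 - w) * subset-fraction``."""
    return FitnessEvaluator(data, spec or FitnessSpec())(mask)
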