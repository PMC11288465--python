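"""Evaluation metrics and the optimizer x classifier nomination loop.

Metrics come from a ``c x c`` confusion matrix (rows = true class, columns =
predicted).  Per class ``k`` the one-vs-rest counts TP/FP/FN/TN give

    P_k = TP / (TP + FP),  R_k = TP / (TP + FN),  F1_k = 2 P_k R_k / (P_k + R_k)

and testing accuracy TA is overall correct / total.  With five classes the
binary formulas need an averaging convention: the default is macro (per-class
one-vs-rest values averaged unweighted), with micro available — under micro
averaging P, R and TA coincide in single-label classification, so a report
where P differs from TA is necessarily not micro-averaged.  A class never
predicted gets P_k = 0 (logged), keeping macro averages total.  Per-class
accuracy is the diagonal entry over its row sum, i.e. the class's recall.

The nomination loop sweeps every optimizer x classifier combination through
split -> feature selection (training rows only) -> train -> test, and keeps
an incumbent that is replaced only when ALL FOUR of TA, P, R and F1 strictly
improve.  This conjunctive rule is preserved exactly as stated; it makes the
outcome depend on evaluation order when combinations are incomparable, so
the evaluation order is part of the configuration and is logged rather than
silently normalized.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix as _sk_confusion_matrix

from .classifiers import ClassifierSpec, TrainedModel, predict, train
from .data import FeatureMask, FeatureTable, SplitSpec, apply_mask, stratified_split
from .fitness import FitnessSpec
from .optimizers import OptimizerConfig, Trace, optimize

__all__ = [
    "ConfusionMatrix",
    "Metrics",
    "CombinationRecord",
    "SelectionResult",
    "confusion_matrix",
    "compute_metrics",
    "evaluate_combination",
    "nominate",
    "nominate_records",
    "NominationError",
]

logger = logging.getLogger(__name__)


class NominationError(RuntimeError):
    """No combination ever satisfied the conjunctive improvement rule."""


@dataclass
class ConfusionMatrix:
    """c x c integer count table; rows = true class, columns = predicted."""

    counts: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        self.labels = np.asarray(self.labels, dtype=object)
        c = len(self.labels)
        if self.counts.shape != (c, c):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match {c} labels"
            )
        if (self.counts < 0).any():
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class Metrics:
    """TA/P/R/F1 plus per-class accuracy under a stated averaging mode."""

    ta: float
    precision: float
    recall: float
    f1: float
    per_class_accuracy: np.ndarray
    averaging: str = "macro"

    def as_dict(self) -> dict:
        return {
            "TA": self.ta,
            "P": self.precision,
            "R": self.recall,
            "F1": self.f1,
            "per_class_accuracy": [float(v) for v in self.per_class_accuracy],
            "averaging": self.averaging,
        }


def confusion_matrix(
    y_true: Sequence, y_pred: Sequence, labels: Sequence | None = None
) -> ConfusionMatrix:
    """Tally counts[i][j] = #{rows with true = labels[i], pred = labels[j]}."""
    y_true = np.asarray(y_true, dtype=object).astype(str)
    y_pred = np.asarray(y_pred, dtype=object).astype(str)
    if len(y_true) != len(y_pred):
        raise ValueError(f"length mismatch: {len(y_true)} true vs {len(y_pred)} predicted")
    if labels is None:
        labels = sorted(set(y_true) | set(y_pred))
    labels = [str(l) for l in labels]
    unknown = (set(y_true) | set(y_pred)) - set(labels)
    if unknown:
        raise ValueError(f"labels outside the declared set: {sorted(unknown)}")
    counts = _sk_confusion_matrix(y_true, y_pred, labels=labels)
    return ConfusionMatrix(counts=counts, labels=np.asarray(labels, dtype=object))


def compute_metrics(cm: ConfusionMatrix, averaging: str = "macro") -> Metrics:
    """Derive TA, P, R, F1 and per-class accuracy from a confusion matrix."""
    if averaging not in ("macro", "micro"):
        raise ValueError(f"averaging must be 'macro' or 'micro', got {averaging!r}")
    counts = cm.counts
    total = counts.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    tp = np.diag(counts).astype(float)
    fp = counts.sum(axis=0) - tp
    fn = counts.sum(axis=1) - tp
    ta = tp.sum() / total
    row_sums = counts.sum(axis=1).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        per_class_acc = np.where(row_sums > 0, tp / row_sums, 0.0)
    if averaging == "micro":
        # single-label multiclass: micro-P == micro-R == TA
        return Metrics(ta, ta, ta, ta, per_class_acc, "micro")
    p_k = np.zeros(len(tp))
    r_k = np.zeros(len(tp))
    for k in range(len(tp)):
        if tp[k] + fp[k] > 0:
            p_k[k] = tp[k] / (tp[k] + fp[k])
        else:
            logger.info(
                "class %r has no predicted positives; precision defined as 0",
                cm.labels[k],
            )
        if tp[k] + fn[k] > 0:
            r_k[k] = tp[k] / (tp[k] + fn[k])
    with np.errstate(invalid="ignore", divide="ignore"):
        f1_k = np.where(p_k + r_k > 0, 2 * p_k * r_k / (p_k + r_k), 0.0)
    return Metrics(
        float(ta),
        float(p_k.mean()),
        float(r_k.mean()),
        float(f1_k.mean()),
        per_class_acc,
        "macro",
    )


@dataclass
class CombinationRecord:
    """One row of the sweep report: who ran, how well, how long."""

    optimizer: str
    classifier: str
    metrics: Metrics
    n_selected: int
    fs_time_s: float
    train_time_s: float
    test_time_s: float
    mask: FeatureMask
    model: TrainedModel
    trace: Trace
    fitness_sample_ids: set = field(default_factory=set)

    def row(self) -> dict:
        return {
            "optimizer": self.optimizer,
            "classifier": self.classifier,
            "TA": self.metrics.ta,
            "P": self.metrics.precision,
            "R": self.metrics.recall,
            "F1": self.metrics.f1,
            "fs_train_time_s": self.fs_time_s + self.train_time_s,
            "test_time_s": self.test_time_s,
            "n_features": self.n_selected,
        }


@dataclass
class SelectionResult:
    """All sweep records, in evaluation order, plus the nominated winner."""

    records: list[CombinationRecord]
    nominated: CombinationRecord

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.row() for r in self.records])

    def save(self, csv_path: str | Path, json_path: str | Path | None = None) -> None:
        self.to_frame().to_csv(csv_path, index=False)
        if json_path is not None:
            summary = {
                "nominated": {
                    "optimizer": self.nominated.optimizer,
                    "classifier": self.nominated.classifier,
                    **self.nominated.metrics.as_dict(),
                    "n_features": self.nominated.n_selected,
                },
                "evaluation_order": [
                    f"{r.optimizer}-{r.classifier}" for r in self.records
                ],
            }
            Path(json_path).write_text(json.dumps(summary, indent=2) + "\n")


def evaluate_combination(
    table: FeatureTable,
    optimizer_config: OptimizerConfig,
    classifier_spec: ClassifierSpec,
    split_spec: SplitSpec | None = None,
    fitness_spec: FitnessSpec | None = None,
    averaging: str = "macro",
) -> CombinationRecord:
    """Run one optimizer x classifier combination end to end.

    The table is split first; feature selection sees only the training
    portion (every fitness evaluation's sample ids are recorded so the
    no-leakage property is auditable), the classifier trains on the masked
    training rows and is scored on the masked test rows.
    """
    split_spec = split_spec or SplitSpec()
    fitness_spec = fitness_spec or FitnessSpec()
    train_part, test_part = stratified_split(table, split_spec)

    audited: set = set()

    t0 = time.perf_counter()
    mask, trace = optimize(
        train_part, fitness_spec, optimizer_config, audit_hook=audited.update
    )
    fs_time = time.perf_counter() - t0

    model = train(apply_mask(train_part, mask), classifier_spec)

    t0 = time.perf_counter()
    y_pred, _ = predict(model, apply_mask(test_part, mask))
    test_time = time.perf_counter() - t0

    cm = confusion_matrix(
        test_part.labels, y_pred, labels=[str(c) for c in table.classes]
    )
    metrics = compute_metrics(cm, averaging=averaging)
    return CombinationRecord(
        optimizer=optimizer_config.algorithm,
        classifier=classifier_spec.kind,
        metrics=metrics,
        n_selected=mask.n_selected,
        fs_time_s=fs_time,
        train_time_s=model.train_time_s,
        test_time_s=test_time,
        mask=mask,
        model=model,
        trace=trace,
        fitness_sample_ids=audited,
    )


def nominate_records(records: Sequence[CombinationRecord]) -> CombinationRecord:
    """Apply the conjunctive incumbent rule to records in evaluation order.

    The incumbent starts at zero on all four metrics and is replaced only
    when a record strictly improves TA AND P AND R AND F1 simultaneously.
    Incomparable records (each better on some metric) leave the incumbent in
    place, so the order of ``records`` matters.
    """
    best = {"TA": 0.0, "P": 0.0, "R": 0.0, "F1": 0.0}
    nominated: CombinationRecord | None = None
    for rec in records:
        m = rec.metrics
        if (
            m.ta > best["TA"]
            and m.precision > best["P"]
            and m.recall > best["R"]
            and m.f1 > best["F1"]
        ):
            best = {"TA": m.ta, "P": m.precision, "R": m.recall, "F1": m.f1}
            nominated = rec
    if nominated is None:
        raise NominationError(
            "no combination strictly improved on the zero incumbent in all four metrics"
        )
    return nominated


def nominate(
    table: FeatureTable,
    optimizer_configs: Sequence[OptimizerConfig],
    classifier_specs: Sequence[ClassifierSpec],
    split_spec: SplitSpec | None = None,
    fitness_spec: FitnessSpec | None = None,
    averaging: str = "macro",
) -> SelectionResult:
    """Sweep every optimizer x classifier combination and nominate a winner.

    Evaluation order is optimizers outer, classifiers inner, as given; the
    winner is the conjunctive-rule incumbent over that order (see
    :func:`nominate_records`).
    """
    if len(optimizer_configs) == 0 or len(classifier_specs) == 0:
        raise ValueError("need at least one optimizer and one classifier")
    records: list[CombinationRecord] = []
    for oc in optimizer_configs:
        for cs in classifier_specs:
            rec = evaluate_combination(
                table, oc, cs, split_spec, fitness_spec, averaging
            )
            records.append(rec)
            m = rec.metrics
            logger.info(
                "evaluated %s-%s: TA=%.4f P=%.4f R=%.4f F1=%.4f (%d features)",
                rec.optimizer, rec.classifier, m.ta, m.precision, m.recall, m.f1,
                rec.n_selected,
            )
    return SelectionResult(records=records, nominated=nominate_records(records))
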