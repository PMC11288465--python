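"""Metrics from confusion matrices and the conjunctive nomination loop."""

import numpy as np
import pytest

from swarmfs.classifiers import ClassifierSpec
from swarmfs.data import SplitSpec
from swarmfs.fitness import FitnessSpec
from swarmfs.optimizers import OptimizerConfig
from swarmfs.selection import (
    CombinationRecord,
    ConfusionMatrix,
    Metrics,
    NominationError,
    compute_metrics,
    confusion_matrix,
    evaluate_combination,
    nominate,
    nominate_records,
)


def metrics_oracle(counts, averaging):
    """Independent per-class one-vs-rest arithmetic (explicit loops)."""
    counts = np.asarray(counts, dtype=float)
    c = counts.shape[0]
    total = counts.sum()
    correct = sum(counts[i][i] for i in range(c))
    ta = correct / total
    if averaging == "micro":
        return ta, ta, ta, ta
    ps, rs, f1s = [], [], []
    for k in range(c):
        tp = counts[k][k]
        fp = sum(counts[i][k] for i in range(c)) - tp
        fn = sum(counts[k][j] for j in range(c)) - tp
        p = tp / (tp + fp) if tp + fp > 0 else 0.0
        r = tp / (tp + fn) if tp + fn > 0 else 0.0
        ps.append(p)
        rs.append(r)
        f1s.append(2 * p * r / (p + r) if p + r > 0 else 0.0)
    return ta, float(np.mean(ps)), float(np.mean(rs)), float(np.mean(f1s))


def fake_record(ta, p, r, f1, name="X"):
    m = Metrics(ta, p, r, f1, np.array([ta]), "macro")
    return CombinationRecord(
        optimizer=name, classifier="ANN", metrics=m, n_selected=1,
        fs_time_s=0.0, train_time_s=0.0, test_time_s=0.0,
        mask=None, model=None, trace=None,
    )


class TestConfusionMatrix:
    def test_hand_tally(self):
        cm = confusion_matrix(
            ["A", "A", "B", "B", "B"], ["A", "B", "B", "B", "A"], labels=["A", "B"]
        )
        np.testing.assert_array_equal(cm.counts, [[1, 1], [1, 2]])
        assert cm.total == 5

    def test_perfect_predictions_are_diagonal(self):
        y = ["a", "b", "c", "a", "b"]
        cm = confusion_matrix(y, y)
        assert (cm.counts == np.diag(np.diag(cm.counts))).all()
        assert cm.total == 5

    def test_errors(self):
        with pytest.raises(ValueError, match="length"):
            confusion_matrix(["a"], ["a", "b"])
        with pytest.raises(ValueError, match="declared"):
            confusion_matrix(["a"], ["z"], labels=["a", "b"])


class TestComputeMetrics:
    def test_perfect_multiclass(self):
        cm = confusion_matrix(list("abcde"), list("abcde"))
        m = compute_metrics(cm)
        assert m.ta == m.precision == m.recall == m.f1 == 1.0
        np.testing.assert_allclose(m.per_class_accuracy, 1.0)

    def test_binary_arithmetic(self):
        """TP=8, FP=2, FN=1, TN=9 for the positive class."""
        cm = ConfusionMatrix(
            counts=np.array([[8, 1], [2, 9]]), labels=np.array(["pos", "neg"], dtype=object)
        )
        m = compute_metrics(cm, averaging="macro")
        assert m.ta == pytest.approx(0.85)
        assert m.per_class_accuracy[0] == pytest.approx(8 / 9)  # positive-class recall
        # macro P averages the positive-class 8/10 with the negative-class 9/10
        assert m.precision == pytest.approx((8 / 10 + 9 / 10) / 2)
        ta, p, r, f1 = metrics_oracle(cm.counts, "macro")
        assert (m.ta, m.precision, m.recall, m.f1) == (ta, p, r, f1)

    def test_per_class_accuracy_is_row_normalized_diagonal(self):
        cm = ConfusionMatrix(
            counts=np.array([[45, 5], [10, 40]]),
            labels=np.array(["a", "b"], dtype=object),
        )
        m = compute_metrics(cm)
        assert m.per_class_accuracy[0] == pytest.approx(0.9)

    def test_micro_collapses_to_ta(self):
        rng = np.random.default_rng(0)
        cm = ConfusionMatrix(
            counts=rng.integers(0, 20, size=(4, 4)),
            labels=np.array(list("abcd"), dtype=object),
        )
        m = compute_metrics(cm, averaging="micro")
        assert m.ta == m.precision == m.recall == m.f1

    def test_never_predicted_class_gets_zero_precision(self):
        cm = ConfusionMatrix(
            counts=np.array([[0, 5], [0, 5]]), labels=np.array(["a", "b"], dtype=object)
        )
        m = compute_metrics(cm)
        ta, p, r, f1 = metrics_oracle(cm.counts, "macro")
        assert (m.ta, m.precision, m.recall, m.f1) == (ta, p, r, f1)

    def test_oracle_equivalence_random_matrices(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            c = int(rng.integers(2, 7))
            counts = rng.integers(0, 30, size=(c, c))
            if counts.sum() == 0:
                counts[0, 0] = 1
            cm = ConfusionMatrix(
                counts=counts, labels=np.array([f"c{i}" for i in range(c)], dtype=object)
            )
            for mode in ("macro", "micro"):
                m = compute_metrics(cm, mode)
                assert (m.ta, m.precision, m.recall, m.f1) == metrics_oracle(counts, mode)


class TestNominationRule:
    def test_single_record_wins(self):
        rec = fake_record(0.5, 0.5, 0.5, 0.5)
        assert nominate_records([rec]) is rec

    def test_strict_dominance_wins_any_order(self):
        dom = fake_record(0.9, 0.9, 0.9, 0.9, "dom")
        others = [fake_record(0.8, 0.85, 0.7, 0.75, "o1"), fake_record(0.7, 0.7, 0.8, 0.7, "o2")]
        for order in ([dom] + others, others + [dom], [others[0], dom, others[1]]):
            assert nominate_records(order).optimizer == "dom"

    def test_incomparable_records_keep_earlier_incumbent(self):
        a = fake_record(0.9, 0.7, 0.9, 0.8, "a")
        b = fake_record(0.8, 0.9, 0.8, 0.85, "b")  # better P/F1, worse TA/R
        assert nominate_records([a, b]).optimizer == "a"
        assert nominate_records([b, a]).optimizer == "b"

    def test_all_zero_metrics_raise(self):
        with pytest.raises(NominationError):
            nominate_records([fake_record(0.0, 0.0, 0.0, 0.0)])


@pytest.fixture(scope="module")
def record(small_synthetic):
    table, _ = small_synthetic
    return table, evaluate_combination(
        table,
        OptimizerConfig(algorithm="PSO", population=4, iterations=3, seed=21),
        ClassifierSpec(kind="SVM", seed=21),
        SplitSpec(seed=21),
        FitnessSpec(seed=21),
    )


class TestEvaluateCombination:
    def test_no_leakage_into_fitness(self, record):
        """Fitness evaluation must never see a test-partition row."""
        table, rec = record
        from swarmfs.data import stratified_split

        _, test_part = stratified_split(table, SplitSpec(seed=21))
        assert rec.fitness_sample_ids
        assert not (rec.fitness_sample_ids & set(test_part.sample_ids))

    def test_record_is_deterministic(self, record, small_synthetic):
        table, rec = record
        again = evaluate_combination(
            table,
            OptimizerConfig(algorithm="PSO", population=4, iterations=3, seed=21),
            ClassifierSpec(kind="SVM", seed=21),
            SplitSpec(seed=21),
            FitnessSpec(seed=21),
        )
        assert again.metrics.as_dict() == rec.metrics.as_dict()
        np.testing.assert_array_equal(again.mask.bits, rec.mask.bits)

    def test_record_schema(self, record):
        _, rec = record
        row = rec.row()
        assert set(row) == {
            "optimizer", "classifier", "TA", "P", "R", "F1",
            "fs_train_time_s", "test_time_s", "n_features",
        }
        assert rec.n_selected == rec.mask.n_selected


class TestNominateSweep:
    def test_sweep_matches_exhaustive_oracle(self, small_synthetic):
        table, _ = small_synthetic
        opts = [
            OptimizerConfig(algorithm=a, population=3, iterations=2, seed=5)
            for a in ("WO", "GWO")
        ]
        clfs = [ClassifierSpec(kind="SVM", seed=5)]
        res = nominate(table, opts, clfs, SplitSpec(seed=5), FitnessSpec(seed=5))
        assert len(res.records) == 2
        assert res.nominated is nominate_records(res.records)
        assert res.nominated in res.records

    def test_result_serialization(self, small_synthetic, tmp_path):
        table, _ = small_synthetic
        res = nominate(
            table,
            [OptimizerConfig(algorithm="PSO", population=3, iterations=1, seed=2)],
            [ClassifierSpec(kind="SVM", seed=2)],
            SplitSpec(seed=2),
            FitnessSpec(seed=2),
        )
        res.save(tmp_path / "records.csv", tmp_path / "winner.json")
        assert (tmp_path / "records.csv").exists()
        assert "nominated" in (tmp_path / "winner.json").read_text()

    def test_empty_sweep_rejected(self, small_synthetic):
        table, _ = small_synthetic
        with pytest.raises(ValueError):
            nominate(table, [], [ClassifierSpec()])
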