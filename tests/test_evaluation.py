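"""LOSO folds, metrics against independent oracles, training behavior."""

import numpy as np
import pytest
from sklearn.metrics import accuracy_score, precision_recall_fscore_support

from radarposture.evaluation import (
    ConfusionMatrix,
    FoldSpec,
    TrainingConfig,
    _split_fold,
    aggregate_report,
    aggregate_roc,
    evaluate_fold,
    macro_metrics,
    make_loso_folds,
    train_fold,
)
from radarposture.fusion_models import ModelConfig, SamplePair


class TestLosoFolds:
    def test_ten_participants_ten_folds_train_eight(self):
        folds = make_loso_folds([f"P{i}" for i in range(10)])
        assert len(folds) == 10
        assert all(len(f.training_participants) == 8 for f in folds)

    def test_each_participant_tests_and_validates_once(self):
        parts = [f"P{i}" for i in range(10)]
        folds = make_loso_folds(parts)
        assert sorted(f.test_participant for f in folds) == sorted(parts)
        assert sorted(f.validation_participant for f in folds) == sorted(parts)

    def test_roles_disjoint_within_fold(self):
        for f in make_loso_folds(["a", "b", "c", "d"]):
            assert f.test_participant != f.validation_participant
            assert f.test_participant not in f.training_participants
            assert f.validation_participant not in f.training_participants

    def test_three_participants_degenerate_but_valid(self):
        folds = make_loso_folds(["a", "b", "c"])
        assert all(len(f.training_participants) == 1 for f in folds)

    def test_fewer_than_three_rejected(self):
        with pytest.raises(ValueError):
            make_loso_folds(["a", "b"])

    def test_split_rejects_overlapping_roles(self):
        fold = FoldSpec(0, "a", "a", ["b"])
        with pytest.raises(ValueError, match="disjoint"):
            _split_fold(fold, [])


def _expand(counts):
    y_true, y_pred = [], []
    K = counts.shape[0]
    for i in range(K):
        for j in range(K):
            y_true += [i] * counts[i, j]
            y_pred += [j] * counts[i, j]
    return np.array(y_true), np.array(y_pred)


class TestMacroMetrics:
    def test_perfect_diagonal(self):
        r = macro_metrics(ConfusionMatrix(np.diag([10, 10, 10, 10, 10])))
        assert (r.accuracy, r.macro_precision, r.macro_recall, r.macro_f1) \
            == (1.0, 1.0, 1.0, 1.0)

    def test_three_class_example_against_sample_recount(self):
        counts = np.array([[5, 1, 0], [1, 3, 1], [0, 1, 4]])
        r = macro_metrics(ConfusionMatrix(counts))
        assert r.accuracy == pytest.approx(12 / 16)
        y_true, y_pred = _expand(counts)
        p, rec, f1, _ = precision_recall_fscore_support(
            y_true, y_pred, average="macro", zero_division=0)
        assert r.macro_precision == pytest.approx(p, abs=1e-12)
        assert r.macro_recall == pytest.approx(rec, abs=1e-12)
        assert r.macro_f1 == pytest.approx(f1, abs=1e-12)

    def test_constant_predictor_zero_division_convention(self):
        # balanced truth, everything predicted as class 0
        counts = np.zeros((5, 5), dtype=int)
        counts[:, 0] = 8
        r = macro_metrics(ConfusionMatrix(counts))
        assert r.accuracy == pytest.approx(0.2)
        assert r.macro_recall == pytest.approx(0.2)
        assert r.macro_precision == pytest.approx(0.04)
        assert np.all(r.precision_per_class[1:] == 0.0)

    def test_balanced_truth_makes_accuracy_equal_macro_recall(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            counts = np.stack([rng.multinomial(40, rng.dirichlet(np.ones(5)))
                               for _ in range(5)])  # equal row sums
            r = macro_metrics(ConfusionMatrix(counts))
            assert r.accuracy == pytest.approx(r.macro_recall, abs=1e-12)

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            macro_metrics(ConfusionMatrix(np.zeros((5, 5), dtype=int)))


class TestAggregateRoc:
    def test_one_hot_scores_give_perfect_auc(self):
        labels = np.repeat(np.arange(5), 10)
        scores = np.eye(5)[labels]
        roc = aggregate_roc(scores, labels)
        assert all(entry[2] == pytest.approx(1.0) for entry in roc.per_class)

    def test_random_scores_near_chance(self):
        rng = np.random.default_rng(1)
        labels = np.repeat(np.arange(5), 2000)
        scores = rng.random((10000, 5))
        roc = aggregate_roc(scores, labels)
        for entry in roc.per_class:
            assert entry[2] == pytest.approx(0.5, abs=0.05)

    def test_curves_monotone(self):
        rng = np.random.default_rng(2)
        labels = rng.integers(0, 5, 500)
        scores = rng.random((500, 5))
        for entry in aggregate_roc(scores, labels).per_class:
            fpr, tpr, _ = entry
            assert np.all(np.diff(fpr) >= 0) and np.all(np.diff(tpr) >= 0)

    def test_absent_class_reported_missing(self):
        labels = np.zeros(20, dtype=int)
        scores = np.tile([1, 0, 0, 0, 0.0], (20, 1))
        roc = aggregate_roc(scores, labels)
        assert roc.per_class[0] is not None
        assert all(e is None for e in roc.per_class[1:])


class TestAggregateReport:
    def _report(self, acc):
        from radarposture.evaluation import MetricsReport
        return MetricsReport(acc, acc, acc, acc, np.ones(5), np.ones(5),
                             np.ones(5))

    def test_identical_folds_zero_spread(self):
        cm = ConfusionMatrix(np.diag([2, 2, 2, 2, 2]))
        out = aggregate_report([self._report(0.9)] * 3, [cm] * 3)
        assert out["accuracy"] == {"mean": pytest.approx(0.9), "std": 0.0}

    def test_two_fold_mean_and_sample_std(self):
        cm = ConfusionMatrix(np.diag([1, 1, 1, 1, 1]))
        out = aggregate_report([self._report(0.8), self._report(1.0)], [cm, cm])
        assert out["accuracy"]["mean"] == pytest.approx(0.9)
        assert out["accuracy"]["std"] == pytest.approx(0.1414, abs=1e-3)

    def test_cumulative_confusion_adds_fold_totals(self):
        cms = [ConfusionMatrix(np.full((5, 5), i, dtype=int)) for i in (1, 2)]
        out = aggregate_report([self._report(0.5)] * 2, cms)
        assert out["cumulative_confusion"].sum() == sum(c.total for c in cms)


# ---------------------------------------------------------------------------
# Training on a programmatically separable toy set
# ---------------------------------------------------------------------------

def _toy_pair(cls, pid, rng, permutation=None):
    """Label is a deterministic function of a single bright image region."""
    xd = np.zeros((1, 96, 288), dtype=np.float32)
    col = 10 + cls * 54 + int(rng.integers(-3, 4))
    xd[0, 15:80, col:col + 40] = 1.0
    xd += rng.normal(0, 0.01, xd.shape).astype(np.float32)
    xv = np.zeros((1, 50, 80), dtype=np.float32)
    xv[0, :, cls * 16:(cls + 1) * 16] = 1.0
    xv += rng.normal(0, 0.01, xv.shape).astype(np.float32)
    y = cls if permutation is None else int(permutation[cls])
    return SamplePair(xd=np.clip(xd, 0, 1), xv=np.clip(xv, 0, 1), y=y,
                      participant_id=pid)


def _toy_dataset(per_class=8, permutation=None, seed=0):
    rng = np.random.default_rng(seed)
    return [
        _toy_pair(cls, pid, rng, permutation)
        for pid in ("P1", "P2", "P3")
        for cls in range(5)
        for _ in range(per_class)
    ]


_TOY_FOLD = FoldSpec(0, "P3", "P2", ["P1"])
_TOY_CONFIG = TrainingConfig(learning_rate=3e-3, batch_size=8, max_epochs=8,
                             patience=8)


class TestTrainFold:
    @pytest.mark.parametrize("permutation", [None, (2, 0, 4, 1, 3)])
    def test_separable_toy_reaches_high_validation_accuracy(self, permutation):
        dataset = _toy_dataset(permutation=permutation)
        res = train_fold("attn", _TOY_FOLD, dataset, _TOY_CONFIG, seed=0,
                         model_config=ModelConfig.desk_scale())
        assert res.best_val_accuracy >= 0.95
        # with permuted labels the learned structure follows the permutation:
        # test-set predictions recover the permuted labeling
        report, confusion, _, _ = evaluate_fold(res.model, _TOY_FOLD, dataset)
        assert report.accuracy >= 0.9

    def test_checkpoint_is_best_validation_epoch(self):
        res = train_fold("concat", _TOY_FOLD, _toy_dataset(per_class=4),
                         TrainingConfig(learning_rate=3e-3, batch_size=16,
                                        max_epochs=3, patience=3),
                         seed=1, model_config=ModelConfig.desk_scale())
        accs = [e["val_accuracy"] for e in res.log]
        assert res.best_val_accuracy == max(accs)
        assert res.best_epoch == int(np.argmax(accs))  # earliest tie wins

    def test_same_seed_reproduces_weights(self):
        cfg = TrainingConfig(learning_rate=1e-3, batch_size=16, max_epochs=1,
                             patience=1)
        ds = _toy_dataset(per_class=3)
        r1 = train_fold("concat", _TOY_FOLD, ds, cfg, seed=7,
                        model_config=ModelConfig.desk_scale())
        r2 = train_fold("concat", _TOY_FOLD, ds, cfg, seed=7,
                        model_config=ModelConfig.desk_scale())
        for a, b in zip(r1.model.params(), r2.model.params()):
            np.testing.assert_array_equal(a.value, b.value)

    def test_missing_training_participant_rejected(self):
        ds = [p for p in _toy_dataset(per_class=2) if p.participant_id != "P1"]
        with pytest.raises(ValueError, match="train"):
            train_fold("concat", _TOY_FOLD, ds, _TOY_CONFIG, seed=0,
                       model_config=ModelConfig.desk_scale())


class TestEvaluateFold:
    def test_metrics_match_independent_recount(self):
        dataset = _toy_dataset(per_class=4)
        res = train_fold("concat", _TOY_FOLD, dataset,
                         TrainingConfig(learning_rate=3e-3, batch_size=16,
                                        max_epochs=2, patience=2),
                         seed=3, model_config=ModelConfig.desk_scale())
        report, confusion, scores, y_true = evaluate_fold(res.model, _TOY_FOLD,
                                                          dataset)
        y_pred = scores.argmax(axis=1)
        assert report.accuracy == pytest.approx(accuracy_score(y_true, y_pred))
        p, r, f1, _ = precision_recall_fscore_support(
            y_true, y_pred, labels=range(5), average="macro", zero_division=0)
        assert report.macro_f1 == pytest.approx(f1, abs=1e-12)
        assert confusion.total == len(y_true)
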