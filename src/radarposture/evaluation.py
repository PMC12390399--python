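"""Leave-one-subject-out training and evaluation.

Folds hold out one participant for testing and one for validation (rotation:
fold i tests participant i and validates participant i+1 mod n), training on
the remaining n-2.  Training minimizes cross-entropy with Adam; after each
epoch validation accuracy is logged, the best-validation checkpoint is kept
(ties break to the earliest epoch) and training stops early when validation
accuracy has not improved for ``patience`` epochs.

Metrics follow the standard confusion-matrix definitions: accuracy is the
trace over the total; per-class precision TP/(TP+FP) and recall TP/(TP+FN)
are macro-averaged over the K=5 classes, with the convention that a zero
denominator yields 0.  Per-class one-vs-rest ROC/AUC is computed on the test
scores pooled over all folds.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import roc_curve as _sk_roc_curve

from .fusion_models import ModelConfig, SamplePair, make_model
from .radar_io import CLASSES
from . import nn

N_CLASSES = len(CLASSES)


# ---------------------------------------------------------------------------
# Folds
# ---------------------------------------------------------------------------

@dataclass
class FoldSpec:
    fold_id: int
    test_participant: str
    validation_participant: str
    training_participants: list[str]


def make_loso_folds(participants: Sequence[str]) -> list[FoldSpec]:
    """Rotation LOSO folds: test i, validate (i+1) mod n, train the rest.

    Every participant serves exactly once as test and once as validation;
    training size is n - 2.
    """
    participants = list(participants)
    n = len(participants)
    if n < 3:
        raise ValueError(f"need at least 3 participants, got {n}")
    if len(set(participants)) != n:
        raise ValueError("participants must be unique")
    folds = []
    for i, test in enumerate(participants):
        val = participants[(i + 1) % n]
        train = [p for p in participants if p not in (test, val)]
        folds.append(FoldSpec(i, test, val, train))
    return folds


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

@dataclass
class ConfusionMatrix:
    """K x K counts; rows are true classes, columns predicted classes."""

    counts: np.ndarray

    @classmethod
    def from_predictions(cls, y_true, y_pred, n_classes: int = N_CLASSES):
        counts = np.zeros((n_classes, n_classes), dtype=np.int64)
        for t, p in zip(np.asarray(y_true), np.asarray(y_pred)):
            counts[int(t), int(p)] += 1
        return cls(counts)

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class MetricsReport:
    accuracy: float
    macro_precision: float
    macro_recall: float
    macro_f1: float
    precision_per_class: np.ndarray
    recall_per_class: np.ndarray
    f1_per_class: np.ndarray
    fold_id: Optional[int] = None


def macro_metrics(confusion: ConfusionMatrix, fold_id: Optional[int] = None
                  ) -> MetricsReport:
    """Accuracy and macro precision/recall/F1 from a confusion matrix.

    A class with no predicted (or no true) instances contributes precision
    (or recall) 0; F1 is 0 where precision + recall = 0.
    """
    c = np.asarray(confusion.counts, dtype=np.float64)
    n = c.sum()
    if n < 1:
        raise ValueError("empty confusion matrix")
    tp = np.diag(c)
    fp = c.sum(axis=0) - tp
    fn = c.sum(axis=1) - tp
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(tp + fp > 0, tp / (tp + fp), 0.0)
        recall = np.where(tp + fn > 0, tp / (tp + fn), 0.0)
        pr = precision + recall
        f1 = np.where(pr > 0, 2.0 * precision * recall / np.where(pr > 0, pr, 1.0), 0.0)
    return MetricsReport(
        accuracy=float(tp.sum() / n),
        macro_precision=float(precision.mean()),
        macro_recall=float(recall.mean()),
        macro_f1=float(f1.mean()),
        precision_per_class=precision,
        recall_per_class=recall,
        f1_per_class=f1,
        fold_id=fold_id,
    )


@dataclass
class RocResult:
    """Per-class one-vs-rest ROC on pooled test scores.

    ``per_class[k]`` is ``(fpr, tpr, auc)`` or ``None`` when class k is
    absent from the pooled truth (AUC undefined).
    """

    per_class: list


def aggregate_roc(scores: np.ndarray, labels: np.ndarray,
                  n_classes: int = N_CLASSES) -> RocResult:
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    out = []
    for k in range(n_classes):
        truth = (labels == k).astype(int)
        if truth.sum() == 0:
            out.append(None)
            continue
        fpr, tpr, _ = _sk_roc_curve(truth, scores[:, k])
        out.append((fpr, tpr, float(_sk_auc(fpr, tpr))))
    return RocResult(out)


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

@dataclass
class TrainingConfig:
    """Optimization settings (all exposed; defaults are full-scale values)."""

    learning_rate: float = 1e-3
    batch_size: int = 64
    max_epochs: int = 50
    patience: int = 10
    steps_per_epoch: Optional[int] = None  # None -> full pass over the data
    val_max_samples: Optional[int] = None  # None -> full validation set


def _stack(pairs: Sequence[SamplePair]):
    xd = np.stack([p.xd for p in pairs]).astype(np.float32)
    xv = np.stack([p.xv for p in pairs]).astype(np.float32)
    y = np.array([p.y for p in pairs], dtype=np.int64)
    return xd, xv, y


def predict_scores(model, pairs: Sequence[SamplePair],
                   batch_size: int = 64) -> np.ndarray:
    """Post-softmax class probabilities, (n_samples, K)."""
    xd, xv, _ = _stack(pairs)
    out = []
    for i in range(0, len(pairs), batch_size):
        logits = model.forward(xd[i:i + batch_size], xv[i:i + batch_size],
                               train=False)
        out.append(nn.softmax(logits))
    if hasattr(model, "free_caches"):
        model.free_caches()
    return np.concatenate(out, axis=0)


def _accuracy(model, pairs: Sequence[SamplePair], batch_size: int) -> float:
    scores = predict_scores(model, pairs, batch_size)
    y = np.array([p.y for p in pairs])
    return float(np.mean(scores.argmax(axis=1) == y))


@dataclass
class TrainResult:
    model: object
    log: list  # one dict per epoch: epoch, train_loss, val_accuracy
    best_epoch: int
    best_val_accuracy: float


def _split_fold(fold: FoldSpec, dataset: Sequence[SamplePair]):
    roles = {p: "train" for p in fold.training_participants}
    if fold.test_participant in roles or fold.validation_participant in roles \
            or fold.test_participant == fold.validation_participant:
        raise ValueError("fold roles are not disjoint")
    roles[fold.validation_participant] = "val"
    roles[fold.test_participant] = "test"
    split = {"train": [], "val": [], "test": []}
    for pair in dataset:
        role = roles.get(pair.participant_id)
        if role is not None:
            split[role].append(pair)
    for name in ("train", "val", "test"):
        if not split[name]:
            raise ValueError(f"fold {fold.fold_id}: empty {name} set")
    return split


def train_fold(
    model_name: str,
    fold: FoldSpec,
    dataset: Sequence[SamplePair],
    training_config: Optional[TrainingConfig] = None,
    seed: int = 0,
    model_config: Optional[ModelConfig] = None,
) -> TrainResult:
    """Train one fold; returns the best-validation checkpoint and the log."""
    cfg = training_config or TrainingConfig()
    split = _split_fold(fold, dataset)
    mc = model_config or ModelConfig()
    mc = dataclasses.replace(mc, seed=seed)
    model = make_model(model_name, mc)
    opt = nn.Adam(model.params(), lr=cfg.learning_rate)
    rng = np.random.default_rng(seed + 1)

    xd, xv, y = _stack(split["train"])
    val_pairs = split["val"]
    if cfg.val_max_samples is not None and len(val_pairs) > cfg.val_max_samples:
        idx = np.linspace(0, len(val_pairs) - 1, cfg.val_max_samples).astype(int)
        val_pairs = [val_pairs[i] for i in idx]

    log = []
    best = (-1.0, -1, None)  # (val_acc, epoch, snapshot)
    since_improvement = 0
    n = len(y)
    for epoch in range(cfg.max_epochs):
        order = rng.permutation(n)
        if cfg.steps_per_epoch is not None:
            order = order[: cfg.steps_per_epoch * cfg.batch_size]
        losses = []
        for i in range(0, len(order), cfg.batch_size):
            sel = order[i:i + cfg.batch_size]
            if sel.size < 2:
                continue  # batch statistics need >= 2 samples
            opt.zero_grad()
            logits = model.forward(xd[sel], xv[sel], train=True)
            loss, dlogits = nn.cross_entropy(logits, y[sel])
            model.backward(dlogits)
            opt.step()
            losses.append(loss)
        val_acc = _accuracy(model, val_pairs, cfg.batch_size)
        log.append({"epoch": epoch, "train_loss": float(np.mean(losses)),
                    "val_accuracy": val_acc})
        if val_acc > best[0]:  # strict: ties keep the earliest epoch
            best = (val_acc, epoch, model.snapshot())
            since_improvement = 0
        else:
            since_improvement += 1
            if since_improvement >= cfg.patience:
                break
    model.restore(best[2])
    model.free_caches()
    return TrainResult(model=model, log=log, best_epoch=best[1],
                       best_val_accuracy=best[0])


def evaluate_fold(model, fold: FoldSpec, dataset: Sequence[SamplePair],
                  batch_size: int = 64):
    """Evaluate on the fold's held-out test participant.

    Returns ``(MetricsReport, ConfusionMatrix, scores, labels)`` where
    ``scores`` are the per-sample softmax probabilities retained for ROC
    pooling.
    """
    test = [p for p in dataset if p.participant_id == fold.test_participant]
    if not test:
        raise ValueError("empty test set")
    scores = predict_scores(model, test, batch_size)
    y_true = np.array([p.y for p in test])
    y_pred = scores.argmax(axis=1)
    confusion = ConfusionMatrix.from_predictions(y_true, y_pred)
    report = macro_metrics(confusion, fold_id=fold.fold_id)
    return report, confusion, scores, y_true


# ---------------------------------------------------------------------------
# Aggregation
# ---------------------------------------------------------------------------

def aggregate_report(reports: Sequence[MetricsReport],
                     confusions: Sequence[ConfusionMatrix]) -> dict:
    """Mean +/- sample standard deviation per metric, cumulative confusion."""
    if not reports:
        raise ValueError("no folds to aggregate")

    def ms(values):
        v = np.asarray(values, dtype=np.float64)
        sd = float(np.std(v, ddof=1)) if v.size > 1 else 0.0
        return {"mean": float(v.mean()), "std": sd}

    cumulative = sum((c.counts for c in confusions),
                     np.zeros((N_CLASSES, N_CLASSES), dtype=np.int64))
    row_sums = cumulative.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore"):
        row_pct = np.where(row_sums > 0, 100.0 * cumulative / row_sums, 0.0)
    return {
        "accuracy": ms([r.accuracy for r in reports]),
        "macro_precision": ms([r.macro_precision for r in reports]),
        "macro_recall": ms([r.macro_recall for r in reports]),
        "macro_f1": ms([r.macro_f1 for r in reports]),
        "cumulative_confusion": cumulative,
        "cumulative_confusion_row_pct": row_pct,
        "n_folds": len(reports),
    }


def run_loso(
    dataset: Sequence[SamplePair],
    model_name: str = "attn",
    training_config: Optional[TrainingConfig] = None,
    master_seed: int = 0,
    model_config: Optional[ModelConfig] = None,
    folds: Optional[list[FoldSpec]] = None,
) -> dict:
    """Full LOSO-CV run: train/evaluate every fold, pool scores for ROC."""
    participants = sorted({p.participant_id for p in dataset})
    folds = folds or make_loso_folds(participants)
    reports, confusions, all_scores, all_labels, results = [], [], [], [], []
    for fold in folds:
        res = train_fold(model_name, fold, dataset, training_config,
                         seed=master_seed + fold.fold_id,
                         model_config=model_config)
        report, confusion, scores, labels = evaluate_fold(res.model, fold, dataset)
        reports.append(report)
        confusions.append(confusion)
        all_scores.append(scores)
        all_labels.append(labels)
        results.append(res)
    summary = aggregate_report(reports, confusions)
    roc = aggregate_roc(np.concatenate(all_scores), np.concatenate(all_labels))
    return {
        "folds": folds,
        "reports": reports,
        "confusions": confusions,
        "summary": summary,
        "roc": roc,
        "train_results": results,
        "pooled_scores": np.concatenate(all_scores),
        "pooled_labels": np.concatenate(all_labels),
    }
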