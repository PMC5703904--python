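"""Performance measures: confusion counts, accuracy/TPR/FPR, empirical ROC
curves and trapezoidal AUC, confidence reports, association-rule confidence,
and cross-validated orchestration of any learner.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .synthetic_cohort import CohortTable

__all__ = [
    "ConfusionMatrix",
    "ROCCurve",
    "ConfidenceReport",
    "confusion_matrix",
    "accuracy",
    "tpr",
    "fpr",
    "roc_curve",
    "auc",
    "confidence_report",
    "rule_confidence",
    "crossval_evaluate",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class ROCCurve:
    """Empirical step ROC: thresholds descending, points from (0,0) to (1,1)."""

    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray

    def points(self) -> np.ndarray:
        return np.column_stack([self.fpr, self.tpr])


@dataclass
class ConfidenceReport:
    mean_correct: float | None
    mean_incorrect: float | None
    min_confidence: float
    max_confidence: float
    coverage_table: list[dict] = field(default_factory=list)


def confusion_matrix(pred_labels: np.ndarray, true_labels: np.ndarray) -> ConfusionMatrix:
    pred = np.asarray(pred_labels)
    truth = np.asarray(true_labels)
    if pred.shape != truth.shape:
        raise ValueError("prediction and truth vectors differ in length")
    if not (np.all(np.isin(pred, (-1, 1))) and np.all(np.isin(truth, (-1, 1)))):
        raise ValueError("labels must be -1 or +1")
    return ConfusionMatrix(
        tp=int(np.sum((pred == 1) & (truth == 1))),
        fp=int(np.sum((pred == 1) & (truth == -1))),
        tn=int(np.sum((pred == -1) & (truth == -1))),
        fn=int(np.sum((pred == -1) & (truth == 1))),
    )


def accuracy(cm: ConfusionMatrix) -> float:
    return (cm.tp + cm.tn) / cm.n


def tpr(cm: ConfusionMatrix) -> float:
    """Sensitivity; undefined (NaN) when there are no positives."""
    denom = cm.tp + cm.fn
    return cm.tp / denom if denom else float("nan")


def fpr(cm: ConfusionMatrix) -> float:
    """1 - specificity; undefined (NaN) when there are no negatives."""
    denom = cm.fp + cm.tn
    return cm.fp / denom if denom else float("nan")


def roc_curve(scores: np.ndarray, true_labels: np.ndarray) -> ROCCurve:
    """Standard empirical step curve over all distinct score thresholds,
    ties grouped; anchored at (0,0) and (1,1)."""
    from sklearn.metrics import roc_curve as _sk_roc

    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(true_labels)
    if np.unique(truth).size < 2:
        raise ValueError("ROC needs both classes present")
    f, t, thr = _sk_roc(truth, scores, pos_label=1, drop_intermediate=False)
    return ROCCurve(thresholds=thr, fpr=f, tpr=t)


def auc(roc: ROCCurve) -> float:
    """Trapezoidal area; equals the tie-corrected Mann-Whitney concordance."""
    return float(np.trapezoid(roc.tpr, roc.fpr))


DEFAULT_COVERAGE_LEVELS = tuple(np.arange(0.50, 1.0, 0.05))


def confidence_report(
    confidences: np.ndarray,
    correct: np.ndarray,
    levels: Sequence[float] = DEFAULT_COVERAGE_LEVELS,
) -> ConfidenceReport:
    """Mean confidence of correct vs incorrect predictions plus a coverage
    table: at each level c, the fraction of predictions with confidence >= c
    and their accuracy.  ``correct`` is boolean."""
    conf = np.asarray(confidences, dtype=float)
    ok = np.asarray(correct, dtype=bool)
    if conf.shape != ok.shape:
        raise ValueError("confidences and correctness differ in length")
    if not np.isfinite(conf).all():
        raise ValueError("confidences must be finite")
    mean_correct = float(conf[ok].mean()) if ok.any() else None
    mean_incorrect = float(conf[~ok].mean()) if (~ok).any() else None
    coverage = []
    for c in levels:
        covered = conf >= c
        coverage.append(
            {
                "level": float(c),
                "coverage": float(covered.mean()),
                "accuracy": float(ok[covered].mean()) if covered.any() else None,
            }
        )
    return ConfidenceReport(
        mean_correct=mean_correct,
        mean_incorrect=mean_incorrect,
        min_confidence=float(conf.min()),
        max_confidence=float(conf.max()),
        coverage_table=coverage,
    )


def rule_confidence(antecedent_mask: np.ndarray, consequent_mask: np.ndarray) -> float:
    """Association-rule confidence: of the rows satisfying the antecedent,
    the fraction also satisfying the consequent."""
    a = np.asarray(antecedent_mask, dtype=bool)
    c = np.asarray(consequent_mask, dtype=bool)
    if a.shape != c.shape:
        raise ValueError("masks differ in length")
    support = a.sum()
    if support == 0:
        raise ValueError("antecedent has empty support")
    return float((a & c).sum() / support)


def crossval_evaluate(
    table: CohortTable,
    train_fn: Callable[[CohortTable], object],
    k: int = 10,
    seed: int = 0,
    stratified: bool = True,
) -> dict:
    """k-fold cross-validation of any trainer under the five measures.

    ``train_fn`` maps a training CohortTable to a TrainedModel.  Returns
    per-fold metrics plus mean and (ddof=1) standard deviation — the error
    bars conventionally drawn on cross-validated bar charts.
    """
    from .learners import predict
    from .preprocess import make_cv_folds

    folds = make_cv_folds(table, k=k, seed=seed, stratified=stratified)
    per_fold = []
    for tr_idx, va_idx in folds:
        model = train_fn(table.take_rows(tr_idx))
        val = table.take_rows(va_idx)
        pred = predict(model, val)
        cm = confusion_matrix(pred.labels, val.labels)
        try:
            fold_auc = auc(roc_curve(pred.scores, val.labels))
        except ValueError:
            fold_auc = float("nan")
        rep = confidence_report(pred.confidences, pred.labels == val.labels)
        per_fold.append(
            {
                "accuracy": accuracy(cm),
                "auc": fold_auc,
                "tpr": tpr(cm),
                "fpr": fpr(cm),
                "mean_correct": rep.mean_correct,
                "mean_incorrect": rep.mean_incorrect,
            }
        )
    summary = {}
    for key in per_fold[0]:
        vals = np.array([f[key] for f in per_fold if f[key] is not None], dtype=float)
        vals = vals[~np.isnan(vals)]
        summary[key] = {
            "mean": float(vals.mean()) if vals.size else None,
            "sd": float(vals.std(ddof=1)) if vals.size > 1 else None,
        }
    return {"folds": per_fold, "summary": summary}
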