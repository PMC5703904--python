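"""Cost-sensitive hybrid model (CSHM).

Class-imbalance is handled by rescaling: a positive (minority) instance
receives weight lambda1 and a negative one lambda2, so the minority class
influences every base learner lambda1/lambda2 times as much per instance.
Heterogeneous bases (by default forward-selection logistic regression, an
RBF SVM, and a CHAID tree) are trained on the rescaled weights, screened by
a validation-AUC discard rule (drop bases with AUC < 0.6), and combined
either by the sign of the average base label or by confidence-weighted
voting.  With lambda1 = lambda2 the weights are all equal and the ensemble
reduces to plain class-balance learning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .evaluation import auc, roc_curve
from .learners import LearnerConfig, Predictions, TrainedModel, predict, train_learner
from .preprocess import SplitSpec, split_train_test
from .synthetic_cohort import CohortTable

__all__ = [
    "CostSpec",
    "EnsembleModel",
    "rescale_instance_weights",
    "combine_sign_average",
    "combine_confidence_weighted",
    "apply_discard",
    "train_cshm",
    "predict_ensemble",
]

log = logging.getLogger(__name__)

DEFAULT_BASE_KINDS = ("LR", "SVM", "CHAID")


@dataclass(frozen=True)
class CostSpec:
    """Misclassification costs.

    ``lambda1`` is the cost of misclassifying a true positive, ``lambda2``
    that of a true negative; correct predictions cost zero (the implied 2x2
    cost matrix has a zero diagonal).  ``c_hard`` stores an optional expert
    cost bound for completeness; the rescaling realisation used here never
    optimises against it.
    """

    lambda1: float = 1.0
    lambda2: float = 1.0
    c_hard: float | None = None

    def __post_init__(self) -> None:
        if self.lambda1 <= 0 or self.lambda2 <= 0:
            raise ValueError("lambda1 and lambda2 must be positive")
        if self.c_hard is not None and self.c_hard <= 0:
            raise ValueError("c_hard must be positive when given")

    @property
    def cost_matrix(self) -> np.ndarray:
        """Rows: true class (-1, +1); columns: predicted class (-1, +1)."""
        return np.array([[0.0, self.lambda2], [self.lambda1, 0.0]])

    @property
    def cost_ratio(self) -> float:
        return self.lambda1 / self.lambda2


@dataclass
class EnsembleModel:
    base_models: list[TrainedModel]
    kept_mask: np.ndarray
    combination_rule: str  # "confidence_weighted" | "sign_average" | "max_confidence"
    cost_spec: CostSpec
    validation_aucs: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.base_models:
            raise ValueError("ensemble needs at least one base model")
        if not np.asarray(self.kept_mask).any():
            raise ValueError("at least one base model must be kept")

    @property
    def kept_models(self) -> list[TrainedModel]:
        return [m for m, k in zip(self.base_models, self.kept_mask) if k]


def rescale_instance_weights(labels: np.ndarray, cost: CostSpec) -> np.ndarray:
    """Per-instance weights: lambda1 on +1 rows, lambda2 on -1 rows,
    normalised to mean 1 so the total effective sample size is unchanged."""
    labels = np.asarray(labels)
    if not np.all(np.isin(labels, (-1, 1))):
        raise ValueError("labels must be -1 or +1")
    w = np.where(labels == 1, cost.lambda1, cost.lambda2).astype(float)
    return w / w.mean()


def combine_sign_average(base_labels: np.ndarray) -> int:
    """Sign of the mean base label; an exact tie goes to -1 (the majority
    class in the imbalanced setting, so positives need strict evidence)."""
    labels = np.asarray(base_labels)
    if labels.size == 0:
        raise ValueError("no base labels to combine")
    s = labels.mean()
    return 1 if s > 0 else -1


def combine_confidence_weighted(
    base_labels: np.ndarray, base_confidences: np.ndarray
) -> tuple[int, float]:
    """Summed-confidence voting.

    vote(c) = sum of confidences of bases predicting class c; the winning
    class takes the larger vote, ties going first to the class holding the
    single largest base confidence and then to -1.  The ensemble confidence
    is the winning vote share, which can drop below 0.5 with 3+ bases.
    """
    labels = np.asarray(base_labels)
    conf = np.asarray(base_confidences, dtype=float)
    if labels.shape != conf.shape:
        raise ValueError("labels and confidences differ in length")
    if np.any(conf < 0.5 - 1e-9) or np.any(conf > 1.0 + 1e-9):
        raise ValueError("base confidences must lie in [0.5, 1]")
    vote_pos = conf[labels == 1].sum()
    vote_neg = conf[labels == -1].sum()
    total = conf.sum()
    if vote_pos > vote_neg:
        label = 1
    elif vote_neg > vote_pos:
        label = -1
    else:
        top = labels[np.argmax(conf)]
        label = int(top) if np.sum(conf == conf.max()) == 1 else -1
    share = (vote_pos if label == 1 else vote_neg) / total
    return label, float(share)


def apply_discard(
    base_models: list[TrainedModel], validation: CohortTable, auc_threshold: float = 0.6
) -> np.ndarray:
    """Keep a base iff its validation AUC >= threshold; if none survive,
    keep the single best with a warning."""
    if np.unique(validation.labels).size < 2:
        raise ValueError("validation table must contain both classes")
    aucs = np.array(
        [auc(roc_curve(predict(m, validation).scores, validation.labels)) for m in base_models]
    )
    kept = aucs >= auc_threshold
    if not kept.any():
        log.warning("all bases below AUC %.2f; keeping the best (AUC %.3f)", auc_threshold, aucs.max())
        kept = np.zeros_like(kept)
        kept[int(np.argmax(aucs))] = True
    return kept


def train_cshm(
    train: CohortTable,
    cost: CostSpec,
    base_kinds: tuple[str, ...] = DEFAULT_BASE_KINDS,
    rule: str = "confidence_weighted",
    seed: int = 0,
    discard_auc: float = 0.6,
    base_configs: dict[str, LearnerConfig] | None = None,
) -> EnsembleModel:
    """Train the cost-sensitive ensemble.

    An internal stratified 20% slice of the training data is held out to
    compute the discard-rule AUCs; bases that survive are refitted on the
    full (rescaled-weight) training data.
    """
    if rule not in ("confidence_weighted", "sign_average", "max_confidence"):
        raise ValueError(f"unknown combination rule {rule!r}")
    base_configs = base_configs or {}
    inner_train, inner_val = split_train_test(
        train, SplitSpec(train_fraction=0.8, stratified=True, seed=seed)
    )

    screened: list[TrainedModel] = []
    for i, kind in enumerate(base_kinds):
        cfg = base_configs.get(kind, LearnerConfig(kind=kind, seed=seed + i))
        w = rescale_instance_weights(inner_train.labels, cost)
        screened.append(train_learner(inner_train, cfg, w))
    kept = apply_discard(screened, inner_val, discard_auc)
    val_aucs = [
        auc(roc_curve(predict(m, inner_val).scores, inner_val.labels)) for m in screened
    ]

    final: list[TrainedModel] = []
    w_full = rescale_instance_weights(train.labels, cost)
    for i, kind in enumerate(base_kinds):
        if kept[i]:
            cfg = base_configs.get(kind, LearnerConfig(kind=kind, seed=seed + i))
            final.append(train_learner(train, cfg, w_full))
        else:
            final.append(screened[i])  # retained for inspection, masked out

    return EnsembleModel(
        base_models=final,
        kept_mask=kept,
        combination_rule=rule,
        cost_spec=cost,
        validation_aucs=val_aucs,
    )


def predict_ensemble(model: EnsembleModel, table: CohortTable) -> Predictions:
    """Combine the kept bases' predictions under the ensemble's rule.

    The reported score is a continuous positive-class probability — the
    confidence-weighted mean of the base probability scores (or the plain
    mean under the sign rule) — which supports ROC/AUC analysis of the
    ensemble; labels come from the voting rule, and the ensemble confidence
    is the winning vote share.
    """
    base_preds = [predict(m, table) for m in model.kept_models]
    L = len(base_preds)
    n = table.n_subjects
    labels = np.empty(n, dtype=int)
    confidences = np.empty(n)
    scores = np.empty(n)
    b_labels = np.stack([p.labels for p in base_preds])        # (L, n)
    b_conf = np.stack([p.confidences for p in base_preds])

    b_scores = np.stack([p.scores for p in base_preds])
    if model.combination_rule == "sign_average":
        for i in range(n):
            labels[i] = combine_sign_average(b_labels[:, i])
        share_pos = (b_labels == 1).mean(axis=0)
        scores = b_scores.mean(axis=0)
        confidences = np.maximum(share_pos, 1.0 - share_pos)
    elif model.combination_rule == "max_confidence":
        # highest-confidence base wins outright
        top = np.argmax(b_conf, axis=0)
        labels = b_labels[top, np.arange(n)]
        confidences = b_conf[top, np.arange(n)]
        scores = b_scores[top, np.arange(n)]
    else:  # confidence_weighted
        for i in range(n):
            labels[i], confidences[i] = combine_confidence_weighted(b_labels[:, i], b_conf[:, i])
        scores = (b_conf * b_scores).sum(axis=0) / b_conf.sum(axis=0)
    return Predictions(scores=scores, labels=labels, confidences=confidences)
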