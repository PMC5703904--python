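"""Five base classifiers behind one uniform contract.

Every trainer takes a complete (imputed) cohort plus per-instance weights
and returns a :class:`TrainedModel` whose predictions expose, per subject:

* ``score``      — estimated probability of the positive class, in [0, 1]
* ``label``      — +1 if score >= threshold (default 0.50) else -1
* ``confidence`` — max(score, 1 - score), in [0.5, 1]

The learners are the ones conventionally applied to early-pregnancy EHR
tabular data: forward-selection logistic regression, naive Bayes, a boosted
multilayer perceptron, an RBF-kernel SVM with Platt-calibrated scores, and
a CHAID decision tree (chi-square category merging with Bonferroni-adjusted
split selection), implemented here from scratch since no mainstream Python
library ships CHAID.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from math import factorial
from typing import Callable

import numpy as np
from scipy import stats

from .synthetic_cohort import CohortTable

__all__ = [
    "LearnerConfig",
    "TrainedModel",
    "Predictions",
    "train_logistic_forward",
    "train_naive_bayes",
    "train_mlp_boosted",
    "train_svm_rbf",
    "train_chaid",
    "train_learner",
    "predict",
]

log = logging.getLogger(__name__)

DEFAULT_SETTINGS: dict[str, dict] = {
    "LR": {"entry_alpha": 0.05},
    "NB": {"laplace": 1.0},
    "NN": {
        "n_components": 10,
        "max_cycles": 250,
        "holdout_fraction": 0.30,
        "learning_rate_init": 0.01,
    },
    "SVM": {"C": 1.0, "tol": 1.0e-3, "epsilon": 0.1},  # epsilon is a regression
    # setting kept for config fidelity; classification ignores it (notice logged)
    "CHAID": {
        "max_depth": 16,
        "min_parent_fraction": 0.02,
        "min_child_fraction": 0.01,
        "merge_alpha": 0.05,
        "split_alpha": 0.05,
        "max_merge_iterations": 200,
    },
}


@dataclass(frozen=True)
class LearnerConfig:
    kind: str = "LR"
    threshold: float = 0.50
    seed: int = 0
    settings: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in DEFAULT_SETTINGS:
            raise ValueError(f"unknown learner kind {self.kind!r}")
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must lie strictly in (0, 1)")

    def setting(self, key: str):
        return self.settings.get(key, DEFAULT_SETTINGS[self.kind][key])


@dataclass
class Predictions:
    scores: np.ndarray
    labels: np.ndarray
    confidences: np.ndarray


class _ConstantScorer:
    """Always returns one probability (degenerate fits)."""

    def __init__(self, p: float):
        self.p = float(p)

    def __call__(self, X: np.ndarray) -> np.ndarray:
        return np.full(X.shape[0], self.p)


class _ColumnSubsetLrScorer:
    def __init__(self, clf, cols: list[int]):
        self.clf = clf
        self.cols = list(cols)

    def __call__(self, X: np.ndarray) -> np.ndarray:
        return self.clf.predict_proba(X[:, self.cols])[:, 1]


class _NaiveBayesScorer:
    def __init__(self, log_prior, tables, class_w, laplace):
        self.log_prior = log_prior
        self.tables = tables
        self.class_w = class_w
        self.laplace = laplace

    def __call__(self, Xnew: np.ndarray) -> np.ndarray:
        log_post = np.tile(self.log_prior, (Xnew.shape[0], 1))
        for j, (levels, log_cond) in enumerate(self.tables):
            idx = np.searchsorted(levels, Xnew[:, j])
            idx_clip = np.clip(idx, 0, levels.size - 1)
            seen = levels[idx_clip] == Xnew[:, j]
            contrib = log_cond[:, idx_clip].T
            unseen_lp = np.log(self.laplace) - np.log(self.class_w + self.laplace * levels.size)
            contrib[~seen] = unseen_lp
            log_post += contrib
        log_post -= log_post.max(axis=1, keepdims=True)
        post = np.exp(log_post)
        return post[:, 1] / post.sum(axis=1)


class _BoostedScorer:
    def __init__(self, alphas, estimators):
        self.alphas = alphas
        self.estimators = estimators

    def __call__(self, Xnew: np.ndarray) -> np.ndarray:
        out = np.zeros(Xnew.shape[0])
        for a, mlp in zip(self.alphas, self.estimators):
            proba = mlp.predict_proba(Xnew)
            pos_col = int(np.flatnonzero(mlp.classes_ == 1)[0])
            out += a * proba[:, pos_col]
        return out


class _PlattSvmScorer:
    def __init__(self, svc, platt):
        self.svc = svc
        self.platt = platt

    def __call__(self, Xnew: np.ndarray) -> np.ndarray:
        d = self.svc.decision_function(Xnew)
        return self.platt.predict_proba(d.reshape(-1, 1))[:, 1]


class _ChaidScorer:
    def __init__(self, root):
        self.root = root

    def __call__(self, Xnew: np.ndarray) -> np.ndarray:
        out = np.empty(Xnew.shape[0])
        for i in range(Xnew.shape[0]):
            node = self.root
            while node.feature_idx is not None:
                gi = node.group_of.get(float(Xnew[i, node.feature_idx]), node.heaviest)
                node = node.children[gi]
            out[i] = node.score
        return out


@dataclass
class TrainedModel:
    """A fitted predictor with the score/label/confidence contract."""

    kind: str
    feature_names: list[str]
    threshold: float
    _scorer: Callable[[np.ndarray], np.ndarray]
    detail: dict = field(default_factory=dict)

    def predict_scores(self, X: np.ndarray) -> np.ndarray:
        return np.clip(self._scorer(np.asarray(X, dtype=float)), 0.0, 1.0)


def predict(model: TrainedModel, table: CohortTable) -> Predictions:
    """Score a cohort with a trained model; schema-checked."""
    for want, got in zip(model.feature_names, table.feature_names):
        if want != got:
            raise ValueError(f"schema mismatch: expected feature {want!r}, found {got!r}")
    if len(table.feature_names) != len(model.feature_names):
        raise ValueError("schema mismatch: different number of features")
    X = _matrix(table)
    scores = model.predict_scores(X)
    labels = np.where(scores >= model.threshold, 1, -1)
    confidences = np.maximum(scores, 1.0 - scores)
    return Predictions(scores=scores, labels=labels, confidences=confidences)


def _matrix(table: CohortTable) -> np.ndarray:
    if np.isnan(table.values).any():
        raise ValueError("learners need complete data; impute first")
    return table.values


def _weights(table: CohortTable, weights: np.ndarray | None) -> np.ndarray:
    if weights is None:
        return np.ones(table.n_subjects)
    w = np.asarray(weights, dtype=float)
    if w.shape != (table.n_subjects,) or np.any(w <= 0):
        raise ValueError("weights must be positive, one per subject")
    return w


# ---------------------------------------------------------------------------
# Logistic regression with forward selection
# ---------------------------------------------------------------------------

def _weighted_deviance(p: np.ndarray, y01: np.ndarray, w: np.ndarray) -> float:
    eps = 1e-12
    ll = np.sum(w * (y01 * np.log(p + eps) + (1 - y01) * np.log(1 - p + eps)))
    return -2.0 * float(ll)


def _fit_lr(X: np.ndarray, y01: np.ndarray, w: np.ndarray):
    """Unpenalised weighted logistic fit; ridge-stabilised on separation."""
    from sklearn.linear_model import LogisticRegression

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        clf = LogisticRegression(C=np.inf, solver="lbfgs", max_iter=2000)
        clf.fit(X, y01, sample_weight=w)
    if np.abs(clf.coef_).max(initial=0.0) > 30.0:
        log.warning("quasi-separation detected; falling back to ridge-stabilised logistic fit")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            clf = LogisticRegression(C=1.0, solver="lbfgs", max_iter=2000)
            clf.fit(X, y01, sample_weight=w)
    return clf


def train_logistic_forward(
    train: CohortTable, config: LearnerConfig | None = None, weights: np.ndarray | None = None
) -> TrainedModel:
    """Weighted main-effects logistic regression with forward selection.

    Starting from the intercept-only model, each step adds the candidate
    feature that most reduces the weighted deviance, provided its
    likelihood-ratio p-value is below the entry criterion (default 0.05);
    otherwise selection stops.
    """
    config = config or LearnerConfig(kind="LR")
    X = _matrix(train)
    w = _weights(train, weights)
    y01 = (train.labels == 1).astype(int)
    if len(np.unique(y01)) < 2:
        raise ValueError("training data must contain both classes")
    alpha = config.setting("entry_alpha")

    selected: list[int] = []
    base_rate = float(np.average(y01, weights=w))
    current_dev = _weighted_deviance(np.full_like(w, base_rate), y01, w)
    remaining = list(range(X.shape[1]))
    # skip constant columns: they cannot change the likelihood
    remaining = [j for j in remaining if np.unique(X[:, j]).size > 1]

    while remaining:
        best = None
        for j in remaining:
            clf = _fit_lr(X[:, selected + [j]], y01, w)
            dev = _weighted_deviance(clf.predict_proba(X[:, selected + [j]])[:, 1], y01, w)
            if best is None or dev < best[1]:
                best = (j, dev)
        j, dev = best
        p_entry = stats.chi2.sf(max(0.0, current_dev - dev), df=1)
        if p_entry >= alpha:
            break
        selected.append(j)
        remaining.remove(j)
        current_dev = dev

    if selected:
        clf = _fit_lr(X[:, selected], y01, w)
        scorer = _ColumnSubsetLrScorer(clf, selected)
        detail = {
            "selected": [train.feature_names[j] for j in selected],
            "coef": clf.coef_[0].tolist(),
            "intercept": float(clf.intercept_[0]),
        }
    else:
        scorer = _ConstantScorer(base_rate)
        detail = {"selected": [], "intercept_only_rate": base_rate}

    return TrainedModel("LR", list(train.feature_names), config.threshold, scorer, detail)


# ---------------------------------------------------------------------------
# Naive Bayes (weighted maximum likelihood with Laplace smoothing)
# ---------------------------------------------------------------------------

def train_naive_bayes(
    train: CohortTable, config: LearnerConfig | None = None, weights: np.ndarray | None = None
) -> TrainedModel:
    """Class-conditional categorical naive Bayes on discrete features.

    Parameters are weighted maximum-likelihood estimates with Laplace
    smoothing (default 1); unseen levels at prediction time receive the
    smoothing mass.
    """
    config = config or LearnerConfig(kind="NB")
    X = _matrix(train)
    w = _weights(train, weights)
    y = train.labels
    laplace = config.setting("laplace")

    classes = np.array([-1, 1])
    class_w = np.array([w[y == c].sum() for c in classes])
    if np.any(class_w == 0):
        raise ValueError("training data must contain both classes")
    log_prior = np.log(class_w / class_w.sum())

    # per feature: levels array and (2, n_levels) log conditional table
    tables: list[tuple[np.ndarray, np.ndarray]] = []
    for j in range(X.shape[1]):
        levels = np.unique(X[:, j])
        cond = np.empty((2, levels.size))
        for ci, c in enumerate(classes):
            rows = y == c
            counts = np.array([w[rows & (X[:, j] == lv)].sum() for lv in levels])
            cond[ci] = (counts + laplace) / (class_w[ci] + laplace * levels.size)
        tables.append((levels, np.log(cond)))

    scorer = _NaiveBayesScorer(log_prior, tables, class_w, laplace)
    return TrainedModel("NB", list(train.feature_names), config.threshold, scorer)


# ---------------------------------------------------------------------------
# Boosted multilayer perceptron
# ---------------------------------------------------------------------------

def train_mlp_boosted(
    train: CohortTable, config: LearnerConfig | None = None, weights: np.ndarray | None = None
) -> TrainedModel:
    """Boosted one-hidden-layer perceptrons (default 10 components).

    Each component is trained for at most 250 cycles with early stopping on
    an internal 30% holdout; instance weights (boosting weights times the
    user-supplied weights) enter through weighted resampling, since the
    perceptron optimiser has no native weight support.  Components are
    combined by standard discrete-boosting weights applied to component
    probabilities.  Hidden width follows the auto rule
    round((n_inputs + 2) / 2).
    """
    from sklearn.neural_network import MLPClassifier

    config = config or LearnerConfig(kind="NN")
    X = _matrix(train)
    w = _weights(train, weights)
    y = train.labels
    n, p = X.shape
    rng = np.random.default_rng(config.seed)

    if np.unique(y).size < 2:
        scorer = _ConstantScorer(float(y[0] == 1))
        return TrainedModel("NN", list(train.feature_names), config.threshold, scorer)

    hidden = max(2, round((p + 2) / 2))
    n_comp = config.setting("n_components")
    max_cycles = config.setting("max_cycles")
    holdout = config.setting("holdout_fraction")
    lr_init = config.setting("learning_rate_init")

    boost_w = w / w.sum()
    components: list[tuple[float, MLPClassifier]] = []
    for t in range(n_comp):
        idx = rng.choice(n, size=n, replace=True, p=boost_w)
        if np.unique(y[idx]).size < 2:  # degenerate resample; redraw once
            idx = rng.choice(n, size=n, replace=True, p=boost_w)
            if np.unique(y[idx]).size < 2:
                break
        mlp = MLPClassifier(
            hidden_layer_sizes=(hidden,),
            max_iter=max_cycles,
            early_stopping=True,
            validation_fraction=holdout,
            n_iter_no_change=10,
            learning_rate_init=lr_init,
            batch_size=min(64, n),
            random_state=int(rng.integers(2**31)),
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                mlp.fit(X[idx], y[idx])
            except ValueError:  # holdout infeasible on tiny resamples
                mlp.set_params(early_stopping=False)
                mlp.fit(X[idx], y[idx])
        wrong = mlp.predict(X) != y
        err = float(np.sum(boost_w * wrong))
        if err >= 0.5:  # no better than chance under current weights: reset
            boost_w = w / w.sum()
            continue
        alpha = np.log((1.0 - err) / max(err, 1e-10))
        components.append((alpha, mlp))
        if err < 1e-10:
            break
        boost_w = boost_w * np.exp(alpha * wrong)
        boost_w /= boost_w.sum()

    if not components:  # fall back to a single unboosted component
        mlp = MLPClassifier(
            hidden_layer_sizes=(hidden,),
            max_iter=max_cycles,
            learning_rate_init=lr_init,
            batch_size=min(64, n),
            random_state=config.seed,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            mlp.fit(X, y)
        components = [(1.0, mlp)]

    alphas = np.array([a for a, _ in components])
    alphas = alphas / alphas.sum()
    scorer = _BoostedScorer(alphas, [mlp for _, mlp in components])
    return TrainedModel(
        "NN", list(train.feature_names), config.threshold, scorer,
        {"n_components": len(components)},
    )


# ---------------------------------------------------------------------------
# RBF-kernel SVM with Platt-calibrated scores
# ---------------------------------------------------------------------------

def train_svm_rbf(
    train: CohortTable, config: LearnerConfig | None = None, weights: np.ndarray | None = None
) -> TrainedModel:
    """Soft-margin RBF SVM honouring instance weights.

    Decision values are mapped to [0, 1] by a Platt-style one-dimensional
    logistic calibration fitted on out-of-fold decision values (3 stratified
    folds) when the data allow, otherwise on in-sample decision values.
    """
    from sklearn.linear_model import LogisticRegression
    from sklearn.model_selection import StratifiedKFold
    from sklearn.svm import SVC

    config = config or LearnerConfig(kind="SVM")
    if "epsilon" in config.settings:
        log.info("SVM epsilon setting recorded but unused for classification")
    X = _matrix(train)
    w = _weights(train, weights)
    y = train.labels
    if np.unique(y).size < 2:
        raise ValueError("SVM training needs both classes")

    svc = SVC(kernel="rbf", C=config.setting("C"), tol=config.setting("tol"), gamma="scale")
    svc.fit(X, y, sample_weight=w)

    pos_count = int((y == 1).sum())
    neg_count = int((y == -1).sum())
    dec_cal, y_cal, w_cal = None, None, None
    if min(pos_count, neg_count) >= 3 and len(y) >= 30:
        dec = np.empty(len(y))
        skf = StratifiedKFold(n_splits=3, shuffle=True, random_state=config.seed)
        try:
            for tr, va in skf.split(X, y):
                fold = SVC(
                    kernel="rbf", C=config.setting("C"), tol=config.setting("tol"), gamma="scale"
                )
                fold.fit(X[tr], y[tr], sample_weight=w[tr])
                dec[va] = fold.decision_function(X[va])
            dec_cal, y_cal, w_cal = dec, y, w
        except ValueError:
            dec_cal = None
    if dec_cal is None:
        dec_cal, y_cal, w_cal = svc.decision_function(X), y, w

    if np.ptp(dec_cal) < 1e-12:  # constant margin: score = weighted base rate
        scorer = _ConstantScorer(float(np.average((y == 1), weights=w)))
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            platt = LogisticRegression(C=np.inf, solver="lbfgs", max_iter=2000)
            platt.fit(dec_cal.reshape(-1, 1), (y_cal == 1).astype(int), sample_weight=w_cal)
        scorer = _PlattSvmScorer(svc, platt)
    return TrainedModel("SVM", list(train.feature_names), config.threshold, scorer)


# ---------------------------------------------------------------------------
# CHAID decision tree
# ---------------------------------------------------------------------------

def _pearson_chi2(counts: np.ndarray) -> tuple[float, float, int]:
    """Pearson chi-square on an R x 2 (possibly weighted) count table."""
    counts = np.asarray(counts, dtype=float)
    rows = counts.sum(axis=1)
    cols = counts.sum(axis=0)
    total = counts.sum()
    keep = rows > 0
    counts, rows = counts[keep], rows[keep]
    if counts.shape[0] < 2 or np.any(cols == 0) or total <= 0:
        return 0.0, 1.0, 0
    expected = np.outer(rows, cols) / total
    stat = float(((counts - expected) ** 2 / expected).sum())
    df = counts.shape[0] - 1
    return stat, float(stats.chi2.sf(stat, df)), df


def _bonferroni_multiplier(k: int, c: int) -> float:
    """Number of ways to merge k nominal categories into c groups."""
    if c <= 1 or c >= k:
        return 1.0
    total = 0.0
    for i in range(c):
        total += (-1) ** i * (c - i) ** k / (factorial(i) * factorial(c - i))
    return max(1.0, total)


class _ChaidNode:
    __slots__ = ("score", "weight", "feature_idx", "group_of", "children", "heaviest")

    def __init__(self, score: float, weight: float):
        self.score = score
        self.weight = weight
        self.feature_idx: int | None = None
        self.group_of: dict[float, int] = {}
        self.children: list["_ChaidNode"] = []
        self.heaviest: int | None = None


def _merge_categories(
    x: np.ndarray, y01: np.ndarray, w: np.ndarray, merge_alpha: float, max_iter: int
) -> list[list[float]]:
    """CHAID category merging: repeatedly merge the pair of groups whose
    2 x 2 chi-square with the label has the largest p-value above the merge
    significance, down to a minimum of two groups."""
    groups = [[v] for v in np.unique(x)]
    for _ in range(max_iter):
        if len(groups) <= 2:
            break
        best_pair, best_p = None, -1.0
        for a in range(len(groups)):
            in_a = np.isin(x, groups[a])
            ca = [w[in_a & (y01 == 0)].sum(), w[in_a & (y01 == 1)].sum()]
            for b in range(a + 1, len(groups)):
                in_b = np.isin(x, groups[b])
                cb = [w[in_b & (y01 == 0)].sum(), w[in_b & (y01 == 1)].sum()]
                _, p, _ = _pearson_chi2(np.array([ca, cb]))
                if p > best_p:
                    best_pair, best_p = (a, b), p
        if best_p <= merge_alpha:
            break
        a, b = best_pair
        groups[a] = groups[a] + groups[b]
        del groups[b]
    return groups


def train_chaid(
    train: CohortTable, config: LearnerConfig | None = None, weights: np.ndarray | None = None
) -> TrainedModel:
    """CHAID tree on discrete features.

    At each node and feature, categories are merged pairwise while the
    least-significant pair's chi-square p-value exceeds the merge
    significance (default 0.05, at most 200 iterations); the merged table's
    p-value is Bonferroni-adjusted for the number of possible merges, and
    the node splits on the feature with the smallest adjusted p-value below
    0.05.  Growth stops at depth 16, parents below 2% of n, or children
    below 1% of n.  Leaf score = weighted positive fraction.
    """
    config = config or LearnerConfig(kind="CHAID")
    X = _matrix(train)
    w = _weights(train, weights)
    y01 = (train.labels == 1).astype(int)
    n = X.shape[0]
    for j in range(X.shape[1]):
        if np.unique(X[:, j]).size > 12:
            raise ValueError(
                f"feature {train.feature_names[j]!r} has too many levels for CHAID; discretise first"
            )

    max_depth = config.setting("max_depth")
    min_parent = config.setting("min_parent_fraction") * n
    min_child = config.setting("min_child_fraction") * n
    merge_alpha = config.setting("merge_alpha")
    split_alpha = config.setting("split_alpha")
    max_merge = config.setting("max_merge_iterations")

    def build(idx: np.ndarray, depth: int) -> _ChaidNode:
        wi, yi = w[idx], y01[idx]
        node = _ChaidNode(score=float(np.average(yi, weights=wi)), weight=float(wi.sum()))
        if depth >= max_depth or idx.size < min_parent or np.unique(yi).size < 2:
            return node
        candidates: list[tuple[float, int, list[list[float]]]] = []
        for j in range(X.shape[1]):
            xj = X[idx, j]
            k = np.unique(xj).size
            if k < 2:
                continue
            groups = _merge_categories(xj, yi, wi, merge_alpha, max_merge)
            counts = np.array(
                [
                    [wi[np.isin(xj, g) & (yi == 0)].sum(), wi[np.isin(xj, g) & (yi == 1)].sum()]
                    for g in groups
                ]
            )
            _, p, df = _pearson_chi2(counts)
            if df == 0:
                continue
            p_adj = min(1.0, p * _bonferroni_multiplier(k, len(groups)))
            candidates.append((p_adj, j, groups))
        for p_adj, j, groups in sorted(candidates, key=lambda c: c[0]):
            if p_adj >= split_alpha:
                break
            xj = X[idx, j]
            child_sizes = [int(np.isin(xj, g).sum()) for g in groups]
            if min(child_sizes) < min_child:
                continue  # split rejected by the minimum-child rule; try next
            node.feature_idx = j
            for gi, g in enumerate(groups):
                for v in g:
                    node.group_of[float(v)] = gi
                node.children.append(build(idx[np.isin(xj, g)], depth + 1))
            node.heaviest = int(np.argmax([c.weight for c in node.children]))
            break
        return node

    root = build(np.arange(n), 0)

    return TrainedModel("CHAID", list(train.feature_names), config.threshold, _ChaidScorer(root))


_TRAINERS = {
    "LR": train_logistic_forward,
    "NB": train_naive_bayes,
    "NN": train_mlp_boosted,
    "SVM": train_svm_rbf,
    "CHAID": train_chaid,
}


def train_learner(
    train: CohortTable, config: LearnerConfig, weights: np.ndarray | None = None
) -> TrainedModel:
    """Dispatch to the trainer named by ``config.kind``."""
    return _TRAINERS[config.kind](train, config, weights)
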