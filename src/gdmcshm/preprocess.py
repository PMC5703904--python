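"""EHR-style preprocessing: missingness filters, discretisation, max-min
normalisation, predictive-mean-matching imputation, and partitioning.

The intended order, mirroring how sparse first-trimester extracts are made
fit for classification, is::

    filter_by_missingness -> discretize_continuous -> min_max_normalize
        -> impute_pmm -> pool_imputations -> split_train_test / make_cv_folds

Each parameterised step returns its fitted parameters so they can be
re-applied to held-out data without refitting.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .synthetic_cohort import CohortTable, FeatureSpec

__all__ = [
    "FilterReport",
    "SplitSpec",
    "filter_by_missingness",
    "min_max_normalize",
    "apply_min_max",
    "discretize_continuous",
    "apply_discretization",
    "impute_pmm",
    "pool_imputations",
    "split_train_test",
    "make_cv_folds",
    "undersample_majority",
]

log = logging.getLogger(__name__)


@dataclass
class FilterReport:
    """What a missingness filter removed and why."""

    dropped_features: list[tuple[str, float]] = field(default_factory=list)
    dropped_subjects: list[tuple[int, float]] = field(default_factory=list)
    feature_threshold: float = 0.5
    subject_threshold: float = 0.5


@dataclass(frozen=True)
class SplitSpec:
    train_fraction: float = 0.9
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must lie strictly in (0, 1)")


def filter_by_missingness(
    table: CohortTable,
    feature_threshold: float = 0.5,
    subject_threshold: float = 0.5,
) -> tuple[CohortTable, FilterReport]:
    """Drop features, then subjects, whose missing fraction exceeds the
    threshold (strictly greater).  Idempotent.
    """
    if not (0 <= feature_threshold <= 1 and 0 <= subject_threshold <= 1):
        raise ValueError("thresholds must be in [0, 1]")
    report = FilterReport(feature_threshold=feature_threshold, subject_threshold=subject_threshold)

    miss_by_feature = np.isnan(table.values).mean(axis=0)
    keep_f = miss_by_feature <= feature_threshold
    for j in np.flatnonzero(~keep_f):
        report.dropped_features.append((table.feature_meta[j].name, float(miss_by_feature[j])))

    values = table.values[:, keep_f]
    meta = [s for s, k in zip(table.feature_meta, keep_f) if k]
    if values.shape[1] == 0:
        raise ValueError("missingness filter removed every feature")

    miss_by_subject = np.isnan(values).mean(axis=1)
    keep_s = miss_by_subject <= subject_threshold
    for i in np.flatnonzero(~keep_s):
        report.dropped_subjects.append((int(table.ids[i]), float(miss_by_subject[i])))
    if not keep_s.any():
        raise ValueError("missingness filter removed every subject")

    out = CohortTable(
        values=values[keep_s],
        feature_meta=meta,
        labels=table.labels[keep_s],
        ids=table.ids[keep_s],
    )
    return out, report


def min_max_normalize(table: CohortTable) -> tuple[CohortTable, dict[str, tuple[float, float]]]:
    """Map each continuous feature to (x - min)/(max - min) over its observed
    values; ordinal and binary features are untouched.

    Returns the per-feature (min, max) record so the same affine map can be
    re-applied to held-out data (where values may fall outside [0, 1]).  A
    constant observed column maps to 0 with a logged warning.
    """
    out = table.copy()
    record: dict[str, tuple[float, float]] = {}
    for j, spec in enumerate(out.feature_meta):
        if spec.kind != "continuous":
            continue
        col = out.values[:, j]
        obs = col[~np.isnan(col)]
        if obs.size == 0:
            continue
        lo, hi = float(obs.min()), float(obs.max())
        record[spec.name] = (lo, hi)
        if hi == lo:
            log.warning("feature %s is constant on observed values; normalised to 0", spec.name)
            out.values[:, j] = np.where(np.isnan(col), np.nan, 0.0)
        else:
            out.values[:, j] = (col - lo) / (hi - lo)
    return out, record


def apply_min_max(table: CohortTable, record: dict[str, tuple[float, float]]) -> CohortTable:
    """Re-apply a fitted max-min map to another table (e.g. the test split)."""
    out = table.copy()
    for j, spec in enumerate(out.feature_meta):
        if spec.name not in record:
            continue
        lo, hi = record[spec.name]
        col = out.values[:, j]
        out.values[:, j] = np.where(np.isnan(col), np.nan, 0.0) if hi == lo else (col - lo) / (hi - lo)
    return out


def discretize_continuous(
    table: CohortTable, n_bins: int = 3
) -> tuple[CohortTable, dict[str, np.ndarray]]:
    """Cut each continuous feature into ``n_bins`` equal-frequency intervals
    (codes 1..n_bins) using its observed values; ordinal/binary untouched.

    Returns the per-feature interior cut points for reuse on held-out data.
    Features with fewer distinct observed values than bins fall back to
    distinct-value codes.  Discretised features are re-tagged as ordinal so
    later continuous-only steps skip them.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be at least 2")
    out = table.copy()
    cuts: dict[str, np.ndarray] = {}
    for j, spec in enumerate(out.feature_meta):
        if spec.kind != "continuous":
            continue
        col = out.values[:, j]
        obs = col[~np.isnan(col)]
        distinct = np.unique(obs)
        if distinct.size < n_bins:
            edges = (distinct[:-1] + distinct[1:]) / 2.0 if distinct.size > 1 else np.array([])
        else:
            qs = np.linspace(0, 1, n_bins + 1)[1:-1]
            edges = np.unique(np.quantile(obs, qs))
        cuts[spec.name] = edges
        out.values[:, j] = _code_with_edges(col, edges)
        out.feature_meta[j] = _as_discretized(spec, edges)
    return out, cuts


def apply_discretization(table: CohortTable, cuts: dict[str, np.ndarray]) -> CohortTable:
    out = table.copy()
    for j, spec in enumerate(out.feature_meta):
        if spec.name not in cuts:
            continue
        edges = cuts[spec.name]
        out.values[:, j] = _code_with_edges(out.values[:, j], edges)
        out.feature_meta[j] = _as_discretized(spec, edges)
    return out


def _code_with_edges(col: np.ndarray, edges: np.ndarray) -> np.ndarray:
    codes = np.searchsorted(edges, col, side="left") + 1.0
    return np.where(np.isnan(col), np.nan, codes)


def _as_discretized(spec: FeatureSpec, edges: np.ndarray) -> FeatureSpec:
    k = len(edges) + 1
    probs = tuple(np.full(3, 1 / 3)) if k == 3 else None
    if probs is not None:
        return replace(spec, kind="ordinal3", params={"probs": probs})
    # not representable as ordinal3; keep kind but note the coding
    return replace(spec, params={**spec.params, "discretized_levels": k})


def impute_pmm(
    table: CohortTable, k_donors: int = 5, m: int = 5, seed: int = 0
) -> list[CohortTable]:
    """Predictive-mean-matching multiple imputation.

    For each incomplete feature: regress it on the complete features over
    observed rows (ordinary least squares), draw perturbed coefficients per
    imputation from the asymptotic normal of the fit, predict the missing
    rows, and copy the observed value of one of the ``k_donors`` rows whose
    (unperturbed) predicted mean is closest.  Every imputed value therefore
    equals some observed value of its feature.  Returns ``m`` completed
    tables.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    n = table.n_subjects
    missing = np.isnan(table.values)
    n_obs = (~missing).sum(axis=0)
    for j, spec in enumerate(table.feature_meta):
        if n_obs[j] < k_donors:
            raise ValueError(
                f"feature {spec.name!r} has only {n_obs[j]} observed values; "
                f"need at least k_donors={k_donors}"
            )
    outs = [table.copy() for _ in range(m)]
    if not missing.any():
        return outs

    complete_cols = np.flatnonzero(~missing.any(axis=0))
    rng = np.random.default_rng(seed)

    for j in np.flatnonzero(missing.any(axis=0)):
        obs_rows = ~missing[:, j]
        mis_rows = missing[:, j]
        y = table.values[obs_rows, j]
        if complete_cols.size:
            X = table.values[:, complete_cols]
        else:
            # no fully observed predictors: fall back to column-mean-filled
            X = np.where(missing, np.nanmean(table.values, axis=0)[None, :], table.values)
            X = np.delete(X, j, axis=1)
        X = np.column_stack([np.ones(n), X])
        Xo, Xm = X[obs_rows], X[mis_rows]

        beta, *_ = np.linalg.lstsq(Xo, y, rcond=None)
        resid = y - Xo @ beta
        dof = max(1, Xo.shape[0] - Xo.shape[1])
        sigma2 = float(resid @ resid) / dof
        XtX = Xo.T @ Xo
        cov = sigma2 * np.linalg.pinv(XtX)
        # symmetrise against round-off before the Cholesky-based draw
        cov = (cov + cov.T) / 2.0

        yhat_obs = Xo @ beta
        for t in range(m):
            beta_star = rng.multivariate_normal(beta, cov, method="svd")
            yhat_mis = Xm @ beta_star
            # k nearest donors by predicted mean, one copied at random
            order = np.argsort(np.abs(yhat_obs[None, :] - yhat_mis[:, None]), axis=1, kind="stable")
            donor_pool = order[:, :k_donors]
            pick = rng.integers(0, donor_pool.shape[1], size=donor_pool.shape[0])
            donors = donor_pool[np.arange(donor_pool.shape[0]), pick]
            outs[t].values[mis_rows, j] = y[donors]
    return outs


def pool_imputations(tables: list[CohortTable], mode: str = "median_mode") -> CohortTable:
    """Combine ``m`` completed tables into one.

    Default: cell-wise median for continuous features and mode (ties broken
    toward the lower code) for ordinal/binary ones.  ``mode='first'``
    returns the first imputation unchanged.
    """
    if not tables:
        raise ValueError("pool_imputations needs at least one table")
    if mode == "first":
        return tables[0].copy()
    if mode != "median_mode":
        raise ValueError(f"unknown pooling mode {mode!r}")
    out = tables[0].copy()
    stack = np.stack([t.values for t in tables])  # (m, n, p)
    for j, spec in enumerate(out.feature_meta):
        cells = stack[:, :, j]
        if spec.kind == "continuous":
            out.values[:, j] = np.median(cells, axis=0)
        else:
            out.values[:, j] = _columnwise_mode(cells)
    return out


def _columnwise_mode(cells: np.ndarray) -> np.ndarray:
    """Mode over axis 0; ties resolved toward the smallest value."""
    n = cells.shape[1]
    result = np.empty(n)
    for i in range(n):
        vals, counts = np.unique(cells[:, i], return_counts=True)
        result[i] = vals[np.argmax(counts)]  # np.unique sorts, argmax takes first max
    return result


def split_train_test(table: CohortTable, spec: SplitSpec) -> tuple[CohortTable, CohortTable]:
    """Disjoint, exhaustive train/test split; train size = floor(fraction*n).

    Stratified splits use proportional allocation with largest-remainder
    rounding so class counts match the overall fraction as closely as
    integer arithmetic allows.
    """
    n = table.n_subjects
    n_train = int(np.floor(spec.train_fraction * n))
    if n_train == 0 or n_train == n:
        raise ValueError("split leaves an empty train or test set")
    rng = np.random.default_rng(spec.seed)

    if spec.stratified:
        train_idx = []
        classes = np.unique(table.labels)
        quotas = {}
        for c in classes:
            idx = np.flatnonzero(table.labels == c)
            quotas[c] = spec.train_fraction * idx.size
        base = {c: int(np.floor(q)) for c, q in quotas.items()}
        shortfall = n_train - sum(base.values())
        remainders = sorted(classes, key=lambda c: quotas[c] - base[c], reverse=True)
        for c in remainders[:shortfall]:
            base[c] += 1
        for c in classes:
            idx = rng.permutation(np.flatnonzero(table.labels == c))
            train_idx.extend(idx[: base[c]])
        train_idx = np.sort(np.asarray(train_idx))
    else:
        perm = rng.permutation(n)
        train_idx = np.sort(perm[:n_train])
    mask = np.zeros(n, dtype=bool)
    mask[train_idx] = True
    return table.take_rows(np.flatnonzero(mask)), table.take_rows(np.flatnonzero(~mask))


def make_cv_folds(
    table: CohortTable, k: int = 10, seed: int = 0, stratified: bool = True
) -> list[tuple[np.ndarray, np.ndarray]]:
    """k disjoint, exhaustive (train, validation) index pairs; fold sizes
    differ by at most one; stratified by label by default.
    """
    from sklearn.model_selection import KFold, StratifiedKFold

    n = table.n_subjects
    if not 2 <= k <= n:
        raise ValueError("k must satisfy 2 <= k <= n")
    if stratified:
        pos = int((table.labels == 1).sum())
        neg = n - pos
        if 0 < min(pos, neg) < k:
            warnings.warn("fewer minority-class rows than folds; some folds lack positives")
            splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
            return list(splitter.split(np.zeros(n)))
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        return list(splitter.split(np.zeros(n), table.labels))
    splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
    return list(splitter.split(np.zeros(n)))


def undersample_majority(table: CohortTable, ratio: float = 1.0, seed: int = 0) -> CohortTable:
    """Keep every minority row and a without-replacement sample of majority
    rows so that majority/minority = ``ratio``.
    """
    if ratio <= 0:
        raise ValueError("ratio must be positive")
    pos = np.flatnonzero(table.labels == 1)
    neg = np.flatnonzero(table.labels == -1)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes must be present")
    minority, majority = (pos, neg) if pos.size <= neg.size else (neg, pos)
    n_major = int(round(ratio * minority.size))
    if n_major > majority.size:
        raise ValueError(
            f"ratio {ratio} requires {n_major} majority rows but only {majority.size} exist"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(majority, size=n_major, replace=False)
    keep = np.sort(np.concatenate([minority, chosen]))
    return table.take_rows(keep)
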