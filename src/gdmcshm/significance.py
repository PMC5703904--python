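"""Significance machinery for comparing classifiers.

Three ingredients:

* **DTPR** — the difference in true positive rates of two classifiers read
  off their ROC curves at a shared grid of false-positive-rate thresholds.
* **One-sample t-tests** — applied to a DTPR sequence against 0, reported
  with the 95% confidence interval; also recomputable from published
  summary statistics (n, mean, s.d.) alone.
* **DeLong's test** — the two-sided test for the difference of two
  correlated AUCs computed from the same subjects, via the fast
  placement-value construction.

Note that a location test across DTPR thresholds treats the per-threshold
differences as independent draws, which they are not; the procedure is kept
as-is because it is the conventional reporting device, with DeLong's test
as the statistically grounded companion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .evaluation import ROCCurve

__all__ = [
    "DTPRSeries",
    "TTestResult",
    "DelongResult",
    "tpr_at_fpr",
    "dtpr",
    "one_sample_t",
    "t_from_summary",
    "delong_test",
]


@dataclass(frozen=True)
class DTPRSeries:
    fpr_grid: np.ndarray
    differences: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.diff(self.fpr_grid) <= 0):
            raise ValueError("fpr_grid must be strictly ascending")


@dataclass(frozen=True)
class TTestResult:
    n: int
    mean: float
    sd: float
    se: float
    t: float
    df: int
    p_two_sided: float
    ci_low: float
    ci_high: float


@dataclass(frozen=True)
class DelongResult:
    auc1: float
    auc2: float
    statistic: float
    p_two_sided: float


def tpr_at_fpr(roc: ROCCurve, fpr_value: float) -> float:
    """Step interpolation: the largest TPR achieved at FPR <= ``fpr_value``."""
    if not 0.0 <= fpr_value <= 1.0:
        raise ValueError("fpr_value must be in [0, 1]")
    eligible = roc.fpr <= fpr_value + 1e-12
    return float(roc.tpr[eligible].max()) if eligible.any() else 0.0


def dtpr(roc1: ROCCurve, roc2: ROCCurve, fpr_grid: np.ndarray | None = None) -> DTPRSeries:
    """TPR(model 1) - TPR(model 2) at each grid threshold.

    Default grid: the sorted union of both curves' FPR breakpoints.
    """
    if fpr_grid is None:
        fpr_grid = np.unique(np.concatenate([roc1.fpr, roc2.fpr]))
    fpr_grid = np.asarray(fpr_grid, dtype=float)
    diffs = np.array([tpr_at_fpr(roc1, f) - tpr_at_fpr(roc2, f) for f in fpr_grid])
    return DTPRSeries(fpr_grid=fpr_grid, differences=diffs)


def one_sample_t(values: np.ndarray, mu0: float = 0.0) -> TTestResult:
    """One-sample t-test of mean(values) against ``mu0`` with 95% CI."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least two values")
    sd = float(v.std(ddof=1))
    if sd == 0:
        raise ValueError("zero variance: t statistic undefined")
    return t_from_summary(v.size, float(v.mean()), sd, mu0)


def t_from_summary(n: int, mean: float, sd: float, mu0: float = 0.0) -> TTestResult:
    """Identical test computed from summary statistics alone:
    t = (mean - mu0) / (sd / sqrt(n)), df = n - 1, two-sided p, 95% CI."""
    if n < 2:
        raise ValueError("need n >= 2")
    if sd <= 0:
        raise ValueError("sd must be positive")
    se = sd / np.sqrt(n)
    t = (mean - mu0) / se
    df = n - 1
    p = 2.0 * stats.t.sf(abs(t), df)
    tcrit = stats.t.ppf(0.975, df)
    return TTestResult(
        n=n, mean=mean, sd=sd, se=float(se), t=float(t), df=df,
        p_two_sided=float(p), ci_low=float(mean - tcrit * se), ci_high=float(mean + tcrit * se),
    )


def _placements(pos_scores: np.ndarray, neg_scores: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Mid-rank placement values and the AUC (ties half-counted)."""
    m, n = pos_scores.size, neg_scores.size
    allv = np.concatenate([pos_scores, neg_scores])
    ranks = stats.rankdata(allv)  # mid-ranks
    rpos, rneg = ranks[:m], ranks[m:]
    auc = (rpos.sum() - m * (m + 1) / 2.0) / (m * n)
    v10 = (rpos - stats.rankdata(pos_scores)) / n          # per-positive placements
    v01 = 1.0 - (rneg - stats.rankdata(neg_scores)) / m    # per-negative placements
    return v10, v01, float(auc)


def delong_test(scores1: np.ndarray, scores2: np.ndarray, truth: np.ndarray) -> DelongResult:
    """Two-sided test for equality of two correlated AUCs (same subjects).

    Uses the placement-value covariance construction; the statistic is
    (AUC1 - AUC2) / sqrt(var) referred to the standard normal.
    """
    s1 = np.asarray(scores1, dtype=float)
    s2 = np.asarray(scores2, dtype=float)
    y = np.asarray(truth)
    if not (s1.shape == s2.shape == y.shape):
        raise ValueError("score vectors and truth must share one length")
    pos, neg = y == 1, y == -1
    if not (pos.any() and neg.any()):
        raise ValueError("both classes must be present")

    v10 = np.empty((2, int(pos.sum())))
    v01 = np.empty((2, int(neg.sum())))
    aucs = np.empty(2)
    for i, s in enumerate((s1, s2)):
        v10[i], v01[i], aucs[i] = _placements(s[pos], s[neg])

    m, n = v10.shape[1], v01.shape[1]
    s10 = np.cov(v10, ddof=1) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(v01, ddof=1) if n > 1 else np.zeros((2, 2))
    cov = s10 / m + s01 / n
    var = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
    delta = aucs[0] - aucs[1]
    if var <= 0:
        if abs(delta) < 1e-12:
            return DelongResult(aucs[0], aucs[1], 0.0, 1.0)
        raise ValueError("degenerate zero variance with unequal AUCs")
    z = delta / np.sqrt(var)
    p = 2.0 * stats.norm.sf(abs(z))
    return DelongResult(float(aucs[0]), float(aucs[1]), float(z), float(p))
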