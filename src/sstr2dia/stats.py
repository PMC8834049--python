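"""Statistical battery for predictive-biomarker evaluation.

Empirical ROC analysis with the tie-aware Mann–Whitney AUC, Youden-optimal
cutoffs, the DeLong test for comparing correlated AUCs, and thin wrappers
over the standard nonparametric tests (Wilcoxon rank-sum, Kruskal–Wallis,
Spearman, Pearson chi-square) with Bonferroni correction.

Orientation is fixed throughout: a case is predicted positive (responder)
when its score is greater than or equal to the threshold.

The rank tests delegate to :mod:`scipy.stats`; the AUC, ROC sweep, Youden
cutoff and DeLong covariance estimator are implemented here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

__all__ = [
    "ROCResult",
    "PairedAUCTest",
    "auc_mann_whitney",
    "roc_curve",
    "youden_cutoff",
    "delong_test",
    "wilcoxon_rank_sum",
    "kruskal_wallis",
    "spearman",
    "bonferroni",
    "chi2_test",
]


@dataclass
class ROCResult:
    """Empirical ROC: one operating point per distinct score value."""

    thresholds: np.ndarray  # sorted ascending; positive iff score >= threshold
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    youden_cutoff: float = field(default=np.nan)
    sens_at_cutoff: float = field(default=np.nan)
    spec_at_cutoff: float = field(default=np.nan)


@dataclass
class PairedAUCTest:
    """DeLong comparison of two correlated AUCs on the same cases."""

    auc_a: float
    auc_b: float
    z: float
    p: float
    p_adjusted: float


def _validate_binary(scores, labels):
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("scores and labels must be 1-D and of equal length")
    uniq = np.unique(y)
    if not np.all(np.isin(uniq, [0, 1])):
        raise ValueError("labels must be binary 0/1")
    if uniq.size < 2:
        raise ValueError("both classes must be present")
    return s, y.astype(int)


def auc_mann_whitney(scores, labels) -> float:
    """Tie-aware Mann–Whitney AUC.

    AUC = (# positive–negative pairs with s+ > s−, ties counted 1/2) divided
    by the number of pairs. Equals the trapezoidal area under the empirical
    ROC curve for any tie pattern.
    """
    s, y = _validate_binary(scores, labels)
    pos, neg = s[y == 1], s[y == 0]
    wins = (pos[:, None] > neg[None, :]).sum() + 0.5 * (pos[:, None] == neg[None, :]).sum()
    return float(wins / (pos.size * neg.size))


def roc_curve(scores, labels) -> ROCResult:
    """Threshold sweep over the distinct score values.

    At each threshold t: sensitivity = P(score ≥ t | positive) and
    specificity = P(score < t | negative). The Youden-optimal operating
    point is filled in (see :func:`youden_cutoff` for the tie rules).
    """
    s, y = _validate_binary(scores, labels)
    thresholds = np.unique(s)
    pos, neg = s[y == 1], s[y == 0]
    sens = np.array([(pos >= t).mean() for t in thresholds])
    spec = np.array([(neg < t).mean() for t in thresholds])
    roc = ROCResult(
        thresholds=thresholds,
        sensitivity=sens,
        specificity=spec,
        auc=auc_mann_whitney(s, y),
    )
    cut, se, sp = youden_cutoff(roc)
    roc.youden_cutoff, roc.sens_at_cutoff, roc.spec_at_cutoff = cut, se, sp
    return roc


def youden_cutoff(roc: ROCResult) -> tuple[float, float, float]:
    """Cutoff maximizing Youden's J = sensitivity + specificity − 1.

    Ties on J are broken toward higher specificity, then toward the lower
    cutoff value. Returns (cutoff, sensitivity, specificity).
    """
    j = roc.sensitivity + roc.specificity - 1.0
    order = sorted(
        range(len(roc.thresholds)),
        key=lambda i: (-j[i], -roc.specificity[i], roc.thresholds[i]),
    )
    i = order[0]
    return (
        float(roc.thresholds[i]),
        float(roc.sensitivity[i]),
        float(roc.specificity[i]),
    )


def _placements(scores: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """DeLong structural components (placement values) for one marker."""
    pos, neg = scores[y == 1], scores[y == 0]
    cmp_ = (pos[:, None] > neg[None, :]).astype(float)
    cmp_ += 0.5 * (pos[:, None] == neg[None, :])
    v10 = cmp_.mean(axis=1)  # one per positive case
    v01 = cmp_.mean(axis=0)  # one per negative case
    return float(v10.mean()), v10, v01


def delong_test(scores_a, scores_b, labels, k_comparisons: int = 1) -> PairedAUCTest:
    """DeLong test for two correlated AUCs measured on the same cases.

    The variance of AUC_a − AUC_b is estimated from the empirical covariance
    of the per-case placement values; the statistic is referred to a standard
    normal (two-sided). Bonferroni adjustment uses ``k_comparisons``.
    """
    sa, y = _validate_binary(scores_a, labels)
    sb, y2 = _validate_binary(scores_b, labels)
    if not np.array_equal(y, y2):
        raise ValueError("labels must be identical for both markers")
    auc_a, v10_a, v01_a = _placements(sa, y)
    auc_b, v10_b, v01_b = _placements(sb, y)
    m, n = v10_a.size, v01_a.size
    s10 = np.cov(np.vstack([v10_a, v10_b]), ddof=1)
    s01 = np.cov(np.vstack([v01_a, v01_b]), ddof=1)
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m \
        + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    diff = auc_a - auc_b
    if var <= 0 or not np.isfinite(var):
        if abs(diff) < 1e-12:
            z, p = 0.0, 1.0
        else:
            raise ValueError(
                f"degenerate DeLong variance ({var!r}) with nonzero AUC difference {diff!r}"
            )
    else:
        z = diff / np.sqrt(var)
        p = float(2 * sps.norm.sf(abs(z)))
    if k_comparisons < 1:
        raise ValueError("k_comparisons must be >= 1")
    return PairedAUCTest(
        auc_a=auc_a,
        auc_b=auc_b,
        z=float(z),
        p=float(p),
        p_adjusted=min(1.0, k_comparisons * float(p)),
    )


def wilcoxon_rank_sum(x, y, *, continuity: bool = True, method: str = "asymptotic") -> float:
    """Two-sided Wilcoxon rank-sum (Mann–Whitney) p-value.

    Default is the normal approximation with tie correction and continuity
    correction; ``method="exact"`` enumerates the null distribution (scipy,
    valid without ties) for small samples.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least 2 observations")
    res = sps.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=continuity
    )
    return float(res.pvalue)


def kruskal_wallis(*groups) -> float:
    """Tie-corrected Kruskal–Wallis p-value; degenerate all-equal input → 1."""
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2 or any(g.size == 0 for g in gs):
        raise ValueError("need at least 2 non-empty groups")
    pooled = np.concatenate(gs)
    if np.all(pooled == pooled[0]):
        return 1.0
    return float(sps.kruskal(*gs).pvalue)


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation (average ranks for ties) with two-sided
    t-approximation p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need paired samples of length >= 3")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        raise ValueError("rank correlation undefined for a constant sample")
    rho, p = sps.spearmanr(x, y)
    return float(rho), float(p)


def bonferroni(p_values, m: int) -> np.ndarray:
    """Bonferroni adjustment: p_adj = min(1, m·p)."""
    p = np.asarray(p_values, dtype=float)
    if m < max(1, p.size):
        raise ValueError("m must be at least the number of tests")
    return np.minimum(1.0, m * p)


def chi2_test(table) -> float:
    """Pearson chi-square p-value on a two-way count table.

    No continuity correction; degrees of freedom (r−1)(c−1). Rows or columns
    with a zero margin are dropped with a warning.
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2:
        raise ValueError("contingency table must be 2-D")
    row_ok = t.sum(axis=1) > 0
    col_ok = t.sum(axis=0) > 0
    if not row_ok.all() or not col_ok.all():
        warnings.warn("dropping zero-margin rows/columns from contingency table",
                      stacklevel=2)
        t = t[row_ok][:, col_ok]
    if t.shape[0] < 2 or t.shape[1] < 2:
        raise ValueError("table must be at least 2x2 after dropping zero margins")
    return float(sps.chi2_contingency(t, correction=False).pvalue)
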