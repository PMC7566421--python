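"""ROC analysis from first principles.

Implements the empirical AUC (Mann–Whitney form with midrank tie
handling), the Youden-optimal operating point, De Long's
structural-components estimator for the variance of an AUC (giving
normal-approximation confidence intervals and the paired two-sample
test), and stratified percentile-bootstrap intervals for sensitivity and
specificity at the Youden threshold.

Conventions
-----------
* Labels are binary (1 = event/progression); scores are real with higher
  meaning more event-like.
* The classification rule is positive iff score >= threshold.
* Ties in scores are handled with midranks throughout, which makes the
  AUC equal to the mean over positive-negative pairs of
  ``[s_pos > s_neg] + 0.5 [s_pos == s_neg]``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm, rankdata

from .errors import UndefinedMetricError

__all__ = [
    "RocResult",
    "CiResult",
    "auc",
    "roc_points",
    "youden_optimal",
    "delong_ci",
    "delong_test",
    "bootstrap_ci",
    "roc_analysis",
]


@dataclass(frozen=True)
class CiResult:
    estimate: float
    lower: float
    upper: float
    level: float
    method: str

    def __post_init__(self):
        if not (self.lower - 1e-12 <= self.estimate <= self.upper + 1e-12):
            raise ValueError("estimate must lie within [lower, upper]")


@dataclass(frozen=True)
class RocResult:
    """Full ROC curve with its AUC and Youden operating point."""

    thresholds: np.ndarray  # descending, with +/- inf sentinels
    sens: np.ndarray
    spec: np.ndarray
    auc: float
    youden_threshold: float
    youden_sens: float
    youden_spec: float


def _check_labels(labels, scores):
    y = np.asarray(labels)
    s = np.asarray(scores, dtype=float)
    if y.shape != s.shape or y.ndim != 1:
        raise ValueError("labels and scores must be 1-D and the same length")
    if not np.isin(y, (0, 1)).all():
        raise ValueError("labels must be binary 0/1")
    y = y.astype(int)
    if y.sum() == 0 or y.sum() == len(y):
        raise UndefinedMetricError(
            "AUC undefined: labels contain a single class")
    return y, s


def auc(labels, scores) -> float:
    """Empirical AUC via midranks (equals the Mann–Whitney statistic)."""
    y, s = _check_labels(labels, scores)
    m = int(y.sum())        # positives
    n = len(y) - m          # negatives
    ranks = rankdata(s)     # midranks
    return float((ranks[y == 1].sum() - m * (m + 1) / 2.0) / (m * n))


def roc_points(labels, scores):
    """Sensitivity/specificity at every candidate threshold.

    Thresholds are the unique scores in descending order, bracketed by
    +inf (classify nothing positive) and -inf sentinels.
    """
    y, s = _check_labels(labels, scores)
    m = int(y.sum())
    n = len(y) - m
    uniq = np.unique(s)[::-1]
    thr = np.concatenate([[np.inf], uniq, [-np.inf]])
    pos = np.sort(s[y == 1])
    neg = np.sort(s[y == 0])
    # positives iff score >= threshold
    sens = (m - np.searchsorted(pos, thr, side="left")) / m
    spec = np.searchsorted(neg, thr, side="left") / n
    return thr, sens, spec


def youden_optimal(labels, scores) -> tuple[float, float, float]:
    """Threshold maximizing J = sens + spec - 1 (rule: score >= threshold).

    Only observed score values are candidates.  Ties in J are broken in
    favour of higher specificity (screening contexts put a premium on
    specificity), then in favour of the lower threshold.
    """
    y, s = _check_labels(labels, scores)
    m = int(y.sum())
    n = len(y) - m
    cand = np.unique(s)  # ascending
    pos = np.sort(s[y == 1])
    neg = np.sort(s[y == 0])
    sens = (m - np.searchsorted(pos, cand, side="left")) / m
    spec = np.searchsorted(neg, cand, side="left") / n
    j = sens + spec - 1.0
    best_j = j.max()
    tied = np.flatnonzero(j >= best_j - 1e-12)
    best = tied[np.lexsort((cand[tied], -spec[tied]))][0]
    return float(cand[best]), float(sens[best]), float(spec[best])


def roc_analysis(labels, scores) -> RocResult:
    thr, sens, spec = roc_points(labels, scores)
    t, se, sp = youden_optimal(labels, scores)
    return RocResult(thresholds=thr, sens=sens, spec=spec,
                     auc=auc(labels, scores),
                     youden_threshold=t, youden_sens=se, youden_spec=sp)


# -- De Long machinery -------------------------------------------------

def _placements(labels, scores):
    """De Long structural components (placement values) via midranks.

    V10[i] = Pr-hat(score of positive i exceeds a random negative),
    V01[j] = Pr-hat(a random positive exceeds negative j), with ties
    counted half.
    """
    y, s = _check_labels(labels, scores)
    pos = s[y == 1]
    neg = s[y == 0]
    m, n = len(pos), len(neg)
    all_ranks = rankdata(np.concatenate([pos, neg]))
    pos_ranks = rankdata(pos)
    neg_ranks = rankdata(neg)
    v10 = (all_ranks[:m] - pos_ranks) / n
    v01 = 1.0 - (all_ranks[m:] - neg_ranks) / m
    theta = v10.mean()
    return v10, v01, theta


def _delong_variance(v10, v01):
    m, n = len(v10), len(v01)
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return s10 / m + s01 / n


def delong_ci(labels, scores, level: float = 0.95) -> CiResult:
    """Normal-approximation CI for the AUC with De Long's variance.

    Requires at least two cases per class so the variance is estimable.
    The interval is truncated to [0, 1]; with perfectly separated scores
    the variance is zero and the interval collapses to the estimate.
    """
    y = np.asarray(labels).astype(int)
    if (y == 1).sum() < 2 or (y == 0).sum() < 2:
        raise UndefinedMetricError(
            "De Long variance needs >= 2 positives and >= 2 negatives")
    v10, v01, theta = _placements(labels, scores)
    var = _delong_variance(v10, v01)
    z = norm.ppf(0.5 + level / 2.0)
    half = z * np.sqrt(max(var, 0.0))
    return CiResult(estimate=float(theta),
                    lower=float(max(theta - half, 0.0)),
                    upper=float(min(theta + half, 1.0)),
                    level=level, method="delong")


def delong_test(labels, scores_a, scores_b) -> tuple[float, float]:
    """Paired two-sided De Long test for a difference in AUCs.

    Both score vectors must be computed on the same cases (identical
    labels).  Returns ``(z_statistic, p_value)``.  When the variance of
    the difference is zero the statistic is 0 (p = 1) for equal AUCs.
    """
    sa = np.asarray(scores_a, dtype=float)
    sb = np.asarray(scores_b, dtype=float)
    if sa.shape != sb.shape:
        raise ValueError("paired score vectors must have equal length")
    va10, va01, ta = _placements(labels, sa)
    vb10, vb01, tb = _placements(labels, sb)
    m, n = len(va10), len(va01)
    s10 = np.cov(va10, vb10, ddof=1) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(va01, vb01, ddof=1) if n > 1 else np.zeros((2, 2))
    cov = s10 / m + s01 / n
    var_diff = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
    diff = ta - tb
    if var_diff <= 0:
        z = 0.0 if diff == 0 else np.sign(diff) * np.inf
    else:
        z = diff / np.sqrt(var_diff)
    p = 2 * norm.sf(abs(z)) if np.isfinite(z) else 0.0
    return float(z), float(min(max(p, 0.0), 1.0))


def bootstrap_ci(labels, scores, statistic: str, B: int = 2000,
                 level: float = 0.95, seed: int = 0,
                 refit_threshold: bool = True) -> CiResult:
    """Stratified percentile bootstrap for the Youden-point sensitivity
    or specificity.

    ``statistic`` is ``"sens_at_youden"`` or ``"spec_at_youden"``.
    Resampling is within class (so every resample has both classes) and
    the Youden threshold is re-derived inside each resample unless
    ``refit_threshold=False``, in which case the full-sample threshold is
    reused.  Deterministic given ``seed``.
    """
    if statistic not in ("sens_at_youden", "spec_at_youden"):
        raise ValueError(f"unknown statistic {statistic!r}")
    if B < 100:
        raise ValueError("B must be >= 100")
    y, s = _check_labels(labels, scores)
    thr0, sens0, spec0 = youden_optimal(y, s)
    estimate = sens0 if statistic == "sens_at_youden" else spec0
    pos = s[y == 1]
    neg = s[y == 0]
    m, n = len(pos), len(neg)
    rng = np.random.default_rng(seed)
    vals = np.empty(B)
    yb = np.concatenate([np.ones(m, int), np.zeros(n, int)])
    for b in range(B):
        sb = np.concatenate([pos[rng.integers(0, m, m)],
                             neg[rng.integers(0, n, n)]])
        if refit_threshold:
            t, se, sp = youden_optimal(yb, sb)
        else:
            t = thr0
            se = (sb[:m] >= t).sum() / m
            sp = (sb[m:] < t).sum() / n
        vals[b] = se if statistic == "sens_at_youden" else sp
    alpha = 1.0 - level
    lo, hi = np.quantile(vals, [alpha / 2, 1 - alpha / 2])
    return CiResult(estimate=float(estimate),
                    lower=float(min(lo, estimate)),
                    upper=float(max(hi, estimate)),
                    level=level, method="bootstrap")
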