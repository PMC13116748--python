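"""Empirical ROC analysis: curve points, AUC with DeLong inference, Youden cut-off.

The score is oriented so that larger values predict the positive class (pCR),
and a test-positive call at threshold ``t`` means ``score > t`` — consistent
with the "high" risk group being the strictly-above-cutoff group.

Candidate thresholds are the midpoints between consecutive distinct observed
scores plus sentinels below the minimum and above the maximum, so that every
achievable confusion table appears exactly once on the curve.  An
"observed"-value candidate rule is also available for software that places
cut-offs at the data values themselves.

AUC is computed by the Mann-Whitney pair-counting identity (ties count 1/2),
which equals the trapezoidal area under the empirical curve.  The AUC
standard error uses DeLong's placement-value estimator; the confidence
interval is Wald on the AUC scale, clipped to [0, 1], and the p-value is a
two-sided z-test of AUC = 0.5.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, ClassifierMixin

logger = logging.getLogger(__name__)

__all__ = [
    "ROCResult",
    "ConfusionSummary",
    "roc_points",
    "auc_mann_whitney",
    "delong_inference",
    "youden_optimal",
    "confusion_at_cutoff",
    "YoudenCutoffClassifier",
]


@dataclass(frozen=True)
class ROCResult:
    """Empirical ROC curve with AUC inference and the Youden operating point."""

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    auc_se: float
    auc_ci: tuple[float, float]
    auc_p_vs_half: float
    youden_cutoff: float
    youden_j: float
    sens_at_cutoff: float
    spec_at_cutoff: float
    confidence_level: float = 0.95


@dataclass(frozen=True)
class ConfusionSummary:
    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float
    specificity: float
    ppv: float
    npv: float


def _validate_scores_labels(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be 1-D arrays of equal length")
    if labels.all() or not labels.any():
        raise ValueError("both outcome classes must be present")
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    return scores, labels


def candidate_thresholds(scores: np.ndarray, rule: str = "midpoint") -> np.ndarray:
    """Candidate cut-offs: midpoints between distinct sorted scores plus sentinels.

    ``rule="observed"`` uses the distinct observed values themselves (plus a
    below-minimum sentinel), the convention of some ROC software.
    """
    distinct = np.unique(scores)
    lo = distinct[0] - 1.0
    hi = distinct[-1] + 1.0
    if rule == "midpoint":
        mids = (distinct[:-1] + distinct[1:]) / 2.0
        return np.concatenate([[lo], mids, [hi]])
    if rule == "observed":
        return np.concatenate([[lo], distinct])
    raise ValueError(f"unknown candidate rule {rule!r}")


def roc_points(scores, labels, rule: str = "midpoint"):
    """Thresholds with aligned sensitivity/specificity arrays.

    At threshold ``t`` the call is positive iff ``score > t``;
    sensitivity = TP/(TP+FN), specificity = TN/(TN+FP).
    """
    scores, labels = _validate_scores_labels(scores, labels)
    thresholds = candidate_thresholds(scores, rule)
    pos = scores[labels]
    neg = scores[~labels]
    sens = np.array([(pos > t).mean() for t in thresholds])
    spec = np.array([(neg <= t).mean() for t in thresholds])
    return thresholds, sens, spec


def auc_mann_whitney(scores, labels) -> float:
    """AUC = P(score+ > score-) + 0.5 * P(tie), by pair counting.

    Computed in O(n log n) via ranks; identical to the trapezoidal area under
    the empirical ROC curve.
    """
    scores, labels = _validate_scores_labels(scores, labels)
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    ranks = stats.rankdata(scores)  # midranks handle ties
    u = ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def _placement_values(scores: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """DeLong structural components: per-positive and per-negative placements."""
    pos = scores[labels]
    neg = scores[~labels]
    # v10[i] = fraction of negatives below pos[i] (+ half ties); v01 symmetric
    order = np.sort(neg)
    lt = np.searchsorted(order, pos, side="left")
    le = np.searchsorted(order, pos, side="right")
    v10 = (lt + 0.5 * (le - lt)) / len(neg)
    order = np.sort(pos)
    lt = np.searchsorted(order, neg, side="right")
    v01 = (len(pos) - lt + 0.5 * (lt - np.searchsorted(order, neg, side="left"))) / len(pos)
    # v01[j] = fraction of positives above neg[j] (+ half ties)
    return v10, v01


def delong_inference(scores, labels, level: float = 0.95):
    """AUC confidence interval and two-sided p versus 0.5 by DeLong's method.

    Returns ``(auc, se, (lo, hi), p)``.  Perfect separation gives zero
    estimated variance; the interval then collapses to the point estimate
    with a logged warning and the p-value is reported as 0.
    """
    scores, labels = _validate_scores_labels(scores, labels)
    if labels.sum() < 2 or (~labels).sum() < 2:
        raise ValueError("DeLong inference needs at least 2 observations per class")
    v10, v01 = _placement_values(scores, labels)
    auc = float(v10.mean())
    s10 = v10.var(ddof=1)
    s01 = v01.var(ddof=1)
    var = s10 / len(v10) + s01 / len(v01)
    se = float(np.sqrt(var))
    z_crit = stats.norm.ppf(0.5 + level / 2.0)
    if se == 0.0:
        logger.warning("zero DeLong variance (perfect separation); CI collapses to the estimate")
        ci = (auc, auc)
        p = 0.0 if auc != 0.5 else 1.0
    else:
        ci = (max(0.0, auc - z_crit * se), min(1.0, auc + z_crit * se))
        z = (auc - 0.5) / se
        p = float(2.0 * stats.norm.sf(abs(z)))
    return auc, se, ci, p


def youden_optimal(thresholds, sensitivity, specificity):
    """Cut-off maximizing Youden's J = sensitivity + specificity - 1.

    Ties on J are broken by higher sensitivity, then by lower cut-off.
    Returns ``(cutoff, j, sens, spec)``.
    """
    thresholds = np.asarray(thresholds, dtype=float)
    sens = np.asarray(sensitivity, dtype=float)
    spec = np.asarray(specificity, dtype=float)
    j = sens + spec - 1.0
    best = 0
    for i in range(1, len(thresholds)):
        if (j[i], sens[i], -thresholds[i]) > (j[best], sens[best], -thresholds[best]):
            best = i
    return float(thresholds[best]), float(j[best]), float(sens[best]), float(spec[best])


def confusion_at_cutoff(scores, labels, cutoff: float) -> ConfusionSummary:
    """Confusion counts and rates at a cut-off (positive call iff score > cutoff)."""
    scores, labels = _validate_scores_labels(scores, labels)
    call = scores > cutoff
    tp = int((call & labels).sum())
    fp = int((call & ~labels).sum())
    fn = int((~call & labels).sum())
    tn = int((~call & ~labels).sum())
    return ConfusionSummary(
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
        sensitivity=tp / (tp + fn),
        specificity=tn / (tn + fp),
        ppv=tp / (tp + fp) if tp + fp else float("nan"),
        npv=tn / (tn + fn) if tn + fn else float("nan"),
    )


def analyze_roc(scores, labels, level: float = 0.95, rule: str = "midpoint") -> ROCResult:
    """Full ROC analysis: curve, AUC with DeLong inference, Youden operating point."""
    thresholds, sens, spec = roc_points(scores, labels, rule=rule)
    auc, se, ci, p = delong_inference(scores, labels, level=level)
    cutoff, j, sens_c, spec_c = youden_optimal(thresholds, sens, spec)
    return ROCResult(
        thresholds=thresholds,
        sensitivity=sens,
        specificity=spec,
        auc=auc,
        auc_se=se,
        auc_ci=ci,
        auc_p_vs_half=p,
        youden_cutoff=cutoff,
        youden_j=j,
        sens_at_cutoff=sens_c,
        spec_at_cutoff=spec_c,
        confidence_level=level,
    )


class YoudenCutoffClassifier(BaseEstimator, ClassifierMixin):
    """Dichotomise a continuous score at the Youden-optimal cut-off.

    ``fit(X, y)`` takes the score (a single column or 1-D array) and the
    binary outcome, runs the full ROC analysis, and stores the Youden-optimal
    cut-off; ``predict`` then assigns the high (True) group to scores
    strictly above the cut-off.  A fixed cut-off (e.g. one published for
    another cohort) can be supplied instead, bypassing derivation.

    Attributes
    ----------
    cutoff_ : float
        The operating cut-off (derived or fixed).
    roc_ : ROCResult
        Full ROC analysis of the training data.
    auc_, auc_ci_, auc_p_vs_half_ : floats
        AUC with its Wald/DeLong confidence interval and test versus 0.5.
    """

    def __init__(self, fixed_cutoff: float | None = None, level: float = 0.95, rule: str = "midpoint"):
        self.fixed_cutoff = fixed_cutoff
        self.level = level
        self.rule = rule

    def fit(self, X, y) -> "YoudenCutoffClassifier":
        scores = np.asarray(X, dtype=float)
        if scores.ndim == 2:
            if scores.shape[1] != 1:
                raise ValueError("expected a single score column")
            scores = scores[:, 0]
        self.roc_ = analyze_roc(scores, y, level=self.level, rule=self.rule)
        self.auc_ = self.roc_.auc
        self.auc_ci_ = self.roc_.auc_ci
        self.auc_p_vs_half_ = self.roc_.auc_p_vs_half
        self.cutoff_ = float(self.fixed_cutoff) if self.fixed_cutoff is not None else self.roc_.youden_cutoff
        self.classes_ = np.array([False, True])
        return self

    def predict(self, X) -> np.ndarray:
        scores = np.asarray(X, dtype=float)
        if scores.ndim == 2:
            scores = scores[:, 0]
        return scores > self.cutoff_
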