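"""ROC curve, Mann-Whitney AUC, DeLong inference and Youden cut-off selection.

AUC is checked against a brute-force pair-counting oracle and sklearn's
independent implementation; the DeLong standard error against a bootstrap;
large-sample binormal AUC against the closed form Phi(delta/sqrt(2)).
"""

import numpy as np
import pytest
from scipy import stats
from sklearn.metrics import roc_auc_score

from tipiscore import (
    TIPIScorer,
    YoudenCutoffClassifier,
    analyze_roc,
    auc_mann_whitney,
    confusion_at_cutoff,
    delong_inference,
    roc_points,
    youden_optimal,
)


def pair_counting_auc(scores, labels):
    pos = scores[labels]
    neg = scores[~labels]
    wins = ties = 0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1
            elif p == q:
                ties += 1
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


def test_roc_points_perfect_separation():
    scores = np.array([1.0, 2.0, 3.0, 10.0, 11.0, 12.0])
    labels = np.array([0, 0, 0, 1, 1, 1], dtype=bool)
    _, sens, spec = roc_points(scores, labels)
    assert np.any((sens == 1.0) & (spec == 1.0))


def test_roc_points_all_identical_scores():
    thresholds, sens, spec = roc_points(np.full(6, 2.0), np.array([1, 1, 1, 0, 0, 0], dtype=bool))
    assert len(thresholds) == 2  # sentinels only
    pairs = set(zip(sens.tolist(), spec.tolist()))
    assert pairs == {(1.0, 0.0), (0.0, 1.0)}


def test_roc_requires_both_classes():
    with pytest.raises(ValueError, match="both outcome classes"):
        roc_points(np.arange(4.0), np.ones(4, dtype=bool))


def test_fixture_operating_point(table1_cohort):
    df = TIPIScorer().fit_transform(table1_cohort.to_dataframe())
    scores = df["tipi"].to_numpy()
    labels = df["pcr"].to_numpy(dtype=bool)
    conf = confusion_at_cutoff(scores, labels, 11.41)
    assert (conf.tp, conf.fn, conf.tn, conf.fp) == (27, 7, 20, 21)
    assert conf.sensitivity == pytest.approx(27 / 34)
    assert conf.specificity == pytest.approx(20 / 41)
    assert round(100 * conf.sensitivity, 1) == 79.4
    assert round(100 * conf.specificity, 1) == 48.8


def test_confusion_extreme_cutoffs(rng):
    scores = rng.normal(size=40)
    labels = rng.random(40) < 0.5
    hi = confusion_at_cutoff(scores, labels, scores.max() + 1)
    lo = confusion_at_cutoff(scores, labels, scores.min() - 1)
    assert (hi.sensitivity, hi.specificity) == (0.0, 1.0)
    assert (lo.sensitivity, lo.specificity) == (1.0, 0.0)


def test_auc_perfect_separation():
    scores = np.array([1.0, 2.0, 5.0, 6.0])
    labels = np.array([0, 0, 1, 1], dtype=bool)
    assert auc_mann_whitney(scores, labels) == 1.0


def test_auc_matches_pair_counting_oracle(rng):
    """Rank-based AUC equals brute-force pair counting on 300 random instances."""
    for _ in range(300):
        n = rng.integers(4, 25)
        scores = np.round(rng.normal(size=n), 1)  # rounding induces ties
        labels = rng.random(n) < 0.5
        if labels.all() or not labels.any():
            labels[0] = ~labels[0]
        auc = auc_mann_whitney(scores, labels)
        assert auc == pytest.approx(pair_counting_auc(scores, labels), abs=1e-12)
        assert auc == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)


def test_auc_equals_trapezoidal_area(rng):
    scores = rng.normal(size=200)  # tie-free continuous scores
    labels = rng.random(200) < 0.4
    thresholds, sens, spec = roc_points(scores, labels)
    # empirical curve: FPR = 1 - spec decreasing in threshold
    fpr = 1 - spec
    area = -np.trapezoid(sens, fpr)
    assert auc_mann_whitney(scores, labels) == pytest.approx(area, abs=1e-12)


def test_auc_null_mean_near_half(rng):
    aucs = []
    for _ in range(500):
        scores = rng.normal(size=100)
        labels = np.r_[np.ones(50, bool), np.zeros(50, bool)]
        aucs.append(auc_mann_whitney(scores, labels))
    assert abs(np.mean(aucs) - 0.5) < 0.02


def test_auc_invariant_under_monotone_transform(rng):
    scores = rng.normal(size=150)
    labels = rng.random(150) < 0.5
    labels[:2] = [True, False]
    base = auc_mann_whitney(scores, labels)
    assert auc_mann_whitney(np.exp(scores), labels) == pytest.approx(base, abs=1e-12)
    assert auc_mann_whitney(3 * scores - 7, labels) == pytest.approx(base, abs=1e-12)


def test_delong_label_swap_symmetry(rng):
    scores = rng.normal(size=80)
    labels = rng.random(80) < 0.5
    labels[:2] = [True, False]
    auc, se, _, _ = delong_inference(scores, labels)
    auc_sw, se_sw, _, _ = delong_inference(scores, ~labels)
    assert auc_sw == pytest.approx(1 - auc, abs=1e-12)
    assert se_sw == pytest.approx(se, rel=1e-9)


def test_delong_se_close_to_bootstrap(rng):
    """DeLong SE within 10% of a 2000-resample bootstrap SE (binormal, n=200)."""
    n_pos, n_neg = 100, 100
    pos = rng.normal(1.0, 1.0, n_pos)
    neg = rng.normal(0.0, 1.0, n_neg)
    scores = np.concatenate([pos, neg])
    labels = np.r_[np.ones(n_pos, bool), np.zeros(n_neg, bool)]
    _, se, _, _ = delong_inference(scores, labels)
    boot = np.empty(2000)
    for i in range(2000):
        bp = rng.choice(pos, n_pos, replace=True)
        bn = rng.choice(neg, n_neg, replace=True)
        boot[i] = auc_mann_whitney(np.concatenate([bp, bn]), labels)
    assert se == pytest.approx(boot.std(ddof=1), rel=0.10)


def test_binormal_auc_matches_closed_form(rng):
    """Empirical AUC at n=20000 within 0.01 of Phi(delta/sqrt(2))."""
    delta = 0.8
    n = 10_000
    scores = np.concatenate([rng.normal(delta, 1.0, n), rng.normal(0.0, 1.0, n)])
    labels = np.r_[np.ones(n, bool), np.zeros(n, bool)]
    assert auc_mann_whitney(scores, labels) == pytest.approx(stats.norm.cdf(delta / np.sqrt(2)), abs=0.01)


def test_delong_ci_contains_auc_and_clips():
    scores = np.array([1.0, 2.0, 5.0, 6.0, 7.0, 0.5])
    labels = np.array([0, 0, 1, 1, 1, 0], dtype=bool)
    auc, _, (lo, hi), _ = delong_inference(scores, labels)
    assert 0.0 <= lo <= auc <= hi <= 1.0


def test_youden_perfect_separation():
    scores = np.array([1.0, 2.0, 8.0, 9.0])
    labels = np.array([0, 0, 1, 1], dtype=bool)
    thresholds, sens, spec = roc_points(scores, labels)
    cutoff, j, _, _ = youden_optimal(thresholds, sens, spec)
    assert j == pytest.approx(1.0)
    assert cutoff == pytest.approx(5.0)  # midpoint between classes


def test_youden_uninformative_scores():
    thresholds, sens, spec = roc_points(np.full(8, 3.0), np.array([1, 1, 1, 1, 0, 0, 0, 0], dtype=bool))
    _, j, _, _ = youden_optimal(thresholds, sens, spec)
    assert j == pytest.approx(0.0)


def test_youden_ties_break_to_higher_sensitivity_then_lower_cutoff():
    thresholds = np.array([1.0, 2.0, 3.0])
    sens = np.array([0.9, 0.6, 0.9])
    spec = np.array([0.3, 0.6, 0.3])
    cutoff, j, s, _ = youden_optimal(thresholds, sens, spec)
    assert j == pytest.approx(0.2)
    assert s == 0.9
    assert cutoff == 1.0


def test_youden_matches_grid_optimum_on_binormal(rng):
    """At large n the selected cutoff's J is near the theoretical maximum.

    For equal-variance binormal classes the J-maximising threshold is the
    midpoint of the class means.
    """
    delta = 1.2
    n = 10_000
    scores = np.concatenate([rng.normal(delta, 1.0, n), rng.normal(0.0, 1.0, n)])
    labels = np.r_[np.ones(n, bool), np.zeros(n, bool)]
    res = analyze_roc(scores, labels)
    j_theory = stats.norm.cdf(delta / 2) - stats.norm.cdf(-delta / 2)
    assert res.youden_j == pytest.approx(j_theory, abs=0.05)


def test_curve_monotonicity(rng):
    scores = rng.normal(size=120)
    labels = rng.random(120) < 0.5
    labels[:2] = [True, False]
    thresholds, sens, spec = roc_points(scores, labels)
    assert np.all(np.diff(sens) <= 1e-12)
    assert np.all(np.diff(spec) >= -1e-12)


def test_classifier_estimator_roundtrip(rng):
    scores = np.concatenate([rng.normal(1, 1, 60), rng.normal(0, 1, 60)])
    labels = np.r_[np.ones(60, bool), np.zeros(60, bool)]
    clf = YoudenCutoffClassifier().fit(scores, labels)
    assert 0.5 < clf.auc_ <= 1.0
    pred = clf.predict(scores)
    assert pred.dtype == bool
    assert np.array_equal(pred, scores > clf.cutoff_)
    fixed = YoudenCutoffClassifier(fixed_cutoff=0.25).fit(scores, labels)
    assert fixed.cutoff_ == 0.25
    # get_params/set_params sklearn contract
    assert YoudenCutoffClassifier(**clf.get_params()).get_params() == clf.get_params()
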