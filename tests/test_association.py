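"""Contingency tables, chi-square/Fisher selection and continuous comparisons.

Fisher's exact p is checked against an independent hypergeometric-enumeration
oracle, and the asymptotic Mann-Whitney p against exhaustive permutation.
"""

import itertools

import numpy as np
import pytest
from scipy import stats

from tipiscore import (
    ContingencyTable,
    build_contingency,
    compare_continuous_by_group,
    expected_counts,
    fisher_exact_2x2,
    pearson_chi_square,
    select_and_test,
)

# Published 2x2 stratified counts (rows = covariate levels, cols = pCR+/pCR-)
# with their printed uncorrected-Pearson p-values.
TABLE1_2X2 = {
    "tipi_group": ([[7, 20], [27, 21]], 0.011),
    "hr_status": ([[17, 9], [17, 32]], 0.011),
    "her2_category": ([[31, 29], [3, 12]], 0.028),
    "grade": ([[10, 23], [24, 18]], 0.020),
    "menopausal_status": ([[20, 24], [14, 17]], 0.980),
}


def _table(counts):
    r = len(counts)
    return ContingencyTable(
        row_labels=tuple(f"r{i}" for i in range(r)),
        col_labels=("pcr_pos", "pcr_neg"),
        counts=tuple(tuple(row) for row in counts),
    )


def fisher_two_sided_oracle(counts):
    """Two-sided Fisher p by direct enumeration of the hypergeometric support."""
    (a, b), (c, d) = counts
    r1, c1, n = a + b, a + c, a + b + c + d
    k_lo, k_hi = max(0, r1 + c1 - n), min(r1, c1)
    pmf = {k: stats.hypergeom.pmf(k, n, c1, r1) for k in range(k_lo, k_hi + 1)}
    p_obs = pmf[a]
    return min(1.0, sum(p for p in pmf.values() if p <= p_obs * (1 + 1e-7)))


def test_contingency_totals_and_invariants():
    t = _table([[7, 20], [27, 21]])
    assert t.row_totals == (27, 48)
    assert t.col_totals == (34, 41)
    assert t.n == 75
    with pytest.raises(ValueError):
        _table([[1, -1], [0, 2]])


def test_build_contingency_matches_fixture_counts(table1_cohort):
    t = build_contingency(table1_cohort, "hr_status", levels=("negative", "positive"))
    assert t.counts == ((17, 9), (17, 32))
    # permuting record order leaves counts unchanged
    shuffled = table1_cohort.to_dataframe().sample(frac=1, random_state=1)
    t2 = build_contingency(shuffled, "hr_status", levels=("negative", "positive"))
    assert t2.counts == t.counts


def test_build_contingency_single_level_warns(table1_cohort, caplog):
    df = table1_cohort.to_dataframe()
    df["constant"] = "only"
    with caplog.at_level("WARNING"):
        t = build_contingency(df, "constant")
    assert t.shape == (1, 2)
    assert "single observed level" in caplog.text


def test_expected_counts_hand_value():
    t = _table([[7, 20], [27, 21]])
    e = expected_counts(t)
    assert e[0, 0] == pytest.approx(27 * 34 / 75)  # 12.24
    assert np.allclose(e.sum(axis=0), t.array.sum(axis=0))
    assert np.allclose(e.sum(axis=1), t.array.sum(axis=1))
    assert np.all(expected_counts(_table([[5, 5], [5, 5]])) == 5.0)


@pytest.mark.parametrize("name,case", TABLE1_2X2.items())
def test_pearson_reproduces_printed_p_values(name, case):
    counts, printed = case
    res = pearson_chi_square(_table(counts))
    assert res.method == "pearson_chi2"
    assert res.df == 1
    assert round(res.p_value, 3) == printed


def test_pearson_proportional_rows_give_zero_statistic():
    res = pearson_chi_square(_table([[10, 20], [20, 40]]))
    assert res.statistic == pytest.approx(0.0, abs=1e-12)
    assert res.p_value == pytest.approx(1.0)


def test_pearson_row_col_permutation_invariance(rng):
    counts = rng.integers(1, 30, size=(3, 2))
    base = pearson_chi_square(_table(counts.tolist()))
    perm = counts[[2, 0, 1]][:, [1, 0]]
    permuted = pearson_chi_square(_table(perm.tolist()))
    assert permuted.statistic == pytest.approx(base.statistic)


def test_pearson_zero_margin_is_degenerate():
    with pytest.raises(ValueError, match="degenerate"):
        pearson_chi_square(_table([[0, 5], [0, 7]]))


def test_fisher_symmetric_singleton_table():
    assert fisher_exact_2x2(_table([[1, 0], [0, 1]])).p_value == pytest.approx(1.0)


def test_fisher_zero_margin_gives_p_one():
    assert fisher_exact_2x2(_table([[0, 3], [0, 5]])).p_value == pytest.approx(1.0)
    assert fisher_exact_2x2(_table([[3, 0], [5, 0]])).p_value == pytest.approx(1.0)


def test_fisher_matches_enumeration_oracle(rng):
    """Fisher two-sided p equals hypergeometric enumeration on 200 random tables."""
    for _ in range(200):
        counts = rng.integers(0, 12, size=(2, 2))
        if counts.sum() == 0:
            counts[0, 0] = 1
        res = fisher_exact_2x2(_table(counts.tolist()))
        assert res.p_value == pytest.approx(fisher_two_sided_oracle(counts.tolist()), rel=1e-6, abs=1e-12)


def test_selector_routes_small_expected_to_fisher():
    # published Ki-67 table: min expected 6*34/75 = 2.72 < 5
    res = select_and_test(_table([[1, 5], [33, 36]]))
    assert res.method == "fisher_exact_2x2"


def test_selector_routes_large_2x2_to_pearson():
    res = select_and_test(_table([[20, 24], [14, 17]]))
    assert res.method == "pearson_chi2"
    assert round(res.p_value, 3) == 0.980


def test_selector_routes_rx2_to_pearson_even_with_small_cells():
    res = select_and_test(_table([[1, 5], [10, 12], [8, 9]]))
    assert res.method == "pearson_chi2"
    assert res.df == 2


def test_continuous_identical_samples():
    values = np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
    groups = np.array([1, 1, 1, 0, 0, 0])
    res = compare_continuous_by_group(values, groups)
    assert res.p_value == pytest.approx(1.0)


def test_continuous_all_ties_p_one():
    res = compare_continuous_by_group([4.0] * 8, [1, 1, 1, 1, 0, 0, 0, 0])
    assert res.method == "mann_whitney"
    assert res.p_value == 1.0


def test_continuous_large_separated_samples_tiny_p(rng):
    a = rng.normal(1.0, 1.0, 5000)
    b = rng.normal(0.0, 1.0, 5000)
    res = compare_continuous_by_group(np.concatenate([a, b]), np.r_[np.ones(5000), np.zeros(5000)])
    assert res.p_value < 1e-10
    assert res.mean_pos > res.mean_neg


def test_continuous_requires_three_per_group():
    with pytest.raises(ValueError, match="at least 3"):
        compare_continuous_by_group([1.0, 2.0, 3.0, 4.0], [1, 1, 0, 0])


def mann_whitney_exact_p(x, y):
    """Exact two-sided Mann-Whitney p by full enumeration (tie-free data)."""
    pooled = np.concatenate([x, y])
    n1 = len(x)
    ranks = stats.rankdata(pooled)
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    mu = n1 * len(y) / 2
    count = total = 0
    for combo in itertools.combinations(range(len(pooled)), n1):
        u = ranks[list(combo)].sum() - n1 * (n1 + 1) / 2
        total += 1
        if abs(u - mu) >= abs(u_obs - mu) - 1e-9:
            count += 1
    return count / total


def test_mann_whitney_matches_exact_enumeration_small_samples(rng):
    """For tie-free samples of n <= 8 per group the U test matches full enumeration."""
    for _ in range(10):
        n1, n2 = rng.integers(4, 9, size=2)
        # exponential draws force the Mann-Whitney branch past the normality screen
        x = rng.exponential(1.0, n1) ** 3
        y = rng.exponential(2.5, n2) ** 3
        cmp = compare_continuous_by_group(
            np.concatenate([x, y]), np.r_[np.ones(n1), np.zeros(n2)]
        )
        if cmp.method != "mann_whitney":
            continue
        assert cmp.p_value == pytest.approx(mann_whitney_exact_p(x, y), abs=1e-9)


def test_pearson_null_p_approximately_uniform(rng):
    """Under independence the Pearson p for large balanced 2x2s is ~Uniform(0,1)."""
    sims = 2000
    pvals = np.empty(sims)
    for i in range(sims):
        a = rng.binomial(500, 0.5)
        b = rng.binomial(500, 0.5)
        pvals[i] = pearson_chi_square(_table([[a, 500 - a], [b, 500 - b]])).p_value
    d = stats.ks_1samp(pvals, stats.uniform.cdf).statistic
    assert d < 0.05
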