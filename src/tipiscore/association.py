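"""Contingency-table construction and group-comparison tests.

Categorical covariates are cross-tabulated against the binary pCR outcome
and tested with Pearson's chi-square (no continuity correction) or, for 2x2
tables with any expected count below 5, Fisher's exact test with the
two-sided probability-mass definition.  Continuous variables are compared
between outcome groups with Welch's t-test when both groups look normal by
Shapiro-Wilk (alpha = 0.05), and the tie-corrected asymptotic Mann-Whitney U
test otherwise.

The 2x2 chi-square deliberately omits the Yates continuity correction: the
uncorrected statistic is what reproduces published stratified-table p-values
in this setting, and the correction is widely regarded as over-conservative.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "ContingencyTable",
    "TestResult",
    "ContinuousComparison",
    "build_contingency",
    "expected_counts",
    "pearson_chi_square",
    "fisher_exact_2x2",
    "select_and_test",
    "compare_continuous_by_group",
    "FISHER_EXPECTED_THRESHOLD",
]

#: Route a 2x2 table to Fisher's exact test when any expected count is below this.
FISHER_EXPECTED_THRESHOLD = 5.0


@dataclass(frozen=True)
class ContingencyTable:
    """r x c cross-tabulation of a covariate (rows) against pCR (columns).

    Columns are ordered (pCR+, pCR-).  Totals are derived on construction.
    """

    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...]
    counts: tuple[tuple[int, ...], ...]

    def __post_init__(self) -> None:
        arr = np.asarray(self.counts)
        if arr.ndim != 2:
            raise ValueError("counts must be a 2-D array")
        if arr.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValueError("counts shape must match label lengths")
        if np.any(arr < 0) or not np.issubdtype(arr.dtype, np.integer):
            raise ValueError("counts must be nonnegative integers")
        if arr.sum() < 1:
            raise ValueError("table must contain at least one observation")
        object.__setattr__(self, "counts", tuple(tuple(int(v) for v in row) for row in arr))

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.counts, dtype=np.int64)

    @property
    def row_totals(self) -> tuple[int, ...]:
        return tuple(int(v) for v in self.array.sum(axis=1))

    @property
    def col_totals(self) -> tuple[int, ...]:
        return tuple(int(v) for v in self.array.sum(axis=0))

    @property
    def n(self) -> int:
        return int(self.array.sum())

    @property
    def shape(self) -> tuple[int, int]:
        return self.array.shape  # type: ignore[return-value]


@dataclass(frozen=True)
class TestResult:
    """Outcome of a contingency-table test."""

    p_value: float
    method: str  # "pearson_chi2" | "fisher_exact_2x2"
    statistic: float | None = None
    df: int | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p_value must lie in [0, 1], got {self.p_value}")


@dataclass(frozen=True)
class ContinuousComparison:
    """Two-group comparison of a continuous variable by outcome."""

    mean_pos: float
    mean_neg: float
    statistic: float
    p_value: float
    method: str  # "welch_t" | "mann_whitney"
    shapiro_p: tuple[float, float] = field(default=(float("nan"), float("nan")))


def build_contingency(cohort, covariate: str, levels=None) -> ContingencyTable:
    """Cross-tabulate a categorical cohort field against pCR.

    ``levels`` fixes the row ordering; by default the canonical level order
    of the field is used where known, otherwise first-appearance order.
    Levels with zero observations are dropped with a logged warning.
    Derived categoricals ``ki67_category``, ``tils_category`` and
    ``tipi_group`` (requires scored input) are supported in the pipeline via
    DataFrame input.
    """
    import pandas as pd

    if hasattr(cohort, "to_dataframe"):
        df = cohort.to_dataframe()
    elif isinstance(cohort, pd.DataFrame):
        df = cohort
    else:
        raise TypeError("cohort must be a Cohort or DataFrame")
    if covariate not in df.columns:
        raise ValueError(f"unknown covariate {covariate!r}")
    values = df[covariate].astype(str)
    if levels is None:
        levels = list(dict.fromkeys(values))
    pcr = df["pcr"].astype(bool)
    counts = []
    kept = []
    for level in levels:
        mask = values == str(level)
        total = int(mask.sum())
        if total == 0:
            logger.warning("covariate %r: level %r has zero observations; dropped", covariate, level)
            continue
        kept.append(str(level))
        counts.append((int((mask & pcr).sum()), int((mask & ~pcr).sum())))
    if len(kept) < 1:
        raise ValueError(f"covariate {covariate!r} has no observed levels")
    if len(kept) == 1:
        logger.warning("covariate %r has a single observed level", covariate)
    return ContingencyTable(row_labels=tuple(kept), col_labels=("pcr_pos", "pcr_neg"), counts=tuple(counts))


def expected_counts(table: ContingencyTable) -> np.ndarray:
    """Expected counts under independence: E[i,j] = row_i * col_j / n."""
    arr = table.array
    return np.outer(arr.sum(axis=1), arr.sum(axis=0)) / arr.sum()


def pearson_chi_square(table: ContingencyTable) -> TestResult:
    """Pearson chi-square test of independence, no continuity correction."""
    arr = table.array
    if arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValueError("Pearson chi-square requires at least a 2x2 table")
    expected = expected_counts(table)
    if np.any(expected == 0):
        raise ValueError("degenerate table: an expected count is zero (zero margin)")
    chi2, p, df, _ = stats.chi2_contingency(arr, correction=False)
    return TestResult(statistic=float(chi2), df=int(df), p_value=float(p), method="pearson_chi2")


def fisher_exact_2x2(table: ContingencyTable) -> TestResult:
    """Fisher's exact test for a 2x2 table, two-sided probability-mass definition.

    The two-sided p sums hypergeometric probabilities of all tables (with the
    observed margins) no more probable than the observed one, with a 1+1e-7
    relative tolerance absorbing floating-point ties — the convention of
    mainstream statistical software.
    """
    arr = table.array
    if arr.shape != (2, 2):
        raise ValueError("fisher_exact_2x2 requires a 2x2 table")
    _, p = stats.fisher_exact(arr, alternative="two-sided")
    return TestResult(statistic=None, df=None, p_value=float(min(p, 1.0)), method="fisher_exact_2x2")


def select_and_test(table: ContingencyTable) -> TestResult:
    """Chi-square or Fisher "as appropriate".

    Fisher's exact test is used when the table is 2x2 and any expected count
    falls below :data:`FISHER_EXPECTED_THRESHOLD`; everything else (including
    all r x 2 tables with r > 2) goes to uncorrected Pearson chi-square.
    """
    if table.shape == (2, 2) and expected_counts(table).min() < FISHER_EXPECTED_THRESHOLD:
        logger.info("table routed to Fisher exact (min expected %.3f)", expected_counts(table).min())
        return fisher_exact_2x2(table)
    return pearson_chi_square(table)


def compare_continuous_by_group(values, groups, alpha: float = 0.05) -> ContinuousComparison:
    """Compare a continuous variable between two outcome groups.

    Each group is screened with the Shapiro-Wilk test; if both pass at
    ``alpha`` the groups are compared with Welch's t-test, otherwise with the
    Mann-Whitney U test (exact for small tie-free samples, tie-corrected
    normal approximation without continuity correction otherwise).  Requires
    at least 3 observations per group.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups).astype(bool)
    if values.shape != groups.shape:
        raise ValueError("values and groups must have matching shapes")
    pos = values[groups]
    neg = values[~groups]
    if len(pos) < 3 or len(neg) < 3:
        raise ValueError("each group needs at least 3 observations")

    def _shapiro_p(sample: np.ndarray) -> float:
        if np.ptp(sample) == 0:  # constant sample: trivially non-normal
            return 0.0
        return float(stats.shapiro(sample).pvalue)

    sw = (_shapiro_p(pos), _shapiro_p(neg))
    if sw[0] > alpha and sw[1] > alpha:
        res = stats.ttest_ind(pos, neg, equal_var=False)
        method = "welch_t"
        statistic, p = float(res.statistic), float(res.pvalue)
    else:
        res = stats.mannwhitneyu(pos, neg, alternative="two-sided", method="auto", use_continuity=False)
        method = "mann_whitney"
        statistic, p = float(res.statistic), float(res.pvalue)
        if np.ptp(values) == 0:  # all observations tied: no evidence either way
            p = 1.0
    return ContinuousComparison(
        mean_pos=float(pos.mean()),
        mean_neg=float(neg.mean()),
        statistic=statistic,
        p_value=min(p, 1.0),
        method=method,
        shapiro_p=sw,
    )
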