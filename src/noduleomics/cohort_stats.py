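"""Cohort-level statistics: contingency tests, summary t-tests,
radiomics-semantic correlations, and interobserver ICC.

Defaults follow common radiology reporting practice: Pearson chi-square
(no continuity correction) for categorical CT features, Welch's t-test
for continuous summaries (the equal-variance Student variant is a flag),
Spearman rank correlation for radiomics-vs-semantic associations
(Pearson available), and the two-way random-effects, absolute-agreement,
single-rater ICC - ICC(2,1) - for interobserver reproducibility.  All
tests are two-sided; no multiple-testing correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "ContingencyTable",
    "chi_square_test",
    "welch_t_from_summary",
    "rank_correlation",
    "icc_two_way",
]


@dataclass
class ContingencyTable:
    """Counts of a categorical CT feature cross-tabulated against class."""

    counts: np.ndarray
    row_labels: tuple[str, ...] = ()
    col_labels: tuple[str, ...] = ("LC", "LM")

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("contingency table must be 2-D")
        if (self.counts < 0).any() or not np.issubdtype(self.counts.dtype, np.integer):
            if not np.allclose(self.counts, np.round(self.counts)) or (self.counts < 0).any():
                raise ValueError("counts must be nonnegative integers")
            self.counts = self.counts.astype(int)


def chi_square_test(table) -> tuple[float, int, float]:
    """Pearson chi-square test of independence.

    Returns (X^2, df, p) with X^2 = sum (O-E)^2/E and df = (r-1)(c-1).
    Tables with a zero row or column marginal are rejected.
    """
    counts = table.counts if isinstance(table, ContingencyTable) else np.asarray(table)
    if counts.ndim != 2 or min(counts.shape) < 2:
        raise ValueError("need at least a 2x2 table")
    if (counts.sum(axis=0) == 0).any() or (counts.sum(axis=1) == 0).any():
        raise ValueError("zero marginal in contingency table")
    res = stats.chi2_contingency(counts, correction=False)
    return float(res.statistic), int(res.dof), float(res.pvalue)


def welch_t_from_summary(
    m1: float, sd1: float, n1: int, m2: float, sd2: float, n2: int,
    equal_var: bool = False,
) -> tuple[float, float, float]:
    """Two-sided independent t-test from summary statistics.

    Welch's unequal-variance form by default; ``equal_var=True`` gives the
    pooled Student variant.  Returns (t, df, p).
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("standard deviations must be > 0")
    res = stats.ttest_ind_from_stats(m1, sd1, n1, m2, sd2, n2, equal_var=equal_var)
    if equal_var:
        df = float(n1 + n2 - 2)
    else:
        v1, v2 = sd1**2 / n1, sd2**2 / n2
        df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    return float(res.statistic), float(df), float(res.pvalue)


def rank_correlation(x, y, method: str = "spearman") -> tuple[float, float]:
    """Correlation between a radiomics feature and a (possibly binary or
    ordinal) semantic feature.

    Spearman's rho with average ranks for ties is the default (the
    association statistic usually reported for binary semantic flags);
    ``method='pearson'`` gives the product-moment alternative.  Returns
    (coefficient, two-sided p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need >= 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant variable")
    if method == "spearman":
        res = stats.spearmanr(x, y)
    elif method == "pearson":
        res = stats.pearsonr(x, y)
    else:
        raise ValueError("method must be 'spearman' or 'pearson'")
    return float(res.statistic), float(res.pvalue)


def icc_two_way(ratings) -> float:
    """ICC(2,1): two-way random effects, absolute agreement, single rater.

    ``ratings`` is a complete cases x raters matrix.  Computed from the
    two-way ANOVA mean squares:

        ICC = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)

    with n cases and k raters, MSR the between-case, MSC the
    between-rater and MSE the residual mean square.
    """
    r = np.asarray(ratings, dtype=float)
    if r.ndim != 2:
        raise ValueError("ratings must be a 2-D cases x raters matrix")
    n, k = r.shape
    if k < 2:
        raise ValueError("need at least 2 raters")
    if n < 2:
        raise ValueError("need at least 2 cases")
    if not np.all(np.isfinite(r)):
        raise ValueError("ratings matrix must be complete")
    grand = r.mean()
    row_means = r.mean(axis=1)
    col_means = r.mean(axis=0)
    ssr = k * np.sum((row_means - grand) ** 2)
    ssc = n * np.sum((col_means - grand) ** 2)
    sse = np.sum((r - row_means[:, None] - col_means[None, :] + grand) ** 2)
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom == 0:
        return 1.0  # all ratings identical
    return float((msr - mse) / denom)
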