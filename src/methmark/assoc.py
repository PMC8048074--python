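"""Paired and unpaired association tests for tissue validation and
clinicopathological tables.

Paired tumor/normal methylation calls are compared with the exact McNemar
test on discordant pairs. When only the marginal methylation frequencies
are published (not the pairing), ``worst_case_mcnemar_from_marginals``
bounds the McNemar p-value over every pairing consistent with those
marginals. Categorical covariate associations use Pearson's chi-square
(no continuity correction) or Fisher's exact test; continuous covariates
use the independent-samples t test (two groups) or one-way ANOVA.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "PairedStatusTable",
    "mcnemar_exact",
    "mcnemar_chi2",
    "worst_case_mcnemar_from_marginals",
    "contingency_association",
    "group_location_tests",
]


@dataclass(frozen=True)
class PairedStatusTable:
    """2x2 paired-call counts: a = both positive, b = tumor+/normal-,
    c = tumor-/normal+, d = both negative."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("paired counts must be non-negative")


def mcnemar_exact(table: PairedStatusTable) -> float:
    """Exact two-sided McNemar p: binomial test on discordant pairs,
    p = min(1, 2 * min-tail of Binomial(b + c, 1/2)); p = 1 when b + c = 0."""
    b, c = table.b, table.c
    n = b + c
    if n == 0:
        return 1.0
    return min(1.0, 2.0 * float(stats.binom.cdf(min(b, c), n, 0.5)))


def mcnemar_chi2(table: PairedStatusTable, continuity: bool = True) -> float:
    """Chi-square approximation to McNemar's test (optional continuity
    correction); provided for large discordant counts."""
    b, c = table.b, table.c
    if b + c == 0:
        return 1.0
    num = (abs(b - c) - 1) ** 2 if continuity else (b - c) ** 2
    return float(stats.chi2.sf(num / (b + c), df=1))


def worst_case_mcnemar_from_marginals(
    tumor_pos: int, normal_pos: int, n_pairs: int
) -> float:
    """Maximum exact McNemar p over all pairings consistent with the
    marginal positive counts.

    With a = number of pairs positive in both tissues, the discordant
    counts are b = tumor_pos - a and c = normal_pos - a; a ranges over all
    feasible values. The maximum over a bounds the p-value achievable by
    any actual (unpublished) pairing, so ``p_max < alpha`` proves
    significance regardless of the pairing.
    """
    if not (0 <= tumor_pos <= n_pairs and 0 <= normal_pos <= n_pairs):
        raise ValueError("marginal counts must lie in [0, n_pairs]")
    lo = max(0, tumor_pos + normal_pos - n_pairs)
    hi = min(tumor_pos, normal_pos)
    return max(
        mcnemar_exact(
            PairedStatusTable(
                a=a,
                b=tumor_pos - a,
                c=normal_pos - a,
                d=n_pairs - tumor_pos - normal_pos + a,
            )
        )
        for a in range(lo, hi + 1)
    )


def contingency_association(table, mode: str = "pearson_chi2") -> tuple[float, float]:
    """Association test for an r x k contingency table of counts.

    ``pearson_chi2``: Pearson chi-square without continuity correction,
    df = (r-1)(k-1). ``fisher_exact``: two-sided Fisher test (2x2 only).
    ``auto``: Fisher for a 2x2 table with any expected count < 5, else
    Pearson. Returns (statistic, p); the Fisher statistic is the sample
    odds ratio.
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or t.shape[0] < 2 or t.shape[1] < 2:
        raise ValueError("table must be at least 2x2")
    if (t < 0).any():
        raise ValueError("counts must be non-negative")
    if (t.sum(axis=1) == 0).any() or (t.sum(axis=0) == 0).any():
        raise ValueError("table has a zero row or column margin")
    if mode == "auto":
        if t.shape == (2, 2):
            expected = np.outer(t.sum(axis=1), t.sum(axis=0)) / t.sum()
            mode = "fisher_exact" if (expected < 5).any() else "pearson_chi2"
        else:
            mode = "pearson_chi2"
    if mode == "pearson_chi2":
        chi2, p, _, _ = stats.chi2_contingency(t, correction=False)
        return float(chi2), float(p)
    if mode == "fisher_exact":
        if t.shape != (2, 2):
            raise ValueError("fisher_exact requires a 2x2 table")
        odds, p = stats.fisher_exact(t, alternative="two-sided")
        return float(odds), float(p)
    raise ValueError("mode must be 'pearson_chi2', 'fisher_exact' or 'auto'")


def group_location_tests(values, groups) -> float:
    """Location comparison across groups: equal-variance independent-samples
    t test for two groups, one-way ANOVA F test for more."""
    v = np.asarray(values, dtype=float)
    g = np.asarray(groups)
    if v.shape != g.shape:
        raise ValueError("values and groups must have equal length")
    samples = [v[g == lvl] for lvl in np.unique(g)]
    if len(samples) < 2:
        raise ValueError("need at least two groups")
    if any(s.size < 2 for s in samples):
        raise ValueError("every group needs at least two values")
    if len(samples) == 2:
        res = stats.ttest_ind(samples[0], samples[1], equal_var=True)
    else:
        res = stats.f_oneway(*samples)
    p = float(res.pvalue)
    return 1.0 if np.isnan(p) else p
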