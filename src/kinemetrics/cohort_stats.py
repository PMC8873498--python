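"""Cohort assembly, HINE grouping, group comparisons and outcome correlations.

Infants are split on the Hammersmith Infant Neurological Examination global
score (0-78): scores below 60 flag neurodevelopmental risk ("low" group),
scores of 60 or more form the "high" group.  Continuous variables are
compared between groups with Student's t test or the Mann-Whitney U test
(two-sided); categorical variables with the Pearson chi-squared test
(no continuity correction) or Fisher's exact test.  Associations between
complexity indices and the HINE score use Pearson correlation with a
two-sided t-based p-value.

Method selection in ``auto`` mode: t when both groups pass Shapiro-Wilk
normality at alpha = 0.05, else Mann-Whitney; chi-squared unless an expected
cell count is below 5, else Fisher.  Every result records the method used.
No multiple-testing adjustment is applied by default (per-test alpha); a
Benjamini-Hochberg helper is available.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientDataError, ValidationError

__all__ = [
    "HINE_CUT",
    "assign_group",
    "assign_groups",
    "TestResult",
    "compare_groups_continuous",
    "compare_groups_categorical",
    "correlate_with_outcome",
    "build_cohort_table",
    "benjamini_hochberg",
]

#: HINE global-score cut between the risk ("low") and typical ("high") groups.
HINE_CUT = 60


def assign_group(score: float, cut: int = HINE_CUT) -> str:
    """``"low"`` for HINE < cut, ``"high"`` for HINE >= cut (boundary is high)."""
    if not np.isfinite(score) or not 0 <= score <= 78:
        raise ValidationError(f"HINE global score must be in [0, 78], got {score}")
    return "low" if score < cut else "high"


def assign_groups(scores, cut: int = HINE_CUT) -> np.ndarray:
    """Vectorized :func:`assign_group`; returns an array of 'low'/'high'."""
    scores = np.asarray(scores, dtype=float)
    if np.any(~np.isfinite(scores)) or np.any(scores < 0) or np.any(scores > 78):
        raise ValidationError("HINE global scores must be in [0, 78]")
    return np.where(scores < cut, "low", "high")


@dataclass
class TestResult:
    statistic: float
    pvalue: float
    method: str


def compare_groups_continuous(
    values_low,
    values_high,
    method: str = "auto",
    normality_alpha: float = 0.05,
) -> TestResult:
    """Two-sided comparison of a continuous variable between the two groups.

    ``method``: ``"t"`` (Student's t, equal variances), ``"mann-whitney"``,
    or ``"auto"`` (t when both groups pass Shapiro-Wilk at
    ``normality_alpha``, else Mann-Whitney).  Missing values are dropped.
    If every value in both groups is identical the comparison is degenerate
    and p = 1 is returned with a warning.
    """
    a = np.asarray(values_low, dtype=float)
    b = np.asarray(values_high, dtype=float)
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    if len(a) < 1 or len(b) < 1 or len(a) + len(b) < 3:
        raise InsufficientDataError(f"group sizes {len(a)}/{len(b)} too small")
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0.0:
        warnings.warn("all values identical across both groups; p = 1", stacklevel=2)
        return TestResult(float("nan"), 1.0, "degenerate")
    if method == "auto":
        method = "t" if _both_normal(a, b, normality_alpha) else "mann-whitney"
    if method == "t":
        if len(a) < 2 or len(b) < 2:
            raise InsufficientDataError("Student's t needs n >= 2 per group")
        stat, p = stats.ttest_ind(a, b, equal_var=True)
        return TestResult(float(stat), float(p), "t")
    if method == "mann-whitney":
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
        return TestResult(float(res.statistic), float(res.pvalue), "mann-whitney")
    raise ValidationError(f"unknown method {method!r}")


def _both_normal(a: np.ndarray, b: np.ndarray, alpha: float) -> bool:
    for g in (a, b):
        if len(g) < 3 or np.ptp(g) == 0.0:
            return False
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if stats.shapiro(g).pvalue <= alpha:
                return False
    return True


def compare_groups_categorical(table, method: str = "auto") -> TestResult:
    """Compare a 2x2 contingency table (rows = category, cols = group).

    ``method``: ``"chi-squared"`` (Pearson, no continuity correction),
    ``"fisher"`` (exact, two-sided), or ``"auto"`` (chi-squared unless any
    expected cell count < 5, then Fisher).  A zero row or column margin makes
    the comparison undefined (NaN p, method "undefined").
    """
    tab = np.asarray(table)
    if tab.shape != (2, 2) or np.any(tab < 0) or not np.issubdtype(tab.dtype, np.integer):
        if tab.shape != (2, 2) or np.any(tab < 0) or np.any(tab != np.floor(tab)):
            raise ValidationError("table must be 2x2 nonnegative integer counts")
        tab = tab.astype(int)
    if np.any(tab.sum(axis=0) == 0) or np.any(tab.sum(axis=1) == 0):
        warnings.warn("zero margin in 2x2 table; comparison undefined", stacklevel=2)
        return TestResult(float("nan"), float("nan"), "undefined")
    if method == "auto":
        expected = stats.contingency.expected_freq(tab)
        method = "fisher" if np.any(expected < 5) else "chi-squared"
    if method == "chi-squared":
        chi2, p, _, _ = stats.chi2_contingency(tab, correction=False)
        return TestResult(float(chi2), float(p), "chi-squared")
    if method == "fisher":
        odds, p = stats.fisher_exact(tab, alternative="two-sided")
        return TestResult(float(odds), float(p), "fisher")
    raise ValidationError(f"unknown method {method!r}")


def correlate_with_outcome(indices, scores) -> TestResult:
    """Pearson r between a per-infant index and the HINE score, with p-value.

    Pairs with a missing value on either side are dropped; needs >= 3 pairs.
    The p-value is two-sided from the t distribution on n - 2 df.  Zero
    variance on either side gives NaN (undefined).
    """
    x = np.asarray(indices, dtype=float)
    y = np.asarray(scores, dtype=float)
    if x.shape != y.shape:
        raise ValidationError("indices and scores must be paired (equal length)")
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < 3:
        raise InsufficientDataError(f"need >= 3 complete pairs, got {int(ok.sum())}")
    xs, ys = x[ok], y[ok]
    if np.ptp(xs) == 0.0 or np.ptp(ys) == 0.0:
        return TestResult(float("nan"), float("nan"), "undefined")
    res = stats.pearsonr(xs, ys)
    return TestResult(float(res.statistic), float(res.pvalue), "pearson")


def benjamini_hochberg(pvalues) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (optional; off by default)."""
    p = np.asarray(pvalues, dtype=float)
    n = len(p)
    order = np.argsort(p)
    adj = np.empty(n)
    running = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * n / rank)
        adj[i] = running
    return adj


def build_cohort_table(
    records: pd.DataFrame,
    continuous: list[str],
    categorical: list[str],
    score_col: str = "hine_global",
    cut: int = HINE_CUT,
    continuous_method: str = "mann-whitney",
    decimals: int = 1,
) -> pd.DataFrame:
    """Cohort-characteristics table: mean (sd) / n (%) per group, with p-values.

    One row per variable; columns ``overall``, ``low``, ``high``, ``p``,
    ``method``.  Continuous variables print ``mean (sd)`` and are compared
    with ``continuous_method``; binary categorical variables (0/1 or bool)
    print ``n (%)`` with percentages to one decimal and use the
    chi-squared/Fisher auto rule.  A single-record cohort reports sd = 0
    with a flag in the method column.
    """
    if len(records) < 1:
        raise InsufficientDataError("need at least one record")
    groups = assign_groups(records[score_col].to_numpy(), cut=cut)
    low = records.loc[groups == "low"]
    high = records.loc[groups == "high"]
    rows = []

    def fmt_cont(vals) -> str:
        vals = np.asarray(vals, dtype=float)
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            return "-"
        sd = np.std(vals, ddof=1) if vals.size > 1 else 0.0
        return f"{vals.mean():.{decimals}f} ({sd:.{decimals}f})"

    def fmt_cat(vals) -> str:
        vals = np.asarray(vals, dtype=float)
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            return "-"
        n_yes = int(vals.sum())
        return f"{n_yes} ({100.0 * n_yes / vals.size:.1f})"

    for var in continuous:
        flag = "single-record, sd=0" if len(records) == 1 else ""
        try:
            res = compare_groups_continuous(
                low[var].to_numpy(), high[var].to_numpy(), method=continuous_method
            )
            p, meth = res.pvalue, res.method
        except InsufficientDataError:
            p, meth = float("nan"), "not tested"
        rows.append(
            {
                "variable": var,
                "type": "continuous",
                "overall": fmt_cont(records[var]),
                "low": fmt_cont(low[var]),
                "high": fmt_cont(high[var]),
                "p": p,
                "method": (meth + ("; " + flag if flag else "")),
            }
        )
    for var in categorical:
        vals = records[var].astype(float)
        tab = np.array(
            [
                [int(low[var].astype(float).sum()), int(high[var].astype(float).sum())],
                [
                    int((1 - low[var].astype(float)).sum()),
                    int((1 - high[var].astype(float)).sum()),
                ],
            ]
        )
        if len(low) == 0 or len(high) == 0:
            p, meth = float("nan"), "not tested"
        else:
            res = compare_groups_categorical(tab, method="auto")
            p, meth = res.pvalue, res.method
        rows.append(
            {
                "variable": var,
                "type": "categorical",
                "overall": fmt_cat(vals),
                "low": fmt_cat(low[var].astype(float)),
                "high": fmt_cat(high[var].astype(float)),
                "p": p,
                "method": meth,
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["n_total"] = len(records)
    out.attrs["n_low"] = int((groups == "low").sum())
    out.attrs["n_high"] = int((groups == "high").sum())
    return out
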