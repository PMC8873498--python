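"""Grouping, group-comparison tests and outcome correlation."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from kinemetrics.cohort_stats import (
    assign_group,
    assign_groups,
    benjamini_hochberg,
    build_cohort_table,
    compare_groups_categorical,
    compare_groups_continuous,
    correlate_with_outcome,
)
from kinemetrics.errors import ValidationError


def mannwhitney_exact_oracle(a, b):
    """Two-sided exact p by full enumeration of group assignments (no ties)."""
    pooled = sorted(a) + sorted(b)
    n1 = len(a)

    def ustat(group_a, group_b):
        return sum(1 for x in group_a for y in group_b if x > y)

    u_obs = ustat(a, b)
    n1n2 = len(a) * len(b)
    # scipy convention: p = 2 * P(U >= max(U, n1n2 - U)), capped at 1
    u_hi = max(u_obs, n1n2 - u_obs)
    count = total = 0
    for idx in itertools.combinations(range(len(pooled)), n1):
        ga = [pooled[i] for i in idx]
        gb = [pooled[i] for i in range(len(pooled)) if i not in idx]
        total += 1
        if ustat(ga, gb) >= u_hi:
            count += 1
    return min(1.0, 2.0 * count / total)


def fisher_exact_oracle(table):
    """Two-sided Fisher p by hypergeometric enumeration over the margins."""
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def pmf(k):
        return (
            math.comb(r1, k) * math.comb(r2, c1 - k) / math.comb(n, c1)
        )

    p_obs = pmf(a)
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    return sum(pmf(k) for k in range(lo, hi + 1) if pmf(k) <= p_obs * (1 + 1e-9))


class TestGrouping:
    def test_boundary_belongs_to_high(self):
        assert assign_group(59) == "low"
        assert assign_group(60) == "high"

    def test_extremes(self):
        assert assign_group(0) == "low"
        assert assign_group(78) == "high"

    def test_out_of_range_rejected(self):
        for bad in (-1, 79, float("nan")):
            with pytest.raises(ValidationError):
                assign_group(bad)

    def test_cohort_partition_sizes(self):
        rng = np.random.default_rng(0)
        scores = np.concatenate(
            [rng.integers(30, 60, 16), rng.integers(60, 79, 49)]
        )
        rng.shuffle(scores)
        groups = assign_groups(scores)
        assert (groups == "low").sum() == 16
        assert (groups == "high").sum() == 49
        assert len(groups) == 65


class TestContinuousComparison:
    def test_identical_groups_p_is_one(self):
        res = compare_groups_continuous([1, 2, 3], [1, 2, 3], method="mann-whitney")
        assert res.pvalue == 1.0

    def test_exact_mannwhitney_matches_enumeration(self):
        res = compare_groups_continuous([1, 2, 3], [4, 5, 6], method="mann-whitney")
        want = mannwhitney_exact_oracle([1, 2, 3], [4, 5, 6])
        assert want == pytest.approx(0.1, abs=1e-12)
        assert res.pvalue == pytest.approx(want, abs=1e-10)

    def test_mannwhitney_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(4)
        a = rng.standard_normal(8)
        b = rng.standard_normal(9) + 0.8
        p1 = compare_groups_continuous(a, b, method="mann-whitney").pvalue
        p2 = compare_groups_continuous(np.exp(a), np.exp(b), method="mann-whitney").pvalue
        assert p1 == pytest.approx(p2, abs=1e-12)

    def test_auto_picks_t_for_normal_data(self):
        rng = np.random.default_rng(5)
        res = compare_groups_continuous(
            rng.normal(0, 1, 30), rng.normal(0.5, 1, 30), method="auto"
        )
        assert res.method == "t"

    def test_auto_picks_mannwhitney_for_skewed_data(self):
        rng = np.random.default_rng(6)
        a = rng.exponential(1, 40) ** 3
        b = rng.exponential(1, 40) ** 3
        res = compare_groups_continuous(a, b, method="auto")
        assert res.method == "mann-whitney"

    def test_degenerate_identical_values_warns_p_one(self):
        with pytest.warns(UserWarning):
            res = compare_groups_continuous([2.0, 2.0], [2.0, 2.0, 2.0])
        assert res.pvalue == 1.0


class TestCategoricalComparison:
    def test_printed_multiple_gestations_counts(self):
        """Uncorrected chi-squared on the published 2x2 counts prints 0.002."""
        res = compare_groups_categorical([[5, 11], [36, 13]], method="chi-squared")
        assert res.method == "chi-squared"
        assert round(res.pvalue, 3) == 0.002

    def test_homogeneous_table_p_is_one(self):
        res = compare_groups_categorical([[10, 10], [10, 10]], method="chi-squared")
        assert res.pvalue == pytest.approx(1.0, abs=1e-12)

    def test_fisher_matches_enumeration_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            tab = rng.integers(0, 12, (2, 2))
            if tab.sum(axis=0).min() == 0 or tab.sum(axis=1).min() == 0:
                continue
            res = compare_groups_categorical(tab, method="fisher")
            assert res.pvalue == pytest.approx(fisher_exact_oracle(tab), abs=1e-10)

    def test_auto_switches_to_fisher_on_small_expected_counts(self):
        assert compare_groups_categorical([[1, 2], [3, 30]], method="auto").method == "fisher"
        assert (
            compare_groups_categorical([[20, 20], [20, 20]], method="auto").method
            == "chi-squared"
        )

    def test_zero_margin_undefined(self):
        with pytest.warns(UserWarning):
            res = compare_groups_categorical([[0, 0], [5, 7]], method="auto")
        assert math.isnan(res.pvalue)


class TestOutcomeCorrelation:
    def test_exact_linear_relationship(self):
        scores = np.arange(40, 70)
        res = correlate_with_outcome(scores * 0.001 + 0.02, scores)
        assert res.statistic == pytest.approx(1.0, abs=1e-12)
        assert res.pvalue < 1e-20

    def test_recovers_generated_correlation(self):
        """Cohorts generated at rho = 0.3 are estimated without bias."""
        rng = np.random.default_rng(11)
        rho = 0.3
        ests = []
        for _ in range(200):
            z = rng.standard_normal(65)
            x = rho * z + math.sqrt(1 - rho**2) * rng.standard_normal(65)
            ests.append(correlate_with_outcome(x, z).statistic)
        assert abs(np.mean(ests) - rho) < 0.05

    def test_null_is_calibrated(self):
        rng = np.random.default_rng(12)
        rs, ps = [], []
        for _ in range(200):
            x = rng.standard_normal(65)
            y = rng.standard_normal(65)
            res = correlate_with_outcome(x, y)
            rs.append(abs(res.statistic))
            ps.append(res.pvalue)
        assert np.mean(rs) < 0.1
        # p uniform under the null: mean ~0.5 and ~5% below 0.05
        assert 0.4 < np.mean(ps) < 0.6
        assert np.mean(np.asarray(ps) < 0.05) < 0.12


class TestCohortTable:
    def _records(self, n_low=16, n_high=49, seed=0):
        rng = np.random.default_rng(seed)
        scores = np.concatenate(
            [rng.integers(35, 60, n_low), rng.integers(60, 79, n_high)]
        )
        n = n_low + n_high
        female = np.zeros(n, dtype=int)
        female[:26] = 1
        return pd.DataFrame(
            {
                "hine_global": scores,
                "corrected_age_months": rng.normal(3.75, 0.3, n),
                "sex_female": female,
            }
        )

    def test_percentage_formatting_matches_published_style(self):
        """26 female of 65 prints as '26 (40.0)'."""
        table = build_cohort_table(
            self._records(), continuous=["corrected_age_months"], categorical=["sex_female"]
        )
        row = table.loc[table["variable"] == "sex_female"].iloc[0]
        assert row["overall"] == "26 (40.0)"
        assert table.attrs["n_low"] == 16 and table.attrs["n_high"] == 49

    def test_published_count_rows_reproduce_printed_percentages(self):
        # (count, cohort n, printed %) rows from the published cohort table
        for count, n, printed in [
            (26, 65, "40.0"),
            (12, 65, "18.5"),
            (5, 65, "7.7"),
            (41, 65, "63.1"),
            (8, 16, "50.0"),
            (36, 49, "73.5"),
        ]:
            assert f"{100.0 * count / n:.1f}" == printed

    def test_single_record_reports_sd_zero_with_flag(self):
        rec = pd.DataFrame({"hine_global": [65], "age": [3.5]})
        table = build_cohort_table(rec, continuous=["age"], categorical=[])
        row = table.iloc[0]
        assert "(0.0)" in row["overall"]
        assert "single-record" in row["method"]


def test_benjamini_hochberg_monotone_and_bounded():
    p = np.array([0.001, 0.01, 0.02, 0.04, 0.9])
    adj = benjamini_hochberg(p)
    assert np.all(adj >= p - 1e-15) and np.all(adj <= 1.0)
    assert np.all(np.diff(adj[np.argsort(p)]) >= -1e-15)
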