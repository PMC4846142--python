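"""Assumption gating, two-group comparisons, dimorphism, table assembly."""

from itertools import combinations

import numpy as np
import pytest
from scipy import stats as sps

import steatnet as sn
from steatnet.cohort import Cohort, FishRecord
from steatnet.stats import (build_comparison_table, check_assumptions,
                            compare_groups, dimorphism_screen)


def two_sex_cohort(male_vals, female_vals, statuses_m, statuses_f, analyte="K"):
    """Small cohort with one analyte of interest planted per sex."""
    records = []
    for i, (v, s) in enumerate(zip(male_vals, statuses_m)):
        records.append(FishRecord(f"m{i}", "male", 40.0, 1.5, s,
                                  analytes={analyte: float(v)}))
    for i, (v, s) in enumerate(zip(female_vals, statuses_f)):
        records.append(FishRecord(f"f{i}", "female", 40.0, 1.5, s,
                                  analytes={analyte: float(v)}))
    return Cohort(records)


class TestCheckAssumptions:
    def test_clean_normal_passes(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(0, 1, 15), rng.normal(0, 1, 15)
        res = check_assumptions(a, b)
        assert res.parametric_ok and res.reason == "ok"

    def test_skewed_sample_fails_normality(self):
        rng = np.random.default_rng(1)
        a = rng.exponential(1.0, 40) ** 2
        b = rng.normal(10, 1, 40)
        res = check_assumptions(a, b)
        assert not res.parametric_ok and res.reason == "normality"

    def test_variance_ratio_fails_levene(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(0, 1, 40), rng.normal(0, np.sqrt(10), 40)
        res = check_assumptions(a, b)
        assert not res.parametric_ok and res.reason == "variance"

    def test_tiny_group_forces_nonparametric(self):
        res = check_assumptions([1.0, 2.0], [1.0, 2.0, 3.0])
        assert not res.parametric_ok and res.reason == "insufficient n"

    def test_matches_reference_implementations(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(0, 1, 20), rng.normal(0, 1, 20)
        res = check_assumptions(a, b)
        assert res.shapiro_p[0] == pytest.approx(sps.shapiro(a).pvalue)
        assert res.shapiro_p[1] == pytest.approx(sps.shapiro(b).pvalue)
        assert res.levene_p == pytest.approx(
            sps.levene(a, b, center="mean").pvalue)


def mwu_two_sided_oracle(a, b):
    """Exhaustive-permutation two-sided p for the Mann-Whitney U statistic."""
    pooled = list(a) + list(b)
    n1 = len(a)

    def u_of(idx_a):
        aa = [pooled[i] for i in idx_a]
        bb = [pooled[i] for i in range(len(pooled)) if i not in idx_a]
        u = sum((x > y) + 0.5 * (x == y) for x in aa for y in bb)
        return u

    u_obs = u_of(tuple(range(n1)))
    n1n2 = n1 * len(b)
    crit = min(u_obs, n1n2 - u_obs)
    hits = total = 0
    for idx in combinations(range(len(pooled)), n1):
        u = u_of(idx)
        hits += min(u, n1n2 - u) <= crit + 1e-12
        total += 1
    return hits / total


class TestCompareGroups:
    def test_identical_groups_not_significant(self):
        res = compare_groups([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0])
        assert not res.significant
        assert res.p_value > 0.9
        assert res.direction == "none"

    def test_mann_whitney_matches_enumeration_oracle(self):
        """Tiny separated fixture: U = 0 and the two-sided p equals the
        exhaustive permutation value (2/20)."""
        a, b = [1.0, 2.0, 3.0], [4.0, 5.0, 6.0]
        res = compare_groups(a, b, test="mann_whitney")
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(mwu_two_sided_oracle(a, b))
        assert res.p_value == pytest.approx(0.1)

    def test_mann_whitney_oracle_random_fixtures(self):
        # continuous draws (no ties) keep the small-sample branch exact
        rng = np.random.default_rng(4)
        for _ in range(5):
            a = rng.normal(0, 1, 4)
            b = rng.normal(0.5, 1, 5)
            res = compare_groups(a, b, test="mann_whitney")
            assert res.p_value == pytest.approx(mwu_two_sided_oracle(a, b))

    def test_parametric_path_matches_scipy(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(0, 1, 18), rng.normal(0.5, 1, 21)
        res = compare_groups(a, b)
        assert res.test_used == "t_test"
        ref = sps.ttest_ind(a, b)
        assert abs(res.p_value - ref.pvalue) < 1e-10
        assert abs(res.statistic - ref.statistic) < 1e-10

    def test_relabel_symmetry(self):
        rng = np.random.default_rng(6)
        a, b = rng.normal(0, 1, 12), rng.normal(1, 1, 12)
        for test in ("t_test", "mann_whitney"):
            r1 = compare_groups(a, b, test=test, labels=("A", "B"))
            r2 = compare_groups(b, a, test=test, labels=("B", "A"))
            assert r1.p_value == pytest.approx(r2.p_value)
            assert r1.direction == r2.direction  # labels travel with groups

    def test_empty_group_raises(self):
        with pytest.raises(ValueError, match="empty"):
            compare_groups([np.nan, np.nan], [1.0, 2.0], variable="BA")

    def test_direction_reports_higher_group(self):
        res = compare_groups([5.0, 6.0, 7.0, 8.0], [1.0, 2.0, 3.0, 4.0],
                             labels=("healthy", "diseased"))
        assert res.direction == "healthy"


class TestDimorphismScreen:
    def test_planted_female_shift_detected(self):
        """A 2-pooled-SD female shift at n=20/sex is flagged dimorphic in at
        least 95% of 200 seeded replicates."""
        hits = 0
        n_rep = 200
        for s in range(n_rep):
            rng = np.random.default_rng(s)
            m = rng.normal(10.0, 1.0, 20)
            f = rng.normal(12.0, 1.0, 20)  # delta = 2 pooled SD
            cohort = two_sex_cohort(m, f,
                                    statuses_m=[0.0] * 10 + [2.0] * 10,
                                    statuses_f=[0.0] * 10 + [2.0] * 10)
            hits += dimorphism_screen(cohort, "K").dimorphic
        assert hits / n_rep >= 0.95

    def test_constant_variable_not_dimorphic(self):
        cohort = two_sex_cohort([5.0] * 8, [5.0] * 8,
                                [0.0] * 4 + [2.0] * 4,
                                [0.0] * 4 + [2.0] * 4)
        decision = dimorphism_screen(cohort, "K")
        assert not decision.dimorphic and not decision.undetermined

    def test_missing_stratum_undetermined(self):
        cohort = two_sex_cohort([5.0, 6.0, 7.0], [5.0, 6.0, 7.0],
                                [0.0, 0.0, 0.0], [2.0, 2.0, 2.0])
        with pytest.warns(UserWarning, match="undetermined"):
            decision = dimorphism_screen(cohort, "K")
        assert decision.undetermined


class TestComparisonTable:
    def test_structure_on_study_cohort(self, study_cohort):
        table = build_comparison_table(study_cohort)
        df = table.to_frame()
        # BA and UA are excluded from the battery by default
        assert not set(df["variable"]) & {"BA", "UA"}
        # every tested variable appears either combined or as both sexes
        for var, grp in df.groupby("variable"):
            strata = set(grp["stratum"])
            assert strata in ({"combined"}, {"male", "female"})
            assert table.decisions[var].dimorphic == (strata == {"male", "female"})
        # stratification happens iff the screen said dimorphic
        assert (df["p_value"].between(0, 1)).all()
        assert (df["significant"] == (df["p_value"] < table.alpha)).all()

    def test_single_null_variable_one_combined_row(self):
        rng = np.random.default_rng(7)
        vals_m = rng.normal(5, 1, 10)
        vals_f = rng.normal(5, 1, 10)
        cohort = two_sex_cohort(vals_m, vals_f,
                                [0.0] * 5 + [2.0] * 5,
                                [0.0] * 5 + [2.0] * 5)
        table = build_comparison_table(cohort, variables=("K",))
        assert len(table.results) == 1
        row = table.results[0]
        assert row.stratum == "combined"
        assert not row.significant

    def test_all_missing_variable_skipped_not_fatal(self, study_cohort):
        table = build_comparison_table(study_cohort, variables=("UA", "TP"))
        assert "UA" in table.skipped
        assert table.lookup("TP")

    def test_benjamini_hochberg_option(self, study_cohort):
        """FDR adjustment never lowers a p-value and preserves ordering."""
        raw = build_comparison_table(study_cohort)
        adj = build_comparison_table(study_cohort, p_adjust="bh")
        raw_p = {(r.variable, r.stratum): r.p_value for r in raw.results}
        for r in adj.results:
            assert r.p_value >= raw_p[(r.variable, r.stratum)] - 1e-15
            assert r.p_value <= 1.0
            assert r.significant == (r.p_value < adj.alpha)
        # independent oracle: scipy's step-up FDR control
        p = np.array([raw_p[(r.variable, r.stratum)] for r in adj.results])
        expect = sps.false_discovery_control(p, method="bh")
        got = np.array([r.p_value for r in adj.results])
        assert np.allclose(got, expect)
        with pytest.raises(ValueError, match="p_adjust"):
            build_comparison_table(study_cohort, p_adjust="bonferroni")

    def test_markdown_rendering(self, study_cohort):
        table = build_comparison_table(study_cohort)
        text = table.to_markdown()
        assert "| variable |" in text and "TP" in text
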