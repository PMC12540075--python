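"""Rank tests, screening, Enter-method regression, collinearity diagnostics."""

import itertools

import numpy as np
import pytest
from scipy import stats

from modcare import (
    DomainError,
    collinearity_diagnostics,
    fit_enter_regression,
    h_statistic,
    kruskal_wallis_h,
    mann_whitney_z,
    screen_candidates,
    univariate_screen,
)
from modcare.association import TestResult as RankTestResult
from modcare.association import design_matrix
from modcare.cohort import RespondentProfile, SurveyRecord


def make_record(rid, items=None, **overrides):
    base = dict(
        age_band="60-65", education="low", spouse="yes", children="<=1",
        living_alone=False, disabled=False, chronic=False, income_band="0-1500",
    )
    base.update(overrides)
    return SurveyRecord(rid, RespondentProfile(**base), tuple(items or [3] * 19))


def brute_force_u(a, b):
    """Independent U oracle: count of (a < b) pairs plus half the ties."""
    return sum((x < y) + 0.5 * (x == y) for x in a for y in b)


class TestMannWhitney:
    def test_identical_groups_no_shift(self):
        res = mann_whitney_z([3, 3, 3], [3, 3, 3])
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_exact_p_by_enumeration(self):
        """U = 0 for {1,2} vs {3,4}; 1 of 6 assignments is as extreme."""
        res = mann_whitney_z([1, 2], [3, 4], exact=True)
        assert res.p_value == pytest.approx(2 / 6)

    @pytest.mark.parametrize(
        "a, b",
        [
            ([1, 2], [3, 4]),
            ([1, 5, 3], [2, 2, 4]),
            ([2, 2, 3, 3], [1, 4, 5]),
            ([1, 2, 3, 4], [5, 6, 7, 8]),
        ],
    )
    def test_exact_p_matches_independent_enumeration(self, a, b):
        """Exact p equals a from-scratch permutation of group labels."""
        res = mann_whitney_z(a, b, exact=True)
        pooled = a + b
        n1 = len(a)
        u_obs = brute_force_u(b, a)  # U for group_a: pairs b<a etc.
        us = []
        for comb in itertools.combinations(range(len(pooled)), n1):
            ga = [pooled[i] for i in comb]
            gb = [pooled[i] for i in range(len(pooled)) if i not in comb]
            us.append(brute_force_u(gb, ga))
        us = np.array(us)
        lo = np.mean(us <= u_obs + 1e-12)
        hi = np.mean(us >= u_obs - 1e-12)
        assert res.p_value == pytest.approx(min(1.0, 2 * min(lo, hi)))

    def test_asymptotic_p_matches_scipy_without_continuity(self):
        rng = np.random.default_rng(4)
        a = rng.integers(1, 6, size=40).astype(float)
        b = rng.integers(1, 6, size=55).astype(float)
        ours = mann_whitney_z(a, b)
        ref = stats.mannwhitneyu(a, b, alternative="two-sided",
                                 method="asymptotic", use_continuity=False)
        assert ours.p_value == pytest.approx(ref.pvalue, abs=1e-12)

    def test_shift_never_decreases_absolute_z(self):
        rng = np.random.default_rng(8)
        a = rng.normal(size=25)
        b = rng.normal(size=25)
        zs = [abs(mann_whitney_z(a, b + shift).statistic) for shift in (0.5, 1.0, 2.0, 4.0)]
        assert all(z2 >= z1 - 1e-12 for z1, z2 in zip(zs, zs[1:]))

    def test_empty_group_rejected(self):
        with pytest.raises(DomainError):
            mann_whitney_z([], [1, 2])


class TestKruskalWallis:
    def test_identical_groups(self):
        res = kruskal_wallis_h([[3, 3], [3, 3], [3, 3]])
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_singleton_groups_match_permutation_oracle(self):
        """H for {1},{2},{3} from the rank formula; the permutation
        distribution over all 3! arrangements is constant at that value."""
        h, _ = h_statistic([[1], [2], [3]])
        hs = [h_statistic([[a], [b], [c]])[0] for a, b, c in itertools.permutations([1, 2, 3])]
        assert hs == pytest.approx([h] * 6)
        # manual rank formula: H = 12/(3*4) * (1 + 4 + 9) - 3*4 = 2
        assert h == pytest.approx(2.0)

    def test_matches_scipy_on_tied_data(self):
        rng = np.random.default_rng(12)
        groups = [rng.integers(1, 6, size=m).astype(float) for m in (20, 15, 25, 10)]
        ours = kruskal_wallis_h(groups)
        ref = stats.kruskal(*groups)
        assert ours.statistic == pytest.approx(ref.statistic)
        assert ours.p_value == pytest.approx(ref.pvalue)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(3)
        groups = [rng.normal(size=m) for m in (8, 12, 10)]
        h1, _ = h_statistic(groups)
        h2, _ = h_statistic([np.exp(g) for g in groups])
        assert h1 == pytest.approx(h2)

    def test_two_groups_routed_to_mann_whitney(self):
        with pytest.raises(DomainError):
            kruskal_wallis_h([[1, 2], [3, 4]])

    def test_two_group_h_equals_z_squared_without_ties(self):
        rng = np.random.default_rng(77)
        a = rng.normal(size=35)
        b = rng.normal(loc=0.4, size=40)
        z = mann_whitney_z(a, b).statistic
        h, _ = h_statistic([a, b])
        assert h == pytest.approx(z**2, abs=1e-6)


class TestScreening:
    def mk(self, factor, p):
        return RankTestResult(factor, "life_assistance", "mann_whitney_z", 0.0, p)

    def test_strict_threshold(self):
        tests = [self.mk("a", 0.04), self.mk("b", 0.05), self.mk("c", 0.6)]
        assert screen_candidates(tests, 0.05) == ["a"]

    def test_min_p_across_dimension_tests(self):
        tests = [self.mk("a", 0.2), self.mk("a", 0.01)]
        assert screen_candidates(tests, 0.05) == ["a"]

    def test_empty_input(self):
        assert screen_candidates([], 0.05) == []

    def test_screen_finds_true_effects_in_cohort(self, medium_cohort):
        tests = univariate_screen(medium_cohort, "life_assistance")
        selected = screen_candidates(tests)
        # living alone and disability carry the largest true effects
        assert "living_alone" in selected and "self_care" in selected


class TestEnterRegression:
    def test_perfect_linear_fit(self):
        records = [make_record(i, disabled=(i % 2 == 0)) for i in range(40)]
        y = [2.0 + 0.5 * (r.profile.disabled) for r in records]
        fit = fit_enter_regression(records, "life_assistance", ["self_care"], y=y)
        assert fit.intercept == pytest.approx(2.0)
        assert fit.coefficient("disabled").B == pytest.approx(0.5)
        assert fit.r_squared == pytest.approx(1.0)

    def test_reference_rows_emitted_with_zero_b(self, medium_cohort):
        fit = fit_enter_regression(medium_cohort, "life_assistance", ["age_band", "self_care"])
        ref_rows = [c for c in fit.coefficients if c.is_reference]
        assert {c.predictor for c in ref_rows} == {"age_60_65", "independent"}
        assert all(c.B == 0.0 for c in ref_rows)

    def test_sole_dummy_equals_group_mean_difference(self, medium_cohort):
        from modcare.descriptives import cohort_dimension_scores

        fit = fit_enter_regression(medium_cohort, "medical_care", ["living_alone"])
        scores = cohort_dimension_scores(medium_cohort, "medical_care")
        alone = np.array([r.profile.living_alone for r in medium_cohort])
        diff = scores[alone].mean() - scores[~alone].mean()
        assert fit.coefficient("living_alone").B == pytest.approx(diff)

    def test_tolerance_vif_reciprocal(self, medium_cohort):
        fit = fit_enter_regression(
            medium_cohort, "life_assistance",
            ["age_band", "education", "spouse", "living_alone", "self_care", "chronic"],
        )
        for c in fit.coefficients:
            if not c.is_reference:
                assert c.tolerance * c.vif == pytest.approx(1.0, abs=1e-9)

    def test_orthogonal_dummies_have_unit_vif(self):
        # fully crossed balanced design: education x chronic
        records = []
        rid = 0
        for edu in ("low", "high"):
            for chronic in (False, True):
                for _ in range(10):
                    rid += 1
                    records.append(make_record(rid, education=edu, chronic=chronic))
        frame = design_matrix(records, ["education", "chronic"])
        stats_out, _ = collinearity_diagnostics(frame, np.zeros(len(records)))
        assert all(s.vif == pytest.approx(1.0) for s in stats_out)

    def test_duplicated_predictor_flagged_infinite(self):
        # living_alone == disabled for everyone -> perfectly collinear dummies
        records = [make_record(i, living_alone=(i % 3 == 0), disabled=(i % 3 == 0))
                   for i in range(30)]
        frame = design_matrix(records, ["living_alone", "self_care"])
        stats_out, _ = collinearity_diagnostics(frame, np.zeros(len(records)))
        assert all(s.infinite for s in stats_out)
        with pytest.raises(DomainError, match="collinear"):
            fit_enter_regression(records, "life_assistance", ["living_alone", "self_care"])

    def test_durbin_watson_near_two_for_independent_noise(self, study_truth):
        from modcare import DemographicConfig, generate_cohort

        recs = generate_cohort(DemographicConfig(n=5000, seed=41), study_truth)
        y = [r.latents[1] for r in recs]
        fit = fit_enter_regression(recs, "medical_care", ["self_care", "chronic"], y=y)
        assert fit.durbin_watson == pytest.approx(2.0, abs=0.1)

    def test_rejects_undersized_cohort(self):
        records = [make_record(i) for i in range(3)]
        with pytest.raises(DomainError):
            fit_enter_regression(records, "life_assistance",
                                 ["age_band", "education", "income_band"])
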