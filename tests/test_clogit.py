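"""Conditional-logistic likelihood, fitting, score test, concordance.

Oracles: explicit per-set enumeration of the conditional probability,
central finite differences, the classical matched-pairs discordant-count
estimator, the Cochran-Mantel-Haenszel statistic computed directly from
the stratified 2x2 tables, and statsmodels' ConditionalLogit.
"""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from caerisk.clogit import (
    Term,
    build_design,
    conditional_loglik,
    fit_clogit,
    fit_matched,
    informative_sets,
    matched_concordance,
    score_test,
)
from caerisk.exceptions import ConfigError, DataError, SeparationError

from conftest import cmh_statistic, enumeration_loglik, random_matched_instance


class TestLoglik:
    def test_uniform_at_beta_zero(self):
        rng = np.random.default_rng(1)
        X, y, groups = random_matched_instance(rng, n_sets=7, set_size=3)
        val, _, _ = conditional_loglik(np.zeros(2), X, y, groups)
        assert val == pytest.approx(-7 * np.log(3), abs=1e-12)

    def test_single_set_closed_form(self):
        X = np.array([[1.0], [0.0], [0.0]])
        y = np.array([True, False, False])
        groups = np.zeros(3, dtype=int)
        val, _, _ = conditional_loglik(np.array([np.log(3.0)]), X, y, groups)
        assert val == pytest.approx(np.log(3.0 / 5.0), abs=1e-12)

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(7)
        for trial in range(20):
            n_sets = int(rng.integers(1, 6))
            set_size = int(rng.integers(2, 5))
            X, y, groups = random_matched_instance(rng, n_sets, set_size)
            beta = rng.normal(size=2)
            val, _, _ = conditional_loglik(beta, X, y, groups)
            assert val == pytest.approx(enumeration_loglik(beta, X, y, groups), abs=1e-10)

    def test_gradient_hessian_match_finite_differences(self):
        rng = np.random.default_rng(3)
        X, y, groups = random_matched_instance(rng, n_sets=12, set_size=3)
        beta = rng.normal(scale=0.5, size=2)
        val, grad, hess = conditional_loglik(beta, X, y, groups)
        h = 1e-6
        for j in range(2):
            e = np.zeros(2)
            e[j] = h
            vp, gp, _ = conditional_loglik(beta + e, X, y, groups)
            vm, gm, _ = conditional_loglik(beta - e, X, y, groups)
            assert (vp - vm) / (2 * h) == pytest.approx(grad[j], rel=1e-6, abs=1e-8)
            np.testing.assert_allclose((gp - gm) / (2 * h), hess[:, j], rtol=1e-5, atol=1e-6)

    def test_hessian_negative_semidefinite(self):
        rng = np.random.default_rng(9)
        for _ in range(10):
            X, y, groups = random_matched_instance(rng, n_sets=8, set_size=4)
            _, _, hess = conditional_loglik(rng.normal(size=2), X, y, groups)
            assert np.linalg.eigvalsh(hess).max() < 1e-10

    def test_two_cases_in_a_set_rejected(self):
        X = np.zeros((3, 1))
        y = np.array([True, True, False])
        with pytest.raises(DataError):
            conditional_loglik(np.zeros(1), X, y, np.zeros(3, dtype=int))

    def test_missing_covariate_rejected(self):
        X = np.array([[np.nan], [0.0], [0.0]])
        y = np.array([True, False, False])
        with pytest.raises(DataError):
            conditional_loglik(np.zeros(1), X, y, np.zeros(3, dtype=int))


class TestFit:
    def test_loglik_improves_over_null(self):
        rng = np.random.default_rng(11)
        X, y, groups = random_matched_instance(rng, n_sets=50, set_size=3)
        fit = fit_clogit(X, y, groups)
        assert fit.converged
        assert fit.loglik >= fit.loglik_null
        assert fit.loglik <= 0.0
        ci = fit.conf_int
        assert (ci[:, 0] <= fit.odds_ratio).all() and (fit.odds_ratio <= ci[:, 1]).all()

    def test_matches_statsmodels(self):
        from statsmodels.discrete.conditional_models import ConditionalLogit

        rng = np.random.default_rng(13)
        X, y, groups = random_matched_instance(rng, n_sets=120, set_size=3, p_covs=2)
        fit = fit_clogit(X, y, groups)
        sm_fit = ConditionalLogit(y.astype(int), X, groups=groups).fit(disp=0)
        np.testing.assert_allclose(fit.beta, sm_fit.params, atol=5e-5)
        np.testing.assert_allclose(fit.se, sm_fit.bse, atol=5e-5)

    def test_matched_pairs_reduces_to_discordant_ratio(self):
        """1:1 sets with a binary covariate: beta-hat = log(n10/n01), the
        classical matched-pairs estimator, computed here by direct count."""
        rng = np.random.default_rng(17)
        n = 300
        x_case = (rng.random(n) < 0.6).astype(float)
        x_ctrl = (rng.random(n) < 0.3).astype(float)
        X = np.empty((2 * n, 1))
        X[::2, 0], X[1::2, 0] = x_case, x_ctrl
        y = np.zeros(2 * n, dtype=bool)
        y[::2] = True
        groups = np.repeat(np.arange(n), 2)
        n10 = int(((x_case == 1) & (x_ctrl == 0)).sum())
        n01 = int(((x_case == 0) & (x_ctrl == 1)).sum())
        fit = fit_clogit(X, y, groups)
        assert fit.beta[0] == pytest.approx(np.log(n10 / n01), abs=1e-6)

    def test_complete_separation_raises(self):
        n = 30
        X = np.tile([[1.0], [0.0], [0.0]], (n, 1))
        y = np.tile([True, False, False], n)
        groups = np.repeat(np.arange(n), 3)
        with pytest.raises(SeparationError) as err:
            fit_clogit(X, y, groups, names=["exposure"])
        assert "exposure" in str(err.value)

    def test_constant_exposure_within_sets_is_error(self):
        X = np.array([[1.0], [1.0], [1.0], [0.0], [0.0], [0.0]])
        y = np.array([True, False, False, True, False, False])
        groups = np.repeat([0, 1], 3)
        with pytest.raises(DataError):
            fit_clogit(X, y, groups)

    def test_informative_set_mask(self):
        X = np.array([[1.0], [1.0], [0.0], [1.0]])
        groups = np.array([0, 0, 1, 1])
        np.testing.assert_array_equal(informative_sets(X, groups), [False, True])


class TestScoreTest:
    def test_equals_cmh_on_binary_strata(self):
        rng = np.random.default_rng(19)
        n_sets = 80
        x = (rng.random(3 * n_sets) < 0.4).astype(float)
        y = np.zeros(3 * n_sets, dtype=bool)
        y[::3] = True
        groups = np.repeat(np.arange(n_sets), 3)
        chi2, p = score_test(x, y, groups)
        assert chi2 == pytest.approx(cmh_statistic(x, y, groups), abs=1e-10)
        assert 0.0 <= p <= 1.0

    def test_zero_when_observed_equals_expected(self):
        # one exposed member per set, case exposed in exactly 1/3 of sets
        x = np.tile([1.0, 0.0, 0.0], 3)
        x_rot = np.concatenate([x[:3], np.roll(x[3:6], 1), np.roll(x[6:], 2)])
        y = np.tile([True, False, False], 3)
        groups = np.repeat(np.arange(3), 3)
        chi2, _ = score_test(x_rot, y, groups)
        assert chi2 == pytest.approx(0.0, abs=1e-12)

    def test_zero_information_is_error(self):
        x = np.ones(6)
        y = np.tile([True, False, False], 2)
        with pytest.raises(DataError):
            score_test(x, y, np.repeat([0, 1], 3))


class TestConcordance:
    def test_perfect_separation_gives_one(self):
        lp = np.tile([2.0, 0.0, 1.0], 10)
        y = np.tile([True, False, False], 10)
        groups = np.repeat(np.arange(10), 3)
        assert matched_concordance(lp, y, groups) == 1.0

    def test_constant_predictor_gives_half(self):
        lp = np.zeros(30)
        y = np.tile([True, False, False], 10)
        groups = np.repeat(np.arange(10), 3)
        assert matched_concordance(lp, y, groups) == 0.5

    def test_random_predictor_near_half(self):
        rng = np.random.default_rng(23)
        n_sets = 1000
        lp = rng.normal(size=3 * n_sets)
        y = np.zeros(3 * n_sets, dtype=bool)
        y[::3] = True
        groups = np.repeat(np.arange(n_sets), 3)
        assert abs(matched_concordance(lp, y, groups) - 0.5) < 0.05


class TestDesignMatrix:
    @pytest.fixture
    def cov(self):
        return pd.DataFrame(
            {
                "id": ["a", "b", "c", "d"],
                "age_at_baseline": [60.0, 70.0, 65.0, 72.0],
                "morphology": ["advanced", "non_advanced", "advanced", "non_advanced"],
                "high_cae": [True, False, False, True],
            }
        )

    def test_numeric_indicator_interaction(self, cov):
        terms = [
            Term(name="age", kind="numeric", column="age_at_baseline"),
            Term(name="advanced", kind="indicator", column="morphology", level="advanced"),
            Term(name="cae", kind="indicator", column="high_cae", level=True),
            Term(name="adv_x_cae", kind="interaction", of=("advanced", "cae")),
        ]
        X, names = build_design(cov, terms)
        assert names == ["age", "advanced", "cae", "adv_x_cae"]
        np.testing.assert_array_equal(X[:, 3], [1.0, 0.0, 0.0, 0.0])

    def test_combined_categorical_reference_cell(self, cov):
        term = Term(
            name="mm",
            kind="categorical",
            columns=("morphology", "high_cae"),
            reference=("non_advanced", False),
        )
        X, names = build_design(cov, [term])
        assert len(names) == 3  # 4 observed cells minus reference
        # reference row (b) is all zeros
        assert X[1].sum() == 0.0

    def test_unknown_column_is_config_error(self, cov):
        with pytest.raises(ConfigError) as err:
            build_design(cov, [Term(name="x", kind="numeric", column="nope")])
        assert "nope" in str(err.value)

    def test_fit_matched_end_to_end(self, small_cohort, small_cohort_frame):
        from caerisk.matching import match_cases, sets_to_frame

        sets, _ = match_cases(small_cohort, seed=31)
        sets_df = sets_to_frame(sets)
        fit = fit_matched(
            sets_df,
            small_cohort_frame,
            [Term(name="advanced", kind="indicator", column="morphology", level="advanced")],
        )
        assert fit.converged
        # the generator plants a strongly positive morphology effect
        assert fit.odds_ratio[0] > 1.0


@given(st.integers(min_value=0, max_value=2**31 - 1))
@settings(max_examples=25, deadline=None, derandomize=True)
def test_loglik_at_mle_never_below_null(seed):
    rng = np.random.default_rng(seed)
    X, y, groups = random_matched_instance(rng, n_sets=25, set_size=3)
    try:
        fit = fit_clogit(X, y, groups)
    except SeparationError:
        return  # infinite MLE: the monotone-likelihood property is vacuous
    assert fit.loglik >= fit.loglik_null - 1e-9
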