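"""Quadratic response-surface fit and lack-of-fit ANOVA."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rsmferm import FactorDef, QuadraticResponseSurface, box_behnken, rank_effects
from rsmferm.rsm import _expand, quadratic_terms


def bbd13():
    factors = [FactorDef(n, center=0, step=1) for n in ("x1", "x2", "x3")]
    return box_behnken(factors, n_center=5)


def quad_eval(beta, X):
    return beta[0] + _expand(np.atleast_2d(X)) @ beta[1:]


class TestGoldenFit:
    """The published 17-run surface experiment, recomputed from its table."""

    def test_equation_coefficients(self, bbd_fit):
        assert bbd_fit.intercept_ == pytest.approx(2.07, abs=5e-3)
        c = dict(zip(bbd_fit.term_names_, bbd_fit.coef_))
        assert c["beef_broth"] == pytest.approx(0.0275, abs=5e-4)
        assert c["peptone"] == pytest.approx(-0.04, abs=5e-3)
        assert c["glucose"] == pytest.approx(0.18, abs=5e-3)
        assert c["beef_broth:peptone"] == pytest.approx(0.03, abs=5e-3)
        assert c["beef_broth:glucose"] == pytest.approx(-0.05, abs=5e-3)
        assert c["peptone:glucose"] == pytest.approx(0.095, abs=5e-4)
        assert c["beef_broth^2"] == pytest.approx(-0.045, abs=5e-4)
        assert c["peptone^2"] == pytest.approx(0.04, abs=5e-3)
        assert c["glucose^2"] == pytest.approx(-0.26, abs=5e-3)

    def test_anova_matches_published_table(self, bbd_fit):
        a = bbd_fit.anova_
        assert a.loc["Model", "sum_sq"] == pytest.approx(0.6292, abs=5e-5)
        assert a.loc["Model", "df"] == 9
        assert a.loc["Model", "F"] == pytest.approx(63.97, abs=5e-2)
        expected = {
            "beef_broth": (0.006, 5.54, 0.0509),
            "peptone": (0.0128, 11.71, 0.0111),
            "glucose": (0.2592, 237.18, None),
            "beef_broth:peptone": (0.0036, 3.29, 0.1124),
            "beef_broth:glucose": (0.01, 9.15, 0.0193),
            "peptone:glucose": (0.0361, 33.03, 0.0007),
            "beef_broth^2": (0.0085, 7.80, 0.0268),
            "peptone^2": (0.0067, 6.16, 0.042),
            "glucose^2": (0.2846, 260.45, None),
        }
        for term, (ss, F, p) in expected.items():
            assert a.loc[term, "sum_sq"] == pytest.approx(ss, abs=1e-4)
            assert a.loc[term, "F"] == pytest.approx(F, abs=5e-2)
            if p is not None:
                assert a.loc[term, "p"] == pytest.approx(p, abs=5e-4)
            else:
                assert a.loc[term, "p"] < 1e-4
        assert a.loc["Residual", "sum_sq"] == pytest.approx(0.0077, abs=5e-5)
        assert a.loc["Residual", "df"] == 7
        assert a.loc["Lack of fit", "df"] == 3
        assert a.loc["Lack of fit", "sum_sq"] == pytest.approx(0.0055, abs=1e-4)
        assert a.loc["Lack of fit", "F"] == pytest.approx(3.3, abs=5e-2)
        assert a.loc["Lack of fit", "p"] == pytest.approx(0.1393, abs=5e-4)
        assert a.loc["Pure error", "sum_sq"] == pytest.approx(0.0022, abs=5e-5)
        assert a.loc["Pure error", "df"] == 4
        assert a.loc["Cor total", "sum_sq"] == pytest.approx(0.6368, abs=5e-5)

    def test_diagnostics(self, bbd_fit):
        assert bbd_fit.r2_ == pytest.approx(0.988, abs=5e-4)
        assert bbd_fit.r2_adj_ == pytest.approx(0.9725, abs=5e-5)
        assert bbd_fit.cv_percent_ == pytest.approx(1.7, abs=5e-2)

    def test_predicted_values(self, bbd_fit):
        # center prediction and the run-17 / run-3 table entries
        assert bbd_fit.predict([[0, 0, 0]])[0] == pytest.approx(2.07, abs=5e-3)
        assert bbd_fit.predict([[-1, -1, 0]])[0] == pytest.approx(2.11, abs=5e-3)
        p3 = bbd_fit.predict([[-1, 0, -1]])[0]
        assert round(p3, 2) == 1.51
        assert round(1.48 - p3, 2) == -0.03

    def test_intercept_equals_center_mean(self, bbd_data, bbd_fit):
        design, responses = bbd_data
        center_mean = responses.mean[design.center_flags].mean()
        assert bbd_fit.intercept_ == pytest.approx(center_mean, abs=1e-10)
        assert center_mean == pytest.approx(2.07, abs=1e-10)

    def test_effect_ranking(self, bbd_fit):
        ranks = rank_effects(bbd_fit)
        assert ranks["linear"] == ["glucose", "peptone", "beef_broth"]
        assert ranks["interaction"] == [
            "peptone:glucose",
            "beef_broth:glucose",
            "beef_broth:peptone",
        ]


class TestFitProperties:
    def test_noiseless_recovery(self, rng):
        d = bbd13()
        beta = rng.normal(0, 1, 10)
        y = quad_eval(beta, d.coded)
        fit = QuadraticResponseSurface().fit(d.coded, y)
        np.testing.assert_allclose(
            np.concatenate([[fit.intercept_], fit.coef_]), beta, atol=1e-10
        )

    def test_pure_interaction_interpolation(self):
        d = bbd13()
        y = 1.0 + d.coded[:, 2] ** 2
        fit = QuadraticResponseSurface().fit(d.coded, y)
        assert fit.predict([[0, 0, 1]])[0] == pytest.approx(2.0, abs=1e-10)

    @given(st.lists(st.floats(0.5, 3.0), min_size=17, max_size=17))
    @settings(max_examples=100, derandomize=True)
    def test_ss_conservation_both_levels(self, ys):
        d = bbd13()
        y = np.asarray(ys)
        fit = QuadraticResponseSurface().fit(d.coded, y)
        a = fit.anova_
        assert a.loc["Model", "sum_sq"] + a.loc["Residual", "sum_sq"] == pytest.approx(
            a.loc["Cor total", "sum_sq"], rel=1e-9, abs=1e-12
        )
        assert a.loc["Lack of fit", "sum_sq"] + a.loc["Pure error", "sum_sq"] == pytest.approx(
            a.loc["Residual", "sum_sq"], rel=1e-9, abs=1e-12
        )

    def test_term_ss_equals_drop_one_refit(self, rng):
        """Type III single-df SS == increase in residual SS when the term is dropped."""
        d = bbd13()
        y = rng.normal(2.0, 0.2, 17)
        fit = QuadraticResponseSurface().fit(d.coded, y)
        M = np.column_stack([np.ones(17), _expand(d.coded)])
        full_rss = fit.residual_ss_
        for j, term in enumerate(fit.term_names_, start=1):
            Mr = np.delete(M, j, axis=1)
            beta_r, *_ = np.linalg.lstsq(Mr, y, rcond=None)
            rss_r = float(np.sum((y - Mr @ beta_r) ** 2))
            assert fit.anova_.loc[term, "sum_sq"] == pytest.approx(
                rss_r - full_rss, rel=1e-8, abs=1e-10
            )

    def test_matches_statsmodels(self, bbd_data):
        import statsmodels.api as sm

        design, responses = bbd_data
        M = sm.add_constant(_expand(design.coded))
        ols = sm.OLS(responses.mean, M).fit()
        fit = QuadraticResponseSurface().fit(design.coded, responses.mean)
        np.testing.assert_allclose(
            np.concatenate([[fit.intercept_], fit.coef_]), ols.params, atol=1e-10
        )
        assert fit.r2_ == pytest.approx(ols.rsquared, abs=1e-10)
        # statsmodels t-tests are the square roots of the single-df F tests
        for j, term in enumerate(fit.term_names_, start=1):
            assert fit.anova_.loc[term, "F"] == pytest.approx(ols.tvalues[j] ** 2, rel=1e-8)
            assert fit.anova_.loc[term, "p"] == pytest.approx(ols.pvalues[j], rel=1e-8)

    def test_equal_center_responses_zero_pure_error(self):
        d = bbd13()
        y = 2.0 + 0.1 * d.coded[:, 0] + 0.05 * np.arange(17) % 2 * (~d.center_flags)
        fit = QuadraticResponseSurface().fit(d.coded, y)
        assert fit.anova_.loc["Pure error", "sum_sq"] == pytest.approx(0, abs=1e-20)

    def test_single_center_sets_warning_and_omits_lof(self):
        factors = [FactorDef(n, center=0, step=1) for n in ("a", "b", "c")]
        d = box_behnken(factors, n_center=1)
        y = np.linspace(1, 2, 13)
        fit = QuadraticResponseSurface().fit(d.coded, y)
        assert fit.lack_of_fit_warning_
        assert "Lack of fit" not in fit.anova_.index
        assert "Pure error" not in fit.anova_.index

    def test_too_few_runs_rejected(self):
        X = bbd13().coded[:10]
        with pytest.raises(ValueError, match="runs"):
            QuadraticResponseSurface().fit(X, np.ones(10))

    def test_wrong_prediction_dimension_rejected(self, bbd_fit):
        with pytest.raises(ValueError, match="coordinates"):
            bbd_fit.predict([[0.0, 0.0]])

    def test_tied_terms_keep_declaration_order(self):
        d = bbd13()
        y = 1.0 + 0.2 * d.coded[:, 0] * d.coded[:, 1] + 0.2 * d.coded[:, 0] * d.coded[:, 2]
        fit = QuadraticResponseSurface().fit(d.coded, y, feature_names=d.factor_names)
        ranks = fit.rank_effects()
        assert ranks["interaction"][:2] == ["x1:x2", "x1:x3"]


def test_term_name_ordering():
    names = quadratic_terms(3, ["a", "b", "c"])
    assert names == ["a", "b", "c", "a:b", "a:c", "b:c", "a^2", "b^2", "c^2"]
    pairs = list(itertools.combinations(range(3), 2))
    assert len(pairs) == 3
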