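"""First-order screening fit, ANOVA, and factor selection."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate, stats

from rsmferm import (
    FirstOrderScreening,
    fit_first_order,
    plackett_burman,
    protein_content,
    select_factors,
)
from rsmferm.design import DesignMatrix, ResponseSet


@pytest.fixture(scope="module")
def pb12():
    return plackett_burman(6, 12)


class TestFitGoldenValues:
    """The published 12-run screening experiment, recomputed from its table."""

    def test_fitted_equation_coefficients(self, pb_fit):
        assert pb_fit.intercept_ == pytest.approx(1.64, abs=5e-3)
        coefs = dict(zip(pb_fit.feature_names_in_, pb_fit.coef_))
        assert coefs["beef_broth"] == pytest.approx(-0.0608, abs=5e-5)
        assert coefs["peptone"] == pytest.approx(0.0925, abs=5e-5)
        assert coefs["yeast_extract"] == pytest.approx(-0.0142, abs=5e-5)
        assert coefs["glucose"] == pytest.approx(-0.0808, abs=5e-5)
        assert coefs["KH2PO4"] == pytest.approx(-0.0025, abs=5e-5)
        assert coefs["MgSO4"] == pytest.approx(0.0158, abs=5e-5)

    def test_anova_table(self, pb_fit):
        a = pb_fit.anova_
        expected = {
            "beef_broth": (0.0444, 17.47, 0.0087),
            "peptone": (0.1027, 40.40, 0.0014),
            "yeast_extract": (0.0024, 0.95, 0.3751),
            "glucose": (0.0784, 30.85, 0.0026),
            "KH2PO4": (0.0001, 0.03, 0.8703),
            "MgSO4": (0.0030, 1.18, 0.3263),
        }
        for name, (ss, F, p) in expected.items():
            assert a.loc[name, "sum_sq"] == pytest.approx(ss, abs=5e-5)
            assert a.loc[name, "F"] == pytest.approx(F, abs=5e-2)
            assert a.loc[name, "p"] == pytest.approx(p, abs=5e-5)
            assert a.loc[name, "df"] == 1
        assert a.loc["Residual", "df"] == 5

    def test_goodness_of_fit(self, pb_fit):
        assert pb_fit.r2_adj_ == pytest.approx(0.8853, abs=5e-5)
        assert pb_fit.r2_adj_ <= pb_fit.r2_ <= 1

    def test_predicted_and_residual_columns(self, pb_data, pb_fit):
        _, responses = pb_data
        predicted = np.round(pb_fit.fitted_values_, 2)
        residual = np.round(responses.mean - pb_fit.fitted_values_, 2)
        np.testing.assert_allclose(
            predicted,
            [1.73, 1.41, 1.62, 1.69, 1.57, 1.38, 1.88, 1.56, 1.69, 1.79, 1.69, 1.71],
        )
        np.testing.assert_allclose(
            residual,
            [0.02, 0.02, -0.01, -0.05, -0.03, 0.02, 0.05, 0.02, -0.06, -0.02, 0.03, 0.02],
        )

    def test_predictions_reconstruct_responses(self, pb_data, pb_fit):
        _, responses = pb_data
        np.testing.assert_allclose(
            pb_fit.fitted_values_ + pb_fit.residuals_, responses.mean, atol=1e-12
        )


class TestFitProperties:
    def test_constant_response(self, pb12):
        y = np.full(12, 1.5)
        fit = FirstOrderScreening().fit(pb12.coded, y)
        assert fit.intercept_ == pytest.approx(1.5)
        np.testing.assert_allclose(fit.coef_, 0, atol=1e-12)
        assert fit.residual_ss_ == pytest.approx(0, abs=1e-20)

    @given(st.lists(st.floats(0.1, 5.0), min_size=12, max_size=12))
    @settings(max_examples=100, derandomize=True)
    def test_ols_equals_contrast_formula(self, pb12, ys):
        """On an orthogonal +/-1 design, OLS == sum(x*y)/n per factor."""
        y = np.asarray(ys)
        fit = FirstOrderScreening().fit(pb12.coded, y)
        contrast = pb12.coded.T @ y / 12.0
        np.testing.assert_allclose(fit.coef_, contrast, atol=1e-10)
        assert fit.intercept_ == pytest.approx(y.mean(), abs=1e-10)

    @given(st.lists(st.floats(0.1, 5.0), min_size=12, max_size=12))
    @settings(max_examples=100, derandomize=True)
    def test_ss_conservation(self, pb12, ys):
        y = np.asarray(ys)
        fit = FirstOrderScreening().fit(pb12.coded, y)
        ss_terms = fit.anova_.loc[fit.feature_names_in_, "sum_sq"].sum()
        total = fit.total_ss_
        assert ss_terms + fit.residual_ss_ == pytest.approx(total, rel=1e-9, abs=1e-12)

    def test_permutation_invariance(self, pb12, rng):
        y = rng.normal(2.0, 0.1, 12)
        fit = FirstOrderScreening().fit(pb12.coded, y)
        perm = rng.permutation(12)
        fit_p = FirstOrderScreening().fit(pb12.coded[perm], y[perm])
        np.testing.assert_allclose(fit.coef_, fit_p.coef_, atol=1e-12)
        np.testing.assert_allclose(
            fit.anova_["sum_sq"].to_numpy(), fit_p.anova_["sum_sq"].to_numpy(), atol=1e-12
        )

    def test_matches_statsmodels(self, pb_data):
        import statsmodels.api as sm

        design, responses = pb_data
        ols = sm.OLS(responses.mean, sm.add_constant(design.coded)).fit()
        fit = fit_first_order(design, responses)
        np.testing.assert_allclose(fit.intercept_, ols.params[0], atol=1e-10)
        np.testing.assert_allclose(fit.coef_, ols.params[1:], atol=1e-10)
        assert fit.r2_adj_ == pytest.approx(ols.rsquared_adj, abs=1e-10)

    def test_p_value_matches_quadrature_of_f_density(self, pb_fit):
        """Upper-tail probabilities agree with numeric integration of F(1,5)."""
        F = float(pb_fit.anova_.loc["beef_broth", "F"])
        dens = stats.f(1, 5).pdf
        tail, _ = integrate.quad(dens, F, np.inf)
        assert pb_fit.anova_.loc["beef_broth", "p"] == pytest.approx(tail, rel=1e-6)

    def test_zero_effect_factor_has_unit_p(self):
        # noiseless response depending only on column 0: the null factor
        # gets SS = 0, F = 0, p = 1 even though MS_residual is also zero
        d = plackett_burman(2, 8)
        y = 1.0 + 0.5 * d.coded[:, 0]
        fit = FirstOrderScreening().fit(d.coded, y)
        assert fit.coef_[1] == pytest.approx(0.0, abs=1e-12)
        assert fit.anova_.iloc[1]["sum_sq"] == pytest.approx(0.0, abs=1e-12)
        assert fit.anova_.iloc[1]["F"] == 0.0
        assert fit.anova_.iloc[1]["p"] == 1.0
        assert fit.anova_.iloc[0]["p"] == 0.0

    def test_rank_deficiency_names_aliased_columns(self):
        X = np.array([[1, 1], [1, 1], [-1, -1], [-1, -1], [1, 1], [-1, -1]], float)
        with pytest.raises(ValueError, match="aliased"):
            FirstOrderScreening().fit(X, np.arange(6.0), feature_names=["a", "b"])

    def test_center_runs_rejected(self, bbd_data):
        design, responses = bbd_data
        with pytest.raises(ValueError, match="center"):
            fit_first_order(design, responses)


class TestContribution:
    def test_shares_sum_to_100(self, pb_fit):
        assert pb_fit.contribution_rates().sum() == pytest.approx(100.0, abs=1e-9)

    def test_peptone_dominates(self, pb_fit):
        factors = pb_fit.contribution_rates().drop("Residual")
        assert factors.idxmax() == "peptone"

    def test_single_factor_zero_noise_is_total(self):
        d = plackett_burman(1, 8)
        y = 2.0 + 0.3 * d.coded[:, 0]
        fit = FirstOrderScreening().fit(d.coded, y)
        assert fit.contribution_rates()["X1"] == pytest.approx(100.0, abs=1e-9)


class TestSelection:
    def test_published_selection_at_005(self, pb_fit):
        sel = select_factors(pb_fit, alpha=0.05)
        chosen = set(sel.index[sel["selected"]])
        assert chosen == {"beef_broth", "peptone", "glucose"}
        assert sel.loc["beef_broth", "sign"] == "-"
        assert sel.loc["peptone", "sign"] == "+"
        assert sel.loc["glucose", "sign"] == "-"
        assert "fix" in sel.loc["yeast_extract", "recommendation"]

    def test_alpha_one_selects_everything(self, pb_fit):
        sel = select_factors(pb_fit, alpha=1.0)
        assert sel["selected"].all()

    def test_strict_alpha_selects_nothing(self, pb_fit):
        sel = select_factors(pb_fit, alpha=0.001)
        assert not sel["selected"].any()


class TestProteinContent:
    @pytest.mark.parametrize(
        "c, v, m, expected",
        [(2.0, 1.0, 100.0, 2.0), (0.0, 5.0, 50.0, 0.0), (1.055, 2.0, 100.0, 2.11)],
    )
    def test_values(self, c, v, m, expected):
        assert protein_content(c, v, m) == pytest.approx(expected)

    def test_zero_mass_rejected(self):
        with pytest.raises(ValueError, match="mass"):
            protein_content(1.0, 1.0, 0.0)
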