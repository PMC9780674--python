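"""First-order (main-effects) screening model for Plackett-Burman data.

The model is Y = b0 + sum_i b_i x_i over coded +/-1 factor levels, fitted by
ordinary least squares to the per-run mean responses.  On an orthogonal
two-level design the OLS coefficients coincide with the classical contrast
estimates sum(x_ri * y_r) / n_runs, and each factor's single-degree-of-
freedom sum of squares reduces to n_runs * b_i**2; both identities are
exploited as invariants in the test-suite but the implementation uses the
general least-squares forms so that user-supplied (possibly non-ideal)
matrices are handled correctly.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .design import DesignMatrix, ResponseSet

__all__ = [
    "FirstOrderScreening",
    "fit_first_order",
    "select_factors",
    "contribution_rates",
    "protein_content",
    "significance_flag",
]


def significance_flag(p: float) -> str:
    """Table-style significance marker: ``**`` p<0.01, ``*`` p<0.05."""
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def _term_f_p(ss_terms: np.ndarray, ms_resid: float, df_resid: int, tol: float = 0.0):
    """Per-term F statistics and upper-tail p-values against MS_residual.

    Degenerate noiseless case (MS_residual below ``tol``, the numerical
    zero for the problem's SS scale): a term with zero SS has F = 0,
    p = 1; a term with positive SS has F = inf, p = 0.
    """
    ss_terms = np.asarray(ss_terms, dtype=float)
    if ms_resid > tol:
        F = ss_terms / ms_resid
    else:
        F = np.where(ss_terms > tol, np.inf, 0.0)
    p = stats.f.sf(F, 1, df_resid)
    return F, p


def _ss_zero_tol(ss_total: float) -> float:
    """Numerical zero for sums of squares at this response scale."""
    return 1e-12 * max(ss_total, 1e-30)


class FirstOrderScreening(RegressorMixin, BaseEstimator):
    """OLS main-effects screening model over coded factor levels.

    Fits ``y = intercept_ + X @ coef_`` and computes the per-factor ANOVA
    (single-df Type III sums of squares, F against the regression residual,
    upper-tail p from F(1, df_resid)) plus contribution rates
    ``100 * SS_i / SS_total``.

    Attributes
    ----------
    intercept_ : float
    coef_ : ndarray of shape (n_factors,)
        Effects per coded unit.
    anova_ : DataFrame
        One row per factor plus Residual and Total rows; columns
        ``sum_sq, df, mean_sq, F, p, signif``.
    contribution_ : Series
        Percent of total SS per factor plus a residual share; sums to 100.
    r2_, r2_adj_ : float
    fitted_values_, residuals_ : ndarray
    """

    def __init__(self):
        pass

    def fit(self, X, y, feature_names: list[str] | None = None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if X.ndim != 2:
            raise ValueError("X must be 2-D (runs x factors)")
        n, k = X.shape
        if len(y) != n:
            raise ValueError(f"X has {n} runs but y has {len(y)} responses")
        if n <= k + 1:
            raise ValueError(
                f"need more runs ({n}) than fitted terms ({k + 1}); "
                "use a larger design or fewer factors"
            )
        if feature_names is None:
            feature_names = [f"X{j + 1}" for j in range(k)]
        self.feature_names_in_ = list(feature_names)

        M = np.column_stack([np.ones(n), X])
        rank = np.linalg.matrix_rank(M)
        if rank < k + 1:
            aliased = [
                feature_names[j - 1]
                for j in range(1, k + 1)
                if np.linalg.matrix_rank(np.delete(M, j, axis=1)) == rank
            ]
            raise ValueError(f"model matrix is rank-deficient; aliased columns: {aliased}")

        beta, *_ = np.linalg.lstsq(M, y, rcond=None)
        self.intercept_ = float(beta[0])
        self.coef_ = beta[1:]
        self.fitted_values_ = M @ beta
        self.residuals_ = y - self.fitted_values_

        ss_resid = float(self.residuals_ @ self.residuals_)
        ss_total = float(np.sum((y - y.mean()) ** 2))
        df_resid = n - (k + 1)
        # Type III single-df SS: b_j^2 / [(M'M)^{-1}]_{jj}; equals n*b_j^2
        # on an orthogonal two-level design.
        cinv = np.linalg.inv(M.T @ M)
        ss_terms = self.coef_ ** 2 / np.diag(cinv)[1:]
        ms_resid = ss_resid / df_resid if df_resid > 0 else 0.0
        F, p = _term_f_p(ss_terms, ms_resid, df_resid, tol=_ss_zero_tol(ss_total))

        rows = []
        for name, ss, Fi, pi in zip(feature_names, ss_terms, F, p):
            rows.append(
                {"source": name, "sum_sq": ss, "df": 1, "mean_sq": ss,
                 "F": Fi, "p": pi, "signif": significance_flag(pi)}
            )
        rows.append({"source": "Residual", "sum_sq": ss_resid, "df": df_resid,
                     "mean_sq": ms_resid, "F": np.nan, "p": np.nan, "signif": ""})
        rows.append({"source": "Total", "sum_sq": ss_total, "df": n - 1,
                     "mean_sq": np.nan, "F": np.nan, "p": np.nan, "signif": ""})
        self.anova_ = pd.DataFrame(rows).set_index("source")

        self.residual_ss_ = ss_resid
        self.residual_df_ = df_resid
        self.total_ss_ = ss_total
        self.r2_ = 1.0 - ss_resid / ss_total if ss_total > 0 else 1.0
        self.r2_adj_ = (
            1.0 - (ss_resid / df_resid) / (ss_total / (n - 1))
            if ss_total > 0 and df_resid > 0
            else self.r2_
        )
        if ss_total > 0:
            contrib = {name: 100.0 * ss / ss_total for name, ss in zip(feature_names, ss_terms)}
            contrib["Residual"] = 100.0 * ss_resid / ss_total
            self.contribution_ = pd.Series(contrib, name="contribution_pct")
        else:
            self.contribution_ = None
        self.n_runs_ = n
        return self

    def predict(self, X):
        check_is_fitted(self, "coef_")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != len(self.coef_):
            raise ValueError(f"expected {len(self.coef_)} factor columns, got {X.shape[1]}")
        return self.intercept_ + X @ self.coef_

    def contribution_rates(self) -> pd.Series:
        """Percent of total SS per factor (plus residual share); sums to 100."""
        check_is_fitted(self, "coef_")
        if self.contribution_ is None:
            raise ValueError("total SS is zero; contribution rates undefined")
        return self.contribution_

    def select(self, alpha: float = 0.05) -> pd.DataFrame:
        """Significant factors at level ``alpha`` with recommended direction.

        A selected factor with a positive effect is recommended for an
        increased level, a negative effect for a decreased level;
        non-selected factors are recommended to be fixed at their current
        level.
        """
        check_is_fitted(self, "anova_")
        if not 0 < alpha <= 1:
            raise ValueError(f"alpha must be in (0, 1], got {alpha}")
        rows = []
        for j, name in enumerate(self.feature_names_in_):
            p = float(self.anova_.loc[name, "p"])
            coef = float(self.coef_[j])
            selected = p < alpha
            if selected:
                sign = "+" if coef > 0 else "-"
                rec = (
                    f"increase {name} (positive effect)"
                    if coef > 0
                    else f"decrease {name} (negative effect)"
                )
            else:
                sign, rec = "", f"fix {name} at current level"
            rows.append(
                {"factor": name, "coef": coef, "p": p, "selected": selected,
                 "sign": sign, "recommendation": rec}
            )
        return pd.DataFrame(rows).set_index("factor")


def fit_first_order(design: DesignMatrix, responses: ResponseSet) -> FirstOrderScreening:
    """Fit the screening model to a design and its paired responses.

    Responses are aligned to the design by run label.  Center runs are not
    permitted: a two-level screening design has no coded-0 settings.
    """
    if np.any(design.center_flags):
        raise ValueError("screening fit requires a two-level design without center runs")
    y = responses.aligned_to(design)
    model = FirstOrderScreening()
    return model.fit(design.coded, y, feature_names=design.factor_names)


def select_factors(fit: FirstOrderScreening, alpha: float = 0.05) -> pd.DataFrame:
    """Functional wrapper over :meth:`FirstOrderScreening.select`."""
    return fit.select(alpha)


def contribution_rates(fit: FirstOrderScreening) -> pd.Series:
    """Functional wrapper over :meth:`FirstOrderScreening.contribution_rates`."""
    return fit.contribution_rates()


def protein_content(concentration_mg_ml: float, volume_ml: float, mass_mg: float) -> float:
    """Mycelial soluble protein content in percent: 100 * C * V / M.

    Parameters are the Bradford-assay protein concentration C (mg/mL), the
    extract volume V (mL) and the dry mycelium mass M (mg).
    """
    if mass_mg <= 0:
        raise ValueError(f"mycelium mass must be > 0 mg, got {mass_mg}")
    if concentration_mg_ml < 0 or volume_ml < 0:
        raise ValueError("concentration and volume must be non-negative")
    return 100.0 * concentration_mg_ml * volume_ml / mass_mg
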