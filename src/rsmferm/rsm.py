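"""Second-order response-surface model for Box-Behnken data.

Fits the full quadratic

    Y = b0 + sum b_i x_i + sum_{i<j} b_ij x_i x_j + sum b_ii x_i^2

by unweighted OLS on per-run mean responses, and decomposes the ANOVA the
way response-surface software reports it: single-df Type III sums of
squares per term (for the linear and interaction columns of a Box-Behnken
design these coincide with the orthogonal-contrast SS; the quadratic
columns are mutually correlated, and the drop-one SS is what standard RSM
tables print), model SS as total minus residual, and the residual split
into lack of fit and pure error from the replicated center runs.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .design import DesignMatrix, ResponseSet
from .screening import _ss_zero_tol, _term_f_p, significance_flag

__all__ = ["QuadraticResponseSurface", "fit_quadratic", "rank_effects", "quadratic_terms"]


def quadratic_terms(n_factors: int, names: list[str] | None = None):
    """Term labels of the full quadratic basis (excluding the intercept).

    Order: linear, then interactions (i<j in declaration order), then pure
    quadratics; e.g. for 3 factors ``X1, X2, X3, X1:X2, X1:X3, X2:X3,
    X1^2, X2^2, X3^2``.
    """
    if names is None:
        names = [f"X{j + 1}" for j in range(n_factors)]
    inter = [f"{names[i]}:{names[j]}" for i, j in itertools.combinations(range(n_factors), 2)]
    quad = [f"{n}^2" for n in names]
    return list(names) + inter + quad


def _expand(X: np.ndarray) -> np.ndarray:
    """Column-expand coded factors into the quadratic basis (no intercept)."""
    n, k = X.shape
    cols = [X]
    cols.append(
        np.column_stack([X[:, i] * X[:, j] for i, j in itertools.combinations(range(k), 2)])
        if k >= 2
        else np.empty((n, 0))
    )
    cols.append(X**2)
    return np.column_stack(cols)


class QuadraticResponseSurface(RegressorMixin, BaseEstimator):
    """Full second-order polynomial response surface fitted by OLS.

    Attributes
    ----------
    intercept_ : float
    coef_ : ndarray
        All non-intercept coefficients in :func:`quadratic_terms` order.
    coef_linear_, coef_interaction_, coef_quadratic_ : Series
        The same coefficients grouped by term type.
    anova_ : DataFrame
        Rows Model, each term, Residual, Lack of fit, Pure error,
        Cor total; columns ``sum_sq, df, mean_sq, F, p, signif``.
    r2_, r2_adj_, cv_percent_ : float
    fitted_values_, residuals_ : ndarray
    cov_params_ : ndarray
        OLS covariance of (intercept, coef_) based on MS_residual; used
        for coefficient confidence intervals.
    lack_of_fit_warning_ : bool
        True when fewer than 2 center replicates prevented the lack-of-fit
        split (those ANOVA rows are then omitted).
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
        n_terms = 1 + k + k * (k - 1) // 2 + k
        if n < n_terms + 1:
            raise ValueError(
                f"need at least {n_terms + 1} runs for the {n_terms}-term quadratic, got {n}"
            )
        if feature_names is None:
            feature_names = [f"X{j + 1}" for j in range(k)]
        self.feature_names_in_ = list(feature_names)
        self.n_factors_ = k
        self.term_names_ = quadratic_terms(k, list(feature_names))

        Z = _expand(X)
        M = np.column_stack([np.ones(n), Z])
        if np.linalg.matrix_rank(M) < M.shape[1]:
            raise ValueError("expanded quadratic model matrix is rank-deficient")

        beta, *_ = np.linalg.lstsq(M, y, rcond=None)
        self.intercept_ = float(beta[0])
        self.coef_ = beta[1:]
        self.coef_linear_ = pd.Series(self.coef_[:k], index=self.term_names_[:k])
        n_int = k * (k - 1) // 2
        self.coef_interaction_ = pd.Series(
            self.coef_[k : k + n_int], index=self.term_names_[k : k + n_int]
        )
        self.coef_quadratic_ = pd.Series(self.coef_[k + n_int :], index=self.term_names_[k + n_int :])
        self.fitted_values_ = M @ beta
        self.residuals_ = y - self.fitted_values_

        ss_resid = float(self.residuals_ @ self.residuals_)
        ss_total = float(np.sum((y - y.mean()) ** 2))
        ss_model = ss_total - ss_resid
        df_model = n_terms - 1
        df_resid = n - n_terms
        ms_resid = ss_resid / df_resid if df_resid > 0 else 0.0

        cinv = np.linalg.inv(M.T @ M)
        self.cov_params_ = ms_resid * cinv
        tol = _ss_zero_tol(ss_total)
        ss_terms = beta[1:] ** 2 / np.diag(cinv)[1:]
        F_terms, p_terms = _term_f_p(ss_terms, ms_resid, df_resid, tol=tol)
        if ms_resid > tol:
            F_model = (ss_model / df_model) / ms_resid
        else:
            F_model = np.inf if ss_model > tol else 0.0
        p_model = float(stats.f.sf(F_model, df_model, df_resid))

        rows = [
            {"source": "Model", "sum_sq": ss_model, "df": df_model,
             "mean_sq": ss_model / df_model, "F": F_model, "p": p_model,
             "signif": significance_flag(p_model)}
        ]
        for name, ss, Fi, pi in zip(self.term_names_, ss_terms, F_terms, p_terms):
            rows.append({"source": name, "sum_sq": ss, "df": 1, "mean_sq": ss,
                         "F": Fi, "p": pi, "signif": significance_flag(pi)})
        rows.append({"source": "Residual", "sum_sq": ss_resid, "df": df_resid,
                     "mean_sq": ms_resid, "F": np.nan, "p": np.nan, "signif": ""})

        # lack-of-fit / pure-error split from replicated center runs
        center = np.all(X == 0.0, axis=1)
        n_center = int(center.sum())
        self.n_center_ = n_center
        self.lack_of_fit_warning_ = n_center < 2
        if n_center >= 2:
            yc = y[center]
            ss_pe = float(np.sum((yc - yc.mean()) ** 2))
            df_pe = n_center - 1
            ss_lof = ss_resid - ss_pe
            df_lof = df_resid - df_pe
            ms_pe = ss_pe / df_pe
            ms_lof = ss_lof / df_lof if df_lof > 0 else np.nan
            if df_lof > 0:
                if ms_pe > tol:
                    F_lof = ms_lof / ms_pe
                else:
                    F_lof = np.inf if ss_lof > tol else 0.0
                p_lof = float(stats.f.sf(F_lof, df_lof, df_pe))
            else:
                F_lof, p_lof = np.nan, np.nan
            rows.append({"source": "Lack of fit", "sum_sq": ss_lof, "df": df_lof,
                         "mean_sq": ms_lof, "F": F_lof, "p": p_lof,
                         "signif": significance_flag(p_lof) if np.isfinite(p_lof) else ""})
            rows.append({"source": "Pure error", "sum_sq": ss_pe, "df": df_pe,
                         "mean_sq": ms_pe, "F": np.nan, "p": np.nan, "signif": ""})
            self.pure_error_ss_, self.lack_of_fit_ss_ = ss_pe, ss_lof
        rows.append({"source": "Cor total", "sum_sq": ss_total, "df": n - 1,
                     "mean_sq": np.nan, "F": np.nan, "p": np.nan, "signif": ""})
        self.anova_ = pd.DataFrame(rows).set_index("source")

        self.model_ss_ = ss_model
        self.residual_ss_ = ss_resid
        self.residual_df_ = df_resid
        self.total_ss_ = ss_total
        self.r2_ = ss_model / ss_total if ss_total > 0 else 1.0
        self.r2_adj_ = (
            1.0 - (ss_resid / df_resid) / (ss_total / (n - 1))
            if ss_total > 0 and df_resid > 0
            else self.r2_
        )
        ybar = y.mean()
        self.cv_percent_ = 100.0 * np.sqrt(ms_resid) / ybar if ybar != 0 else np.nan
        self.n_runs_ = n
        return self

    def predict(self, X):
        check_is_fitted(self, "coef_")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_factors_:
            raise ValueError(f"expected {self.n_factors_} coordinates, got {X.shape[1]}")
        if not np.all(np.isfinite(X)):
            raise ValueError("prediction points must be finite")
        return self.intercept_ + _expand(X) @ self.coef_

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        """Two-sided (1-alpha) t intervals for intercept and coefficients."""
        check_is_fitted(self, "cov_params_")
        se = np.sqrt(np.diag(self.cov_params_))
        tcrit = stats.t.ppf(1 - alpha / 2, self.residual_df_)
        est = np.concatenate([[self.intercept_], self.coef_])
        idx = ["Intercept"] + self.term_names_
        return pd.DataFrame(
            {"estimate": est, "lower": est - tcrit * se, "upper": est + tcrit * se}, index=idx
        )

    def rank_effects(self) -> dict[str, list[str]]:
        """Linear and interaction terms ordered by descending F.

        Ties (identical SS) keep the factor declaration order, which the
        descending stable sort preserves.
        """
        check_is_fitted(self, "anova_")
        k = self.n_factors_
        lin = self.term_names_[:k]
        inter = self.term_names_[k : k + k * (k - 1) // 2]
        ss = self.anova_["sum_sq"]
        scale = max(float(ss.loc[self.term_names_].max()), 1e-300)

        def order(terms):
            # round away float noise so exact ties keep declaration order
            return sorted(terms, key=lambda t: -round(float(ss.loc[t]) / scale, 10))

        return {"linear": order(lin), "interaction": order(inter)}


def fit_quadratic(design: DesignMatrix, responses: ResponseSet) -> QuadraticResponseSurface:
    """Fit the quadratic surface to a design and its paired responses."""
    y = responses.aligned_to(design)
    model = QuadraticResponseSurface()
    return model.fit(design.coded, y, feature_names=design.factor_names)


def rank_effects(fit: QuadraticResponseSurface) -> dict[str, list[str]]:
    """Functional wrapper over :meth:`QuadraticResponseSurface.rank_effects`."""
    return fit.rank_effects()
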