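"""Logistic GEE with exchangeable working correlation and robust variance.

The working model treats every subject in a cluster (across all periods of
the cross-sectional design) as exchangeable with common pairwise working
correlation alpha, estimated each iteration by the moment method from
standardised Pearson residuals.  Because subjects within a cluster-period
cell share a mean, the subject-level estimating equations collapse exactly
to cell-level sums: with cell residual r_j = y_j - n_j mu_j, cell variance
v_j = mu_j (1 - mu_j) and cluster size m = sum_j n_j,

    D'V^{-1} e = [ sum_j x_j r_j
                   - c (sum_j n_j v_j^{1/2} x_j) (sum_j r_j v_j^{-1/2}) ] / (1-a)
    D'V^{-1} D = [ sum_j n_j v_j x_j x_j'
                   - c (sum_j n_j v_j^{1/2} x_j)(...)' ] / (1-a),

with c = a / (1 - a + a m).  The intervention effect is a marginal
(population-average) log odds ratio; a marginal-to-conditional conversion
beta1/(1 - rho) is reported alongside for comparison with cluster-specific
models.  P-values compare the Wald statistic against the standard normal;
the default standard error is the model-based (working-covariance) one,
with the Liang-Zeger sandwich available — both covariance matrices are
always computed.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit
from sklearn.base import BaseEstimator

from .base import (
    FitResult,
    as_cells,
    build_design,
    marginal_to_conditional,
    wald_test,
)
from .glm import SEPARATION_BOUND, fit_binomial_irls


def _cluster_slices(cells):
    clusters = cells["cluster"].to_numpy()
    _, starts = np.unique(clusters, return_index=True)
    bounds = np.append(np.sort(starts), len(clusters))
    return [slice(bounds[i], bounds[i + 1]) for i in range(len(bounds) - 1)]


def _alpha_moment(slices, events, n, mu, n_params):
    """Moment estimator of the exchangeable working correlation.

    Sum of products of standardised Pearson residuals over all distinct
    subject pairs within clusters, divided by the bias-adjusted denominator
    phi * (total pair count - p).
    """
    v = mu * (1 - mu)
    r = events - n * mu
    # per-cell sums of subject residuals and squared residuals
    s1 = r / np.sqrt(v)
    s2 = (events * (1 - mu) ** 2 + (n - events) * mu**2) / v
    phi = s2.sum() / (n.sum() - n_params)
    pair_sum = 0.0
    n_pairs = 0.0
    for sl in slices:
        tot = s1[sl].sum()
        pair_sum += 0.5 * (tot**2 - s2[sl].sum())
        m = n[sl].sum()
        n_pairs += 0.5 * m * (m - 1)
    return pair_sum / (phi * (n_pairs - n_params)), phi


class ExchangeableLogisticGEE(BaseEstimator):
    """Population-average logistic regression for clustered binary data.

    Parameters
    ----------
    time_adjustment : {"none", "linear", "categorical"}
    conversion_icc : float or None
        ICC used in the marginal-to-conditional conversion
        beta1* = beta1/(1 - rho). In a simulation the known design ICC is
        the natural choice; with None the estimated working correlation
        alpha is used instead (the real-data option).
    working_alpha : float or None
        Fix the working correlation instead of estimating it; 0.0 gives
        the independence GEE (whose point estimates equal ordinary
        logistic maximum likelihood).
    variance_estimator : {"model", "robust"}
        Standard error used for the Wald test. "model" is the
        working-covariance (model-based) variance; "robust" the
        Liang-Zeger sandwich. Both covariance matrices are always
        computed and exposed as ``model_cov_`` and ``robust_cov_``.
    max_iter, tol : quasi-score iteration controls.

    Attributes
    ----------
    effect_ : marginal intervention log odds ratio.
    effect_conditional_ : converted cluster-specific log odds ratio.
    se_ : robust (sandwich) standard error.
    alpha_ : estimated working correlation.
    """

    method_name = "gee"
    scale = "log-odds"

    def __init__(self, time_adjustment: str = "linear",
                 conversion_icc: float | None = None,
                 working_alpha: float | None = None,
                 variance_estimator: str = "model",
                 max_iter: int = 100, tol: float = 1e-8):
        self.time_adjustment = time_adjustment
        self.conversion_icc = conversion_icc
        self.working_alpha = working_alpha
        self.variance_estimator = variance_estimator
        self.max_iter = max_iter
        self.tol = tol

    def _fail(self, message, names, n_obs):
        self.feature_names_ = names
        self.coef_ = None
        self.effect_ = np.nan
        self.effect_conditional_ = np.nan
        self.se_ = np.nan
        self.alpha_ = np.nan
        self.df_ = np.inf
        self.p_value_ = np.nan
        self.converged_ = False
        self.message_ = message
        self.n_obs_ = n_obs
        return self

    @staticmethod
    def _assemble(x, events, n, mu, alpha, slices):
        """Cell-level collapse of the subject-level exchangeable GEE sums."""
        v = mu * (1 - mu)
        r = events - n * mu
        p = x.shape[1]
        score = np.zeros(p)
        bread = np.zeros((p, p))
        meat = np.zeros((p, p))
        one_minus = 1.0 - alpha
        for sl in slices:
            xk, nk, vk, rk = x[sl], n[sl], v[sl], r[sl]
            m = nk.sum()
            c = alpha / (one_minus + alpha * m)
            sqv = np.sqrt(vk)
            a_vec = (nk * sqv) @ xk          # sum_j n_j v_j^{1/2} x_j
            b_scal = (rk / sqv).sum()        # sum_j r_j v_j^{-1/2}
            uk = (xk.T @ rk - c * a_vec * b_scal) / one_minus
            bk = ((xk * (nk * vk)[:, None]).T @ xk
                  - c * np.outer(a_vec, a_vec)) / one_minus
            score += uk
            bread += bk
            meat += np.outer(uk, uk)
        return score, bread, meat

    def fit(self, data, y=None):
        cells = as_cells(data)
        x, names = build_design(cells, self.time_adjustment)
        events = cells["events"].to_numpy(float)
        n = cells["n"].to_numpy(float)
        n_obs = int(n.sum())
        idx = names.index("treatment")
        slices = _cluster_slices(cells)
        max_m = max(n[sl].sum() for sl in slices)
        alpha_lo = -1.0 / (max_m - 1.0) if max_m > 1 else -1.0

        start = fit_binomial_irls(x, events, n)
        if not start.converged:
            return self._fail("initial independence fit failed: " + start.message,
                              names, n_obs)
        beta = start.beta.copy()
        alpha = 0.0
        converged = False
        for _ in range(self.max_iter):
            mu = expit(x @ beta)
            if self.working_alpha is None:
                alpha, _ = _alpha_moment(slices, events, n, mu, x.shape[1])
            else:
                alpha = float(self.working_alpha)
            if not (alpha_lo < alpha < 1.0) and alpha != 0.0:
                return self._fail(
                    f"working correlation {alpha:.4f} left "
                    f"({alpha_lo:.4f}, 1)", names, n_obs)
            score, bread, _ = self._assemble(x, events, n, mu, alpha, slices)
            try:
                step = np.linalg.solve(bread, score)
            except np.linalg.LinAlgError:
                return self._fail("singular bread matrix", names, n_obs)
            beta = beta + step
            if np.max(np.abs(beta)) > SEPARATION_BOUND:
                return self._fail("separation: coefficient diverged", names, n_obs)
            if np.max(np.abs(step)) < self.tol * (1.0 + np.max(np.abs(beta))):
                converged = True
                break
        if not converged:
            return self._fail("quasi-score iteration did not converge",
                              names, n_obs)

        mu = expit(x @ beta)
        _, bread, meat = self._assemble(x, events, n, mu, alpha, slices)
        try:
            bread_inv = np.linalg.inv(bread)
        except np.linalg.LinAlgError:
            return self._fail("singular bread matrix at solution", names, n_obs)
        robust_cov = bread_inv @ meat @ bread_inv
        if self.variance_estimator == "robust":
            var = robust_cov[idx, idx]
        elif self.variance_estimator == "model":
            var = bread_inv[idx, idx]
        else:
            raise ValueError("variance_estimator must be 'model' or 'robust'")
        if not np.isfinite(var) or var <= 0:
            return self._fail("non-positive effect variance", names, n_obs)

        rho = self.conversion_icc if self.conversion_icc is not None else max(alpha, 0.0)
        self.feature_names_ = names
        self.coef_ = beta
        self.robust_cov_ = robust_cov
        self.model_cov_ = bread_inv
        self.alpha_ = float(alpha)
        self.effect_ = float(beta[idx])
        self.effect_conditional_ = marginal_to_conditional(self.effect_, rho)
        self.se_ = float(np.sqrt(var))
        self.df_ = np.inf
        self.p_value_ = wald_test(self.effect_, self.se_, "normal")
        self.converged_ = True
        self.message_ = ""
        self.n_obs_ = n_obs
        return self

    def to_result(self) -> FitResult:
        return FitResult(
            method=self.method_name,
            estimate=self.effect_,
            scale=self.scale,
            se=self.se_,
            df=self.df_,
            p_value=self.p_value_,
            converged=self.converged_,
            estimate_conditional=self.effect_conditional_,
            time_adjustment=self.time_adjustment,
            n_obs=self.n_obs_,
            message=self.message_,
        )
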