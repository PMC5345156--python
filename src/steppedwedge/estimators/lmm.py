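"""Cluster-summary analysis: a linear mixed model on cell proportions.

Each cluster-period proportion pi_jk = events/n is modelled as

    pi_jk = beta0 + a_0k + beta1 * X_jk + time terms + e_jk,

with a_0k ~ N(0, sigma_u^2) and e_jk ~ N(0, sigma_e^2), fitted by REML.
Cells are unweighted (one row each), so beta1 is an intervention-effect
risk difference.  The REML criterion is profiled: for a given variance
ratio lambda = sigma_u^2/sigma_e^2 the scaled covariance V0 = I + lambda
Z Z' is block diagonal with closed-form inverse and determinant per
cluster, leaving a one-dimensional optimisation over log(lambda).
Inference is a Wald t-test with containment degrees of freedom
(cells minus rank of the combined fixed + random design).
"""

from __future__ import annotations

import numpy as np
from scipy import optimize
from sklearn.base import BaseEstimator

from .base import FitResult, as_cells, build_design, containment_df, wald_test

_LOG_LAMBDA_LO, _LOG_LAMBDA_HI = -14.0, 14.0


def _profiled_reml(log_lambda, x, y, slices):
    """GLS quantities at variance ratio lambda, profiled over sigma_e^2.

    Returns (criterion, beta, xtvx_inv, sigma_e2) where criterion is the
    -2 REML log-likelihood up to a constant.
    """
    lam = np.exp(log_lambda)
    p = x.shape[1]
    nobs = len(y)
    xtvx = np.zeros((p, p))
    xtvy = np.zeros(p)
    logdet_v0 = 0.0
    for sl in slices:
        xk, yk = x[sl], y[sl]
        m = len(yk)
        shrink = lam / (1.0 + lam * m)
        sx = xk.sum(axis=0)
        sy = yk.sum()
        xtvx += xk.T @ xk - shrink * np.outer(sx, sx)
        xtvy += xk.T @ yk - shrink * sx * sy
        logdet_v0 += np.log1p(lam * m)
    try:
        chol = np.linalg.cholesky(xtvx)
    except np.linalg.LinAlgError:
        return np.inf, None, None, np.nan
    beta = np.linalg.solve(xtvx, xtvy)
    rss = 0.0
    for sl in slices:
        rk = y[sl] - x[sl] @ beta
        m = len(rk)
        shrink = lam / (1.0 + lam * m)
        rss += rk @ rk - shrink * rk.sum() ** 2
    sigma_e2 = rss / (nobs - p)
    logdet_xtvx = 2.0 * np.log(np.diag(chol)).sum()
    if sigma_e2 <= 0:
        return np.inf, beta, None, 0.0
    crit = (nobs - p) * np.log(sigma_e2) + logdet_v0 + logdet_xtvx
    xtvx_inv = np.linalg.inv(xtvx)
    return crit, beta, xtvx_inv, sigma_e2


def reml_loglik(crit_parts, nobs, p):
    """Full REML log-likelihood from the profiled criterion pieces."""
    crit, sigma_e2 = crit_parts
    return -0.5 * (crit + (nobs - p) * (1.0 + np.log(2.0 * np.pi)))


class ClusterSummaryLMM(BaseEstimator):
    """Linear mixed model on cluster-period event proportions.

    Parameters
    ----------
    time_adjustment : {"none", "linear", "categorical"}

    Attributes
    ----------
    effect_ : float
        Intervention-effect risk difference.
    se_ : float
        Model-based GLS standard error.
    sigma_u_, sigma_e_ : float
        REML random-intercept and residual standard deviations.
    df_ : float
        Containment degrees of freedom.
    """

    method_name = "cluster_summaries"
    scale = "risk-difference"

    def __init__(self, time_adjustment: str = "linear"):
        self.time_adjustment = time_adjustment

    def _fail(self, message, names, n_cells, df):
        self.feature_names_ = names
        self.coef_ = None
        self.effect_ = np.nan
        self.se_ = np.nan
        self.sigma_u_ = np.nan
        self.sigma_e_ = np.nan
        self.loglik_ = np.nan
        self.df_ = df
        self.p_value_ = np.nan
        self.converged_ = False
        self.message_ = message
        self.n_obs_ = n_cells
        return self

    def fit(self, data, y=None):
        cells = as_cells(data)
        x, names = build_design(cells, self.time_adjustment)
        pi = (cells["events"] / cells["n"]).to_numpy(float)
        clusters = cells["cluster"].to_numpy()
        _, starts = np.unique(clusters, return_index=True)
        bounds = np.append(np.sort(starts), len(clusters))
        slices = [slice(bounds[i], bounds[i + 1]) for i in range(len(bounds) - 1)]
        idx = names.index("treatment")
        n_cells = len(cells)
        df = containment_df(cells, self.time_adjustment, per_subject=False)

        # degenerate constant response: exact zero variance solution
        if np.ptp(pi) < 1e-12:
            beta = np.zeros(x.shape[1])
            beta[0] = pi[0]
            self.feature_names_ = names
            self.coef_ = beta
            self.effect_ = 0.0
            self.se_ = 0.0
            self.sigma_u_ = 0.0
            self.sigma_e_ = 0.0
            self.loglik_ = np.inf
            self.df_ = df
            self.p_value_ = np.nan
            self.converged_ = True
            self.message_ = "constant response"
            self.n_obs_ = n_cells
            return self

        res = optimize.minimize_scalar(
            lambda ll: _profiled_reml(ll, x, pi, slices)[0],
            bounds=(_LOG_LAMBDA_LO, _LOG_LAMBDA_HI),
            method="bounded",
            options={"xatol": 1e-10},
        )
        log_lambda = res.x
        crit, beta, xtvx_inv, sigma_e2 = _profiled_reml(log_lambda, x, pi, slices)
        # compare against the boundary lambda = 0 (no cluster variance)
        crit0, beta0, xtvx_inv0, sigma_e20 = _profiled_reml(-np.inf, x, pi, slices)
        if crit0 <= crit or log_lambda <= _LOG_LAMBDA_LO + 1e-6:
            log_lambda, crit, beta, xtvx_inv, sigma_e2 = (
                -np.inf, crit0, beta0, xtvx_inv0, sigma_e20)
        if beta is None or xtvx_inv is None or not np.isfinite(crit):
            return self._fail("non-positive-definite profiled covariance",
                              names, n_cells, df)

        lam = np.exp(log_lambda) if np.isfinite(log_lambda) else 0.0
        var = sigma_e2 * xtvx_inv[idx, idx]
        if not np.isfinite(var) or var < 0:
            return self._fail("non-positive effect variance", names, n_cells, df)

        self.feature_names_ = names
        self.coef_ = beta
        self.cov_ = sigma_e2 * xtvx_inv
        self.effect_ = float(beta[idx])
        self.se_ = float(np.sqrt(var))
        self.sigma_u_ = float(np.sqrt(lam * sigma_e2))
        self.sigma_e_ = float(np.sqrt(sigma_e2))
        self.loglik_ = reml_loglik((crit, sigma_e2), n_cells, x.shape[1])
        self.df_ = df
        self.p_value_ = wald_test(self.effect_, self.se_, "t", df=self.df_)
        self.converged_ = True
        self.message_ = ""
        self.n_obs_ = n_cells
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
            sigma_u=self.sigma_u_ if self.converged_ else None,
            time_adjustment=self.time_adjustment,
            n_obs=self.n_obs_,
            message=self.message_,
        )
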