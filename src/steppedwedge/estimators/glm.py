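"""Binomial logistic regression by IRLS and the fixed-cluster-effects method."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit
from sklearn.base import BaseEstimator

from .base import FitResult, as_cells, build_design, wald_test

#: |coefficient| beyond which the fit is declared separated (divergent).
SEPARATION_BOUND = 15.0


@dataclass
class IRLSFit:
    beta: np.ndarray
    cov: np.ndarray
    deviance: float
    loglik: float
    converged: bool
    n_iter: int
    message: str = ""


def binomial_loglik(beta, x, events, n):
    """Binomial log-likelihood (without the constant binomial coefficient)."""
    eta = x @ beta
    return float(events @ eta - n @ np.logaddexp(0.0, eta))


def fit_binomial_irls(
    x: np.ndarray,
    events: np.ndarray,
    n: np.ndarray,
    max_iter: int = 100,
    tol: float = 1e-10,
) -> IRLSFit:
    """Maximum-likelihood logistic regression on binomial counts.

    Iteratively reweighted least squares with deviance-based convergence;
    a coefficient drifting beyond ``SEPARATION_BOUND`` on the logit scale
    is treated as complete/quasi-complete separation.
    """
    events = np.asarray(events, float)
    n = np.asarray(n, float)
    p = x.shape[1]
    beta = np.zeros(p)
    # start the intercept at the empirical logit of the pooled proportion
    pbar = min(max(events.sum() / n.sum(), 1e-6), 1 - 1e-6)
    beta[0] = np.log(pbar / (1 - pbar))

    dev_old = np.inf
    for it in range(1, max_iter + 1):
        eta = x @ beta
        mu = expit(eta)
        w = n * mu * (1 - mu)
        if not np.all(np.isfinite(w)) or w.sum() <= 0:
            return IRLSFit(beta, np.full((p, p), np.nan), np.nan, np.nan, False,
                           it, "degenerate weights")
        score = x.T @ (events - n * mu)
        info = (x * w[:, None]).T @ x
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            return IRLSFit(beta, np.full((p, p), np.nan), np.nan, np.nan, False,
                           it, "singular information matrix")
        beta = beta + step
        if np.max(np.abs(beta)) > SEPARATION_BOUND:
            return IRLSFit(beta, np.full((p, p), np.nan), np.nan, np.nan, False,
                           it, "separation: coefficient diverged")
        dev = -2.0 * binomial_loglik(beta, x, events, n)
        if abs(dev_old - dev) < tol * (abs(dev) + tol):
            mu = expit(x @ beta)
            w = n * mu * (1 - mu)
            info = (x * w[:, None]).T @ x
            try:
                cov = np.linalg.inv(info)
            except np.linalg.LinAlgError:
                return IRLSFit(beta, np.full((p, p), np.nan), dev, -dev / 2, False,
                               it, "singular information at optimum")
            return IRLSFit(beta, cov, dev, -dev / 2, True, it)
        dev_old = dev
    return IRLSFit(beta, np.full((p, p), np.nan), dev_old, -dev_old / 2, False,
                   max_iter, "IRLS did not converge")


class FixedEffectsLogistic(BaseEstimator):
    """Logistic regression with cluster fixed effects.

    Model: logit E[Y] = b0 + b1*X + time terms + b3*I(k=2) + ... +
    b_{M+1}*I(k=M), fitted by IRLS on the aggregated binomial counts.
    The intervention effect is tested with a 1-df chi-squared Wald test
    using the model-based standard error.

    Parameters
    ----------
    time_adjustment : {"none", "linear", "categorical"}
    """

    method_name = "fixed_effects"
    scale = "log-odds"

    def __init__(self, time_adjustment: str = "linear"):
        self.time_adjustment = time_adjustment

    def fit(self, data, y=None):
        cells = as_cells(data)
        x, names = build_design(cells, self.time_adjustment, cluster_effects=True)
        res = fit_binomial_irls(
            x, cells["events"].to_numpy(), cells["n"].to_numpy()
        )
        idx = names.index("treatment")
        self.feature_names_ = names
        self.coef_ = res.beta
        self.cov_ = res.cov
        self.effect_ = float(res.beta[idx])
        self.se_ = float(np.sqrt(res.cov[idx, idx])) if res.converged else np.nan
        self.loglik_ = res.loglik
        self.converged_ = bool(res.converged)
        self.message_ = res.message
        self.n_obs_ = int(cells["n"].sum())
        self.df_ = np.inf
        self.p_value_ = (
            wald_test(self.effect_, self.se_, "chisq1") if res.converged else np.nan
        )
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
            time_adjustment=self.time_adjustment,
            n_obs=self.n_obs_,
            message=self.message_,
        )
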