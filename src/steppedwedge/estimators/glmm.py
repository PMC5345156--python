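"""Random-intercept logistic GLMM fitted by adaptive Gauss-Hermite quadrature.

Model: logit E[Y_jk] = beta0 + a_0k + beta1 * X_jk + time terms, with
cluster random intercepts a_0k ~ Normal(0, sigma^2).  Each cluster's
likelihood contribution is integrated over its random intercept with
adaptive (mode- and curvature-centred) Gauss-Hermite quadrature; four
nodes is the default.  Adaptivity matters: non-adaptive quadrature with so
few nodes is badly inaccurate once cluster totals are large, because the
integrand concentrates far from the prior scale.

Inference for the intervention effect uses a Wald t-test with containment
degrees of freedom (N subjects minus the rank of the combined fixed +
random design), the small-sample convention of mixed-model software.
"""

from __future__ import annotations

import numpy as np
from numpy.polynomial.hermite import hermgauss
from scipy import optimize
from scipy.special import expit
from sklearn.base import BaseEstimator

from .base import FitResult, as_cells, build_design, containment_df, wald_test
from .glm import fit_binomial_irls

#: log sigma below which the variance estimate is treated as a boundary fit
#: (sigma_hat = 0); such fits are legitimate under low ICC and are reported
#: as converged with the pooled-GLM inference.
BOUNDARY_LOG_SIGMA = -8.0


def _cluster_arrays(cells):
    """Reshape the cell table to (M, T_max) arrays with a validity mask."""
    groups = cells.groupby("cluster", sort=True)
    sizes = groups.size().to_numpy()
    m, tmax = len(sizes), sizes.max()
    y = np.zeros((m, tmax))
    n = np.zeros((m, tmax))
    mask = np.zeros((m, tmax), bool)
    row_index = np.zeros(len(cells), dtype=int)
    for gi, (_, idx) in enumerate(groups.indices.items()):
        cols = np.arange(len(idx))
        y[gi, cols] = cells["events"].to_numpy()[idx]
        n[gi, cols] = cells["n"].to_numpy()[idx]
        mask[gi, cols] = True
        row_index[idx] = gi * tmax + cols
    return y, n, mask, row_index


class _AGHQLoglik:
    """Marginal log-likelihood of the random-intercept logistic model.

    Parameters are theta = (beta, log sigma).  The per-cluster random
    intercept modes are warm-started between calls, which makes the
    repeated evaluations of a quasi-Newton optimiser cheap.
    """

    def __init__(self, x, y, n, mask, row_index, n_quad=4):
        self.x = x
        self.y = y  # (M, T)
        self.n = n
        self.mask = mask
        self.row_index = row_index
        self.shape = y.shape
        self.nodes, self.weights = hermgauss(n_quad)
        self.log_weights = np.log(self.weights)
        self._u_hat = np.zeros(y.shape[0])

    def _eta0(self, beta):
        flat = np.zeros(self.shape[0] * self.shape[1])
        flat[self.row_index] = self.x @ beta
        return flat.reshape(self.shape)

    def _find_modes(self, eta0, inv_var):
        """Vectorised Newton maximisation of each cluster's integrand log
        h_k(u) = sum_j [y eta - n log(1+e^eta)] - u^2 / (2 sigma^2)."""
        u = self._u_hat.copy()
        for _ in range(100):
            mu = expit(eta0 + u[:, None])
            g = ((self.y - self.n * mu) * self.mask).sum(axis=1) - u * inv_var
            w = (self.n * mu * (1 - mu) * self.mask).sum(axis=1) + inv_var
            step = g / w
            # dampen huge first steps; h is concave so Newton then converges
            step = np.clip(step, -4.0, 4.0)
            u = u + step
            if np.max(np.abs(step)) < 1e-10:
                break
        mu = expit(eta0 + u[:, None])
        curvature = (self.n * mu * (1 - mu) * self.mask).sum(axis=1) + inv_var
        return u, curvature

    def _h(self, eta0, u, inv_var, log_sigma):
        """Integrand on the log scale, per cluster, at intercepts u (M, Q)."""
        eta = eta0[:, :, None] + u[:, None, :]
        ll = ((self.y[:, :, None] * eta
               - self.n[:, :, None] * np.logaddexp(0.0, eta))
              * self.mask[:, :, None]).sum(axis=1)
        prior = -0.5 * u**2 * inv_var - log_sigma - 0.5 * np.log(2 * np.pi)
        return ll + prior

    def loglik(self, theta):
        beta, log_sigma = theta[:-1], theta[-1]
        sigma = np.exp(log_sigma)
        inv_var = np.exp(-2.0 * log_sigma)
        eta0 = self._eta0(beta)
        u_hat, curvature = self._find_modes(eta0, inv_var)
        self._u_hat = u_hat
        tau = 1.0 / np.sqrt(curvature)
        # integral = sqrt(2) tau sum_i w_i exp(h(u_hat + sqrt(2) tau z_i) + z_i^2)
        u_nodes = u_hat[:, None] + np.sqrt(2.0) * tau[:, None] * self.nodes[None, :]
        h = self._h(eta0, u_nodes, inv_var, log_sigma)
        h += self.nodes[None, :] ** 2 + self.log_weights[None, :]
        hmax = h.max(axis=1)
        lse = hmax + np.log(np.exp(h - hmax[:, None]).sum(axis=1))
        per_cluster = 0.5 * np.log(2.0) + np.log(tau) + lse
        return float(per_cluster.sum())

    def negloglik(self, theta):
        return -self.loglik(theta)


def _numerical_hessian(fun, x0, eps=1e-4):
    """Central-difference Hessian; adequate for a smooth 4-6 parameter
    objective evaluated to ~1e-10 relative accuracy."""
    k = len(x0)
    h = eps * (1.0 + np.abs(x0))
    hess = np.zeros((k, k))
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k); ei[i] = h[i]
            ej = np.zeros(k); ej[j] = h[j]
            fpp = fun(x0 + ei + ej)
            fpm = fun(x0 + ei - ej)
            fmp = fun(x0 - ei + ej)
            fmm = fun(x0 - ei - ej)
            hess[i, j] = hess[j, i] = (fpp - fpm - fmp + fmm) / (4 * h[i] * h[j])
    return hess


class RandomInterceptLogisticGLMM(BaseEstimator):
    """Cluster random-intercept logistic regression (adaptive GHQ).

    Parameters
    ----------
    time_adjustment : {"none", "linear", "categorical"}
        Period-effect terms included with the intercept and treatment.
    n_quad : int
        Number of Gauss-Hermite nodes per cluster (adaptive recentring).
    sigma_start : float
        Starting value of the random-intercept standard deviation; fixed
        effects start at the pooled logistic fit.
    max_iter : int
        Quasi-Newton iteration cap.

    Attributes
    ----------
    effect_ : float
        Estimated intervention log odds ratio (cluster-specific).
    se_ : float
        Model-based standard error from the observed information.
    sigma_u_ : float
        Estimated random-intercept standard deviation (0.0 at a boundary
        fit).
    df_ : float
        Containment degrees of freedom for the Wald t-test.
    p_value_ : float
        Two-sided t-test p-value for the intervention effect.
    """

    method_name = "glmm"
    scale = "log-odds"

    def __init__(self, time_adjustment: str = "linear", n_quad: int = 4,
                 sigma_start: float = 0.3, max_iter: int = 200):
        self.time_adjustment = time_adjustment
        self.n_quad = n_quad
        self.sigma_start = sigma_start
        self.max_iter = max_iter

    def _fail(self, message, names, n_obs, df):
        self.feature_names_ = names
        self.coef_ = None
        self.effect_ = np.nan
        self.se_ = np.nan
        self.sigma_u_ = np.nan
        self.loglik_ = np.nan
        self.df_ = df
        self.p_value_ = np.nan
        self.converged_ = False
        self.message_ = message
        self.n_obs_ = n_obs
        return self

    def fit(self, data, y=None):
        cells = as_cells(data)
        x, names = build_design(cells, self.time_adjustment)
        events = cells["events"].to_numpy(float)
        n = cells["n"].to_numpy(float)
        n_obs = int(n.sum())
        df = containment_df(cells, self.time_adjustment, per_subject=True)
        idx = names.index("treatment")

        start_glm = fit_binomial_irls(x, events, n)
        beta_start = start_glm.beta if start_glm.converged else np.zeros(x.shape[1])

        y_arr, n_arr, mask, row_index = _cluster_arrays(cells)
        obj = _AGHQLoglik(x, y_arr, n_arr, mask, row_index, self.n_quad)
        theta0 = np.append(beta_start, np.log(self.sigma_start))
        res = optimize.minimize(
            obj.negloglik, theta0, method="BFGS",
            options={"gtol": 1e-5, "maxiter": self.max_iter},
        )
        # BFGS sometimes reports line-search failure after the gradient is
        # already far below any meaningful scale; accept those optima.
        grad_ok = np.max(np.abs(res.jac)) < 1e-3 * max(1.0, abs(res.fun))
        if not (res.success or grad_ok):
            return self._fail(f"optimizer failure: {res.message}", names, n_obs, df)

        theta = res.x
        boundary = theta[-1] < BOUNDARY_LOG_SIGMA
        if boundary:
            # sigma -> 0: the model collapses to a pooled logistic GLM
            if not start_glm.converged:
                return self._fail(
                    "boundary variance but pooled GLM failed: " + start_glm.message,
                    names, n_obs, df,
                )
            self.coef_ = start_glm.beta
            self.sigma_u_ = 0.0
            self.effect_ = float(start_glm.beta[idx])
            self.se_ = float(np.sqrt(start_glm.cov[idx, idx]))
            self.loglik_ = start_glm.loglik
        else:
            hess = _numerical_hessian(obj.negloglik, theta)
            try:
                cov = np.linalg.inv(hess)
            except np.linalg.LinAlgError:
                return self._fail("singular observed information", names, n_obs, df)
            var = cov[idx, idx]
            if not np.isfinite(var) or var <= 0:
                return self._fail("non-positive-definite information", names,
                                  n_obs, df)
            self.coef_ = theta[:-1]
            self.sigma_u_ = float(np.exp(theta[-1]))
            self.effect_ = float(theta[idx])
            self.se_ = float(np.sqrt(var))
            self.loglik_ = -float(res.fun)

        self.feature_names_ = names
        self.df_ = df
        self.p_value_ = wald_test(self.effect_, self.se_, "t", df=self.df_)
        self.converged_ = True
        self.message_ = "boundary sigma=0" if boundary else ""
        self.n_obs_ = n_obs
        return self

    def loglik_at(self, data, beta, sigma, n_quad=None):
        """Marginal log-likelihood at given parameters (for diagnostics and
        quadrature-accuracy checks); uses ``n_quad`` nodes if supplied."""
        cells = as_cells(data)
        x, _ = build_design(cells, self.time_adjustment)
        y_arr, n_arr, mask, row_index = _cluster_arrays(cells)
        obj = _AGHQLoglik(x, y_arr, n_arr, mask, row_index,
                          n_quad or self.n_quad)
        return obj.loglik(np.append(np.asarray(beta, float), np.log(sigma)))

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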