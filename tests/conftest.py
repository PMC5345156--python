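"""Shared fixtures: small simulated trials and independent oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import quad
from scipy.special import expit

import steppedwedge as sw


@pytest.fixture(scope="session")
def small_trial():
    """A 6-cluster, 4-period trial with moderate cells."""
    cfg = sw.ScenarioConfig(steps=3, n_clusters=6, cell_size=20,
                            baseline_mean=0.2, icc=0.05,
                            or_intervention=2.25, or_time=1.227,
                            replicates=1, seed=7)
    return sw.generate_trial(cfg, np.random.SeedSequence(5))


@pytest.fixture(scope="session")
def mid_trial():
    """A 9-cluster, 4-period trial with 50-subject cells."""
    cfg = sw.ScenarioConfig(steps=3, n_clusters=9, cell_size=50,
                            baseline_mean=0.1, icc=0.05,
                            or_intervention=2.25, or_time=1.227,
                            replicates=1, seed=3)
    return sw.generate_trial(cfg, np.random.SeedSequence(11))


def expand_subjects(cells: pd.DataFrame) -> pd.DataFrame:
    """One row per subject, reconstructing the Bernoulli outcomes."""
    rows = []
    for _, r in cells.iterrows():
        for i in range(int(r["n"])):
            rows.append({
                "cluster": int(r["cluster"]),
                "period": int(r["period"]),
                "treatment": int(r["treatment"]),
                "y": 1 if i < r["events"] else 0,
            })
    return pd.DataFrame(rows)


def brute_force_glmm_loglik(cells: pd.DataFrame, beta, sigma: float) -> float:
    """Dense numerical integration of the random-intercept logistic
    likelihood, independent of the quadrature implementation under test.

    beta = (intercept, treatment, linear time).
    """
    beta = np.asarray(beta, float)
    total = 0.0
    for _, grp in cells.groupby("cluster"):
        t = grp["treatment"].to_numpy()
        j = grp["period"].to_numpy()
        y = grp["events"].to_numpy()
        n = grp["n"].to_numpy()

        def integrand(u):
            p = expit(beta[0] + u + beta[1] * t + beta[2] * j)
            lik = np.prod(p ** y * (1 - p) ** (n - y))
            return lik * np.exp(-u**2 / (2 * sigma**2)) / (sigma * np.sqrt(2 * np.pi))

        val, _ = quad(integrand, -12 * sigma, 12 * sigma, limit=400,
                      epsabs=1e-16, epsrel=1e-13)
        total += np.log(val)
    return total
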