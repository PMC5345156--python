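"""Beta-binomial data generation for cross-sectional stepped wedge trials.

True baseline cluster proportions p_0k are drawn from a Beta(a, b) whose
shape parameters are solved so that E[p_0k] = mu and the intra-cluster
correlation is rho = 1/(a + b + 1).  Cell probabilities follow a
cluster-specific logistic model

    logit(p_jk) = beta_0k + beta_1 * X_jk + beta_2 * j,

with beta_0k = logit(p_0k), and subject outcomes are independent Bernoulli
draws given p_jk.  Subjects within a cell are exchangeable, so outcomes are
stored as binomial event counts per cluster-period cell; every analysis
method in this package has identical likelihood / estimating equations on
the aggregated representation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .config import ScenarioConfig

#: Maximum regenerations of a dataset failing the no-events discard rule
#: before the scenario is declared degenerate.
MAX_DISCARD_RETRIES = 1000


class DegenerateScenarioError(RuntimeError):
    """Raised when the discard rule rejects too many consecutive datasets."""


@dataclass(frozen=True)
class BetaParams:
    """Shape parameters of the baseline-proportion beta distribution."""

    a: float
    b: float

    @property
    def mean(self) -> float:
        return self.a / (self.a + self.b)

    @property
    def icc(self) -> float:
        return 1.0 / (self.a + self.b + 1.0)


@dataclass
class TrialDataset:
    """One simulated stepped wedge trial in cluster-period cell form.

    ``cells`` has one row per (cluster, period) with columns
    ``cluster, period, treatment, n, events, p_true, p0, beta0``.
    """

    cells: pd.DataFrame
    step_allocation: dict[int, int]
    config: ScenarioConfig
    n_discarded: int = 0

    @property
    def total_n(self) -> int:
        return int(self.cells["n"].sum())

    @property
    def n_clusters(self) -> int:
        return self.cells["cluster"].nunique()

    @property
    def periods(self) -> int:
        return self.cells["period"].nunique()

    def to_csv(self, path) -> None:
        """Export cells for external cross-checking."""
        out = self.cells[["cluster", "period", "treatment", "n", "events", "p_true"]]
        out.to_csv(path, index=False)

    def treatment_matrix(self) -> np.ndarray:
        """Cluster-by-period treatment indicators, clusters sorted by switch period."""
        wide = self.cells.pivot(index="cluster", columns="period", values="treatment")
        order = sorted(self.step_allocation, key=self.step_allocation.get)
        return wide.loc[order].to_numpy(dtype=int)


def solve_beta_params(mu: float, icc: float) -> BetaParams:
    """Solve the beta shape parameters matching a target mean and ICC.

    The moment equations E[p] = a/(a+b) and rho = 1/(a+b+1) have the closed
    form a = mu*(1/rho - 1), b = (1 - mu)*(1/rho - 1).
    """
    if not 0.0 < mu < 1.0:
        raise ValueError(f"mu must be in (0, 1), got {mu}")
    if not 0.0 < icc < 1.0:
        raise ValueError(f"icc must be in (0, 1), got {icc}")
    total = 1.0 / icc - 1.0
    return BetaParams(a=mu * total, b=(1.0 - mu) * total)


def allocate_steps(
    n_clusters: int, steps: int, rng: np.random.Generator
) -> dict[int, int]:
    """Randomly assign clusters to switch periods.

    Clusters (labelled 1..M) are permuted uniformly at random and chunked
    into ``steps`` equal groups; group g switches to intervention
    immediately before measurement period g (g = 1..steps), so every
    cluster is in control at period 0 and in intervention by the final
    period.
    """
    if n_clusters % steps != 0:
        raise ValueError(
            f"n_clusters ({n_clusters}) is not divisible by steps ({steps})"
        )
    per_step = n_clusters // steps
    order = rng.permutation(n_clusters) + 1
    return {
        int(cluster): 1 + position // per_step
        for position, cluster in enumerate(order)
    }


def cell_probability(
    beta0k: float, x_jk, j, beta1: float, beta2: float
):
    """True event probability of a cluster-period cell.

    Inverse logit of ``beta0k + beta1 * x_jk + beta2 * j``; accepts scalar
    or array treatment indicator and period index.
    """
    return expit(beta0k + beta1 * np.asarray(x_jk) + beta2 * np.asarray(j))


def _simulate_once(
    config: ScenarioConfig, rng: np.random.Generator
) -> tuple[pd.DataFrame, dict[int, int]]:
    beta = solve_beta_params(config.baseline_mean, config.icc)
    m, t = config.n_clusters, config.periods

    p0 = rng.beta(beta.a, beta.b, size=m)
    beta0 = logit(p0)
    allocation = allocate_steps(m, config.steps, rng)

    periods = np.arange(t)
    switch = np.array([allocation[k] for k in range(1, m + 1)])
    # X[k, j] = 1 once cluster k has switched (non-decreasing in j)
    x = (periods[None, :] >= switch[:, None]).astype(int)
    p = expit(beta0[:, None] + config.beta1 * x + config.beta2 * periods[None, :])
    events = rng.binomial(config.cell_size, p)

    cells = pd.DataFrame(
        {
            "cluster": np.repeat(np.arange(1, m + 1), t),
            "period": np.tile(periods, m),
            "treatment": x.ravel(),
            "n": config.cell_size,
            "events": events.ravel(),
            "p_true": p.ravel(),
            "p0": np.repeat(p0, t),
            "beta0": np.repeat(beta0, t),
        }
    )
    return cells, allocation


def generate_trial(config: ScenarioConfig, rng) -> TrialDataset:
    """Generate one trial dataset satisfying the discard rule.

    A dataset with zero events across all control cells, or zero events
    across all intervention cells, is discarded and regenerated from the
    next spawned substream, so downstream replicates are unaffected by how
    many discards occurred.

    Parameters
    ----------
    rng : int, numpy.random.SeedSequence or numpy.random.Generator
        Source of randomness. Passing a SeedSequence (or int) gives the
        documented substream-per-attempt behaviour; a Generator is used
        directly (attempts then consume the same stream sequentially).
    """
    if isinstance(rng, np.random.Generator):
        streams = None
    else:
        seed_seq = (
            rng
            if isinstance(rng, np.random.SeedSequence)
            else np.random.SeedSequence(rng)
        )
        streams = iter(seed_seq.spawn(MAX_DISCARD_RETRIES + 1))

    n_discarded = 0
    for _ in range(MAX_DISCARD_RETRIES + 1):
        gen = rng if streams is None else np.random.default_rng(next(streams))
        cells, allocation = _simulate_once(config, gen)
        control = cells.loc[cells["treatment"] == 0, "events"].sum()
        treated = cells.loc[cells["treatment"] == 1, "events"].sum()
        if control > 0 and treated > 0:
            return TrialDataset(
                cells=cells,
                step_allocation=allocation,
                config=config,
                n_discarded=n_discarded,
            )
        n_discarded += 1
    raise DegenerateScenarioError(
        f"discard rule rejected {MAX_DISCARD_RETRIES + 1} consecutive datasets; "
        "the scenario produces essentially no events in one arm"
    )
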