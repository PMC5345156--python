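"""Scenario configuration for stepped wedge simulations.

A scenario fixes the trial design (steps, clusters, cell size), the true
data-generating parameters (baseline proportion, ICC, intervention and time
odds ratios) and the Monte-Carlo settings (replicates, seed).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, replace
from math import log
from typing import Any

import yaml

TIME_ADJUSTMENTS = ("none", "linear", "categorical")


@dataclass(frozen=True)
class ScenarioConfig:
    """Full specification of one simulation scenario.

    Parameters
    ----------
    steps : int
        Number of intervention switch points. A design with ``steps`` steps
        has ``steps + 1`` measurement periods; the first period is
        all-control and the last is all-intervention.
    n_clusters : int
        Total number of clusters M; must be divisible by ``steps`` so each
        step switches an equal number of clusters.
    cell_size : int
        Number of subjects measured per cluster per period (n_jk). The
        design is cross-sectional: new subjects every period.
    baseline_mean : float
        Mean of the true baseline cluster proportions, E[p_0k] = mu.
    icc : float
        Intra-cluster correlation rho, induced by drawing p_0k from a
        Beta(a, b) with rho = 1/(a + b + 1).
    or_intervention : float
        True intervention odds ratio exp(beta_1) on the cluster-specific
        (conditional) scale.
    or_time : float
        True per-period time odds ratio exp(beta_2).
    time_adjustment : {"none", "linear", "categorical"}
        How analysis models adjust for period effects (the generator always
        uses a linear-in-logit trend of size log(or_time)).
    replicates : int
        Number of Monte-Carlo replicates for this scenario.
    seed : int
        Master seed; replicate substreams are spawned from it.
    """

    steps: int = 3
    n_clusters: int = 3
    cell_size: int = 100
    baseline_mean: float = 0.1
    icc: float = 0.01
    or_intervention: float = 2.25
    or_time: float = 1.0
    time_adjustment: str = "linear"
    replicates: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.steps < 1:
            raise ValueError("steps must be a positive integer")
        if self.n_clusters < 1:
            raise ValueError("n_clusters must be a positive integer")
        if self.n_clusters % self.steps != 0:
            raise ValueError(
                f"n_clusters ({self.n_clusters}) must be divisible by "
                f"steps ({self.steps}) so each step switches an equal "
                "number of clusters"
            )
        if self.cell_size < 1:
            raise ValueError("cell_size must be a positive integer")
        if not 0.0 < self.baseline_mean < 1.0:
            raise ValueError("baseline_mean must lie in the open interval (0, 1)")
        if not 0.0 < self.icc < 1.0:
            raise ValueError("icc must lie in the open interval (0, 1)")
        if self.or_intervention <= 0 or self.or_time <= 0:
            raise ValueError("odds ratios must be strictly positive")
        if self.time_adjustment not in TIME_ADJUSTMENTS:
            raise ValueError(f"time_adjustment must be one of {TIME_ADJUSTMENTS}")
        if self.replicates < 1:
            raise ValueError("replicates must be a positive integer")

    @property
    def periods(self) -> int:
        """Number of measurement periods (steps + 1)."""
        return self.steps + 1

    @property
    def clusters_per_step(self) -> int:
        return self.n_clusters // self.steps

    @property
    def beta1(self) -> float:
        """True conditional log odds ratio of the intervention."""
        return log(self.or_intervention)

    @property
    def beta2(self) -> float:
        """True per-period log odds ratio of time."""
        return log(self.or_time)

    def with_(self, **kwargs: Any) -> "ScenarioConfig":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioConfig":
        return cls(**d)


def load_config(path: str) -> ScenarioConfig:
    """Read a single scenario from a flat YAML (or JSON) key-value file."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValueError(f"{path} does not contain a mapping of scenario fields")
    return ScenarioConfig.from_dict(data)


def load_grid_spec(path: str) -> dict:
    """Read a declarative grid specification (factor lists) from YAML.

    Recognised keys are the ScenarioConfig field names; scalar values are
    fixed factors and lists are crossed factor levels.
    """
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValueError(f"{path} does not contain a grid specification mapping")
    return data
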