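"""Monte-Carlo harness: replicate simulations, scenario grids and metrics.

A scenario is one combination of design and effect-size factors; the
harness generates ``replicates`` datasets (honouring the no-events discard
rule), fits every requested analysis method to every dataset, and
summarises per cent bias, the rejection rate at the 5% level (type I error
under the null, power otherwise), its Monte-Carlo standard error, and
convergence failures.  Summaries use converged fits only; failures are
counted separately.

Bias is measured on each method's own scale: the conditional log odds
ratio for the GLMM and fixed-effects methods, the converted
(marginal-to-conditional) log odds ratio for the GEE, and the risk
difference for the cluster-summary method, whose truth is
expit(logit(mu) + beta1) - mu.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from joblib import Parallel, delayed
from scipy.special import expit, logit

from .config import ScenarioConfig
from .datagen import generate_trial
from .estimators import METHODS, ModelSpec

ALPHA = 0.05


def percent_bias(estimates: Sequence[float], true_value: float) -> float:
    """Per cent bias 100 * (mean(estimates) - true) / true."""
    estimates = np.asarray(estimates, float)
    if estimates.size == 0:
        raise ValueError("percent_bias requires at least one estimate")
    if true_value == 0:
        raise ValueError("percent_bias is undefined for a zero true value")
    return float(100.0 * (estimates.mean() - true_value) / true_value)


def rejection_rate(p_values: Sequence[float], alpha: float = ALPHA) -> float:
    """Fraction of p-values strictly below alpha."""
    p = np.asarray(p_values, float)
    if p.size == 0:
        raise ValueError("rejection_rate requires at least one p-value")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    return float(np.mean(p < alpha))


def true_effect(config: ScenarioConfig, spec: ModelSpec) -> float:
    """True intervention effect on the scale the method estimates."""
    if spec.method == "cluster_summaries":
        return float(expit(logit(config.baseline_mean) + config.beta1)
                     - config.baseline_mean)
    return config.beta1


def _estimate_for_bias(result) -> float:
    if result.method == "gee" and result.estimate_conditional is not None:
        return result.estimate_conditional
    return result.estimate


@dataclass
class ScenarioResult:
    """Monte-Carlo summary for one scenario and one analysis method."""

    config: ScenarioConfig
    spec: ModelSpec
    n_replicates: int
    n_converged: int
    n_failed: int
    n_discarded_datasets: int
    mean_estimate: float
    sd_estimate: float
    percent_bias: float
    rejection_rate: float
    mc_se_rejection: float
    mean_se: float
    true_value: float

    @property
    def is_null(self) -> bool:
        return self.config.or_intervention == 1.0

    def to_record(self) -> dict:
        rec = {
            **self.config.to_dict(),
            "method": self.spec.method,
            "model_time_adjustment": self.spec.time_adjustment,
            "n_replicates": self.n_replicates,
            "n_converged": self.n_converged,
            "n_failed": self.n_failed,
            "n_discarded_datasets": self.n_discarded_datasets,
            "mean_estimate": self.mean_estimate,
            "sd_estimate": self.sd_estimate,
            "percent_bias": self.percent_bias,
            "rejection_rate": self.rejection_rate,
            "mc_se_rejection": self.mc_se_rejection,
            "mean_se": self.mean_se,
            "true_value": self.true_value,
            "metric": "type_i_error" if self.is_null else "power",
        }
        return rec


def _spec_for(config: ScenarioConfig, spec: ModelSpec) -> ModelSpec:
    """Resolve per-scenario defaults: the model's time adjustment follows
    the scenario unless the spec pins one, and the GEE conversion uses the
    scenario's design ICC unless overridden."""
    conversion = spec.conversion_icc
    if spec.method == "gee" and conversion is None:
        conversion = config.icc
    return ModelSpec(spec.method, spec.time_adjustment, conversion)


def run_scenario(
    config: ScenarioConfig,
    specs: Sequence[ModelSpec] | Sequence[str] = METHODS,
    seed_seq: Optional[np.random.SeedSequence] = None,
) -> list[ScenarioResult]:
    """Simulate one scenario and fit every method to every replicate.

    Deterministic given (config, specs): replicate substreams are spawned
    from ``config.seed`` (or an explicit SeedSequence), and a replicate's
    stream does not depend on any other replicate's discards.
    """
    specs = [ModelSpec(s) if isinstance(s, str) else s for s in specs]
    specs = [_spec_for(config, s) for s in specs]
    if not specs:
        raise ValueError("at least one analysis method is required")
    master = seed_seq if seed_seq is not None else np.random.SeedSequence(config.seed)
    streams = master.spawn(config.replicates)

    estimates: dict[ModelSpec, list[float]] = {s: [] for s in specs}
    pvalues: dict[ModelSpec, list[float]] = {s: [] for s in specs}
    ses: dict[ModelSpec, list[float]] = {s: [] for s in specs}
    failures: dict[ModelSpec, int] = {s: 0 for s in specs}
    n_discarded = 0

    for stream in streams:
        trial = generate_trial(config, stream)
        n_discarded += trial.n_discarded
        for spec in specs:
            res = spec.make_estimator().fit(trial).to_result()
            if res.converged and np.isfinite(res.p_value):
                estimates[spec].append(_estimate_for_bias(res))
                pvalues[spec].append(res.p_value)
                ses[spec].append(res.se)
            else:
                failures[spec] += 1

    out = []
    for spec in specs:
        n_conv = len(pvalues[spec])
        truth = true_effect(config, spec)
        if n_conv:
            rate = rejection_rate(pvalues[spec])
            out.append(ScenarioResult(
                config=config, spec=spec,
                n_replicates=config.replicates,
                n_converged=n_conv, n_failed=failures[spec],
                n_discarded_datasets=n_discarded,
                mean_estimate=float(np.mean(estimates[spec])),
                sd_estimate=(float(np.std(estimates[spec], ddof=1))
                             if n_conv > 1 else np.nan),
                percent_bias=(percent_bias(estimates[spec], truth)
                              if truth != 0 else np.nan),
                rejection_rate=rate,
                mc_se_rejection=float(np.sqrt(rate * (1 - rate) / n_conv)),
                mean_se=float(np.mean(ses[spec])),
                true_value=truth,
            ))
        else:
            out.append(ScenarioResult(
                config=config, spec=spec,
                n_replicates=config.replicates,
                n_converged=0, n_failed=failures[spec],
                n_discarded_datasets=n_discarded,
                mean_estimate=np.nan, sd_estimate=np.nan, percent_bias=np.nan,
                rejection_rate=np.nan, mc_se_rejection=np.nan,
                mean_se=np.nan, true_value=truth,
            ))
    return out


@dataclass
class GridResult:
    """Results over a full factorial scenario grid."""

    results: list[ScenarioResult]
    factor_levels: dict
    master_seed: int
    n_scenarios: int = 0

    def __post_init__(self):
        if not self.n_scenarios:
            self.n_scenarios = len({id(r.config) for r in self.results})

    def to_dataframe(self) -> pd.DataFrame:
        """Tidy table: one row per scenario x method."""
        return pd.DataFrame([r.to_record() for r in self.results])

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    def to_json(self, path) -> None:
        payload = {
            "factor_levels": self.factor_levels,
            "master_seed": self.master_seed,
            "results": self.to_dataframe().to_dict(orient="records"),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, default=float)


_GRID_FACTORS = (
    "steps", "n_clusters", "cell_size", "baseline_mean", "icc",
    "or_intervention", "or_time", "time_adjustment",
)


def expand_grid(grid_spec: dict, replicates: int | None = None,
                seed: int | None = None) -> list[ScenarioConfig]:
    """Cross the factor lists of a grid specification into configs.

    Keys are ScenarioConfig field names; list values are crossed, scalars
    fixed. ``replicates`` and ``seed`` may be given in the spec or as
    arguments (arguments win).
    """
    spec = dict(grid_spec)
    reps = replicates if replicates is not None else spec.pop("replicates", 2000)
    master = seed if seed is not None else spec.pop("seed", 0)
    spec.pop("replicates", None)
    spec.pop("seed", None)
    unknown = set(spec) - set(_GRID_FACTORS)
    if unknown:
        raise ValueError(f"unknown grid factors: {sorted(unknown)}")
    names, levels = [], []
    for key in _GRID_FACTORS:
        if key in spec:
            val = spec[key]
            names.append(key)
            levels.append(list(val) if isinstance(val, (list, tuple)) else [val])
    if not names or not all(levels):
        raise ValueError("grid specification is empty")
    configs = []
    for combo in itertools.product(*levels):
        configs.append(ScenarioConfig(
            **dict(zip(names, combo)), replicates=reps, seed=master))
    return configs


def scenario_a_grid(replicates: int = 2000, seed: int = 0) -> list[ScenarioConfig]:
    """The three-step factorial grid: 5 cluster counts x 4 cell sizes x
    3 ICCs x 2 time effects x 2 intervention effects = 240 scenarios,
    baseline proportion 0.1."""
    return expand_grid({
        "steps": 3,
        "n_clusters": [3, 6, 9, 18, 36],
        "cell_size": [5, 10, 50, 100],
        "baseline_mean": 0.1,
        "icc": [0.01, 0.05, 0.1],
        "or_time": [1.0, 1.227],
        "or_intervention": [1.0, 2.25],
    }, replicates=replicates, seed=seed)


def scenario_b_grid(replicates: int = 2000, seed: int = 0) -> list[ScenarioConfig]:
    """The six-step grid: 4 cluster counts x 4 cell sizes x 3 ICCs x
    2 time effects x 2 intervention effects, baseline proportion 0.2,
    weaker effects (intervention OR 1.33, time OR 1.03)."""
    return expand_grid({
        "steps": 6,
        "n_clusters": [6, 12, 18, 36],
        "cell_size": [5, 10, 25, 50],
        "baseline_mean": 0.2,
        "icc": [0.01, 0.05, 0.1],
        "or_time": [1.0, 1.03],
        "or_intervention": [1.0, 1.33],
    }, replicates=replicates, seed=seed)


def run_grid(
    configs: Sequence[ScenarioConfig] | dict,
    specs: Sequence[ModelSpec] | Sequence[str] = METHODS,
    master_seed: int | None = None,
    n_jobs: int = 1,
) -> GridResult:
    """Run every scenario of a grid.

    Scenarios are independent work units with pre-spawned random
    substreams, so results are invariant to execution order and to
    ``n_jobs``. ``master_seed`` (default: the first config's seed)
    deterministically derives one substream per scenario.
    """
    if isinstance(configs, dict):
        configs = expand_grid(configs)
    configs = list(configs)
    if not configs:
        raise ValueError("empty scenario grid")
    seed = master_seed if master_seed is not None else configs[0].seed
    streams = np.random.SeedSequence(seed).spawn(len(configs))

    def one(config, stream):
        return run_scenario(config, specs, seed_seq=stream)

    if n_jobs == 1:
        chunks = [one(c, s) for c, s in zip(configs, streams)]
    else:
        chunks = Parallel(n_jobs=n_jobs)(
            delayed(one)(c, s) for c, s in zip(configs, streams))

    results = [r for chunk in chunks for r in chunk]
    factor_levels = {
        key: sorted({getattr(c, key) for c in configs})
        for key in _GRID_FACTORS
    }
    return GridResult(results=results, factor_levels=factor_levels,
                      master_seed=seed, n_scenarios=len(configs))
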