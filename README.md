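# steppedwedge

Simulation and analysis of **cross-sectional stepped wedge cluster
randomised trials (SW-CRTs) with binary outcomes**.

In a stepped wedge design every cluster starts in the control condition and
crosses over to the intervention at a randomised, staggered step, until all
clusters are treated. The design confounds the intervention with calendar
time by construction, and trials of this type are frequently run with very
few clusters — which strains every standard analysis method for correlated
binary data. This package is for trial statisticians and methodologists who
want to quantify, by Monte-Carlo simulation, how much bias, type I error
inflation and power loss to expect from the common analysis choices at a
given number of clusters, cluster-period cell size and intra-cluster
correlation (ICC).

## What it does

**Data generation.** True baseline cluster proportions are drawn from a
beta distribution pinned to a target mean μ and ICC ρ by solving

    E[p_0k] = a/(a+b) = μ,        ρ = 1/(a+b+1),

so a = μ(1/ρ − 1), b = (1−μ)(1/ρ − 1). Cell probabilities follow the
cluster-specific logistic model

    logit(p_jk) = β_0k + β₁ X_jk + β₂ j,      β_0k = logit(p_0k),

where X_jk is the treatment indicator of cluster k in period j and β₁, β₂
are the intervention and per-period time log odds ratios. Outcomes are
independent Bernoulli draws within each cluster-period cell, stored as
binomial counts (subjects within a cell are exchangeable, so aggregation is
lossless). Datasets with zero events in either the control or the
intervention arm are discarded and regenerated.

**Four analysis methods**, each a scikit-learn-style estimator:

| class | effect scale | inference |
|---|---|---|
| `RandomInterceptLogisticGLMM` | conditional log OR | 4-node adaptive Gauss–Hermite ML; Wald *t* with containment df |
| `ExchangeableLogisticGEE` | marginal log OR (+ conversion β₁/(1−ρ)) | Wald *z*; model-based or sandwich SE |
| `FixedEffectsLogistic` | log OR with cluster fixed effects | 1-df chi-squared Wald |
| `ClusterSummaryLMM` | risk difference on cell proportions | REML; Wald *t* with containment df |

**Harness.** `run_scenario` / `run_grid` simulate replicate trials over
factorial scenario grids (the built-in `scenario_a_grid` crosses 5 cluster
counts × 4 cell sizes × 3 ICCs × 2 time effects × 2 intervention effects =
240 scenarios of a three-step design; `scenario_b_grid` is a six-step
variant) and report per method: per cent bias 100(mean β̂₁ − β₁)/β₁, the
rejection rate at the 5% level (type I error under the null, power
otherwise) with its Monte-Carlo standard error, and convergence failures.
Replicate substreams are pre-spawned from the master seed, so results are
bit-identical across runs and worker counts.

## Worked example

```python
import numpy as np
import steppedwedge as sw

config = sw.ScenarioConfig(
    steps=3, n_clusters=6, cell_size=100,
    baseline_mean=0.1, icc=0.05,
    or_intervention=2.25, or_time=1.227,
    replicates=200, seed=42,
)

# one simulated trial, analysed with the mixed model
trial = sw.generate_trial(config, np.random.SeedSequence(42))
fit = sw.fit_glmm(trial)
print(f"GLMM log OR = {fit.estimate:.3f} (SE {fit.se:.3f}), "
      f"t({fit.df:.0f}) p = {fit.p_value:.2e}, sigma_u = {fit.sigma_u:.3f}")

# a 200-replicate Monte-Carlo comparison of two methods
for res in sw.run_scenario(config, ["glmm", "gee"]):
    print(f"{res.spec.method}: power = {res.rejection_rate:.3f} "
          f"(MC SE {res.mc_se_rejection:.3f}), "
          f"per cent bias = {res.percent_bias:+.1f}%, "
          f"failures = {res.n_failed}")
```

Output:

```
GLMM log OR = 0.798 (SE 0.180), t(2392) p = 9.35e-06, sigma_u = 0.937
glmm: power = 0.990 (MC SE 0.007), per cent bias = +2.3%, failures = 0
gee: power = 0.975 (MC SE 0.011), per cent bias = +0.9%, failures = 0
```

The single-trial fit recovers a log odds ratio of 0.80 (truth:
ln 2.25 ≈ 0.81) with a cluster random-intercept SD of 0.94. Over 200
replicates both methods detect the doubled event proportion essentially
always at six clusters of this size, and the mean estimate is within a few
per cent of the truth.

The same operations are available from the shell:

```bash
steppedwedge simulate --clusters 6 --cell-size 100 --seed 42 --out trial.csv
steppedwedge scenario --clusters 6 --cell-size 100 --replicates 200 --out result.json
steppedwedge grid my_grid.yaml --methods glmm,gee --n-jobs 4 --out grid.csv
```

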