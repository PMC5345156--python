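# Methods

## The simulation model

The generator emulates a cross-sectional stepped wedge cluster randomised
trial with a binary outcome. A design with S steps has S+1 measurement
periods j = 0,…,S; all M clusters are in control at j = 0, and immediately
before each period g = 1,…,S a randomly chosen group of M/S clusters
switches permanently to the intervention (clusters are permuted uniformly
at random and chunked into equal groups, so every balanced allocation is
equally likely).

Between-cluster heterogeneity is induced at baseline: true cluster
proportions p_0k are drawn from Beta(a, b) with

    a = μ(1/ρ − 1),   b = (1 − μ)(1/ρ − 1),

which solves E[p_0k] = μ and ICC ρ = 1/(a+b+1) exactly (the induced
binary-outcome ICC is Var(p_0k)/(μ(1−μ)) = ρ). Cell probabilities follow

    logit(p_jk) = β_0k + β₁ X_jk + β₂ j,   β_0k = logit(p_0k),

and the n_jk subjects of a cell are independent Bernoulli(p_jk) draws,
stored as a binomial count. Aggregation is lossless: subjects within a
cell are exchangeable, so every analysis method in the package has
identical likelihood or estimating equations on counts, and the harness is
orders of magnitude faster than with subject-level records.

A dataset whose control arm or intervention arm contains zero events
overall is discarded and regenerated (such a trial could not estimate an
odds ratio); each regeneration uses the next spawned random substream, so
replicate r is reproducible regardless of how many discards preceded it.
After 1000 consecutive discards a degenerate-scenario error is raised —
under any realistic configuration discards are rare, so hitting the cap
signals a mis-specification. Whether discarded datasets "count" is a
design choice; here they are replaced, so every scenario summarises
exactly `replicates` analysable datasets.

The time trend is linear on the logit scale both in generation and, by
default, in analysis. Analyses can instead adjust categorically
(indicators for j ≥ 1) or not at all; the generator itself has no
categorical mode.

### Default study conditions

The built-in scenario grids fix the conditions of the simulation study the
package reproduces:

- three-step grid ("scenario A"): M ∈ {3, 6, 9, 18, 36}, n_jk ∈ {5, 10,
  50, 100}, μ = 0.1, ρ ∈ {0.01, 0.05, 0.1}, intervention OR ∈ {1, 2.25}
  (2.25 doubles the event proportion from 0.1 to 0.2, i.e. a true risk
  difference of 0.1), time OR ∈ {1, 1.227} — 240 scenarios;
- six-step grid ("scenario B"): M ∈ {6, 12, 18, 36}, n_jk ∈ {5, 10, 25,
  50}, μ = 0.2, intervention OR ∈ {1, 1.33} (true risk difference ≈ 0.05),
  time OR ∈ {1, 1.03}, same three ICCs. Seven measurement periods
  (six steps plus the all-control baseline) mirror the S+1 structure of
  the three-step design.

The published study used 2000 replicates per scenario (power and type I
error MC standard errors ≈ 0.009 and 0.005). The package default for its
own verification runs is 500 replicates per scenario, chosen so the full
acceptance computation completes in minutes on one CPU; tolerances in the
tests scale accordingly (3 binomial MC SEs at the actual replicate count).

## Analysis methods

All four estimators consume the cluster-period cell table and expose the
intervention effect, its standard error, the reference distribution and a
two-sided Wald p-value. Summaries over replicates use converged fits only;
failures are counted separately, mirroring how simulation studies report
convergence separately from performance.

**GLMM.** Random-intercept logistic regression,
logit E[Y] = β₀ + a_0k + β₁X + time terms, a_0k ~ N(0, σ²), maximised by
adaptive Gauss–Hermite quadrature with 4 nodes. Adaptivity (recentring the
nodes at each cluster's posterior mode with the local curvature as scale)
is essential: non-adaptive 4-node quadrature is badly inaccurate once
cluster totals are large, because the integrand concentrates far from the
prior scale. Note the model is deliberately mis-specified relative to the
generator — the random intercept is normal while the generating baseline
is beta on the probability scale — reflecting what a practitioner would
fit. Implementation choices:

- variance parameter optimised as log σ to enforce positivity; a fit
  reaching log σ < −8 is a boundary fit, reported as converged with
  σ̂ = 0 and the pooled-GLM inference (boundary fits are legitimate under
  low ICC; discarding them would bias the summaries);
- starting values: fixed effects from a pooled logistic IRLS fit,
  σ_start = 0.3; BFGS quasi-Newton, gradient tolerance 1e-5, ≤200
  iterations; per-cluster posterior modes found by damped Newton (the
  integrand is log-concave) and warm-started between objective calls;
- standard errors from the inverse of a central-difference observed
  information at the optimum; non-positive-definite information or
  optimiser failure ⇒ converged = false;
- inference: Wald t with containment degrees of freedom,
  df = N_subjects − rank([X Z]), the convention of mixed-model software
  for effects that vary within clusters.

The 4-node quadrature's truncation error grows steeply with σ. At the
study's low-ICC scale (σ ≈ 0.25 on the logit scale) it agrees with dense
numerical integration to ~1e-8 per dataset; at σ ≈ 1 the gap is ~1e-4,
and at the wild σ̂ values that tiny datasets can produce (σ̂ > 5) it can
reach 1e-1. The tests therefore pin quadrature accuracy at
design-scale parameters and separately verify that the same machinery at
200 nodes matches a brute-force integration oracle everywhere.

**GEE.** Population-average logistic model with an exchangeable working
correlation over all subjects of a cluster (all periods pooled, as
appropriate for a cross-sectional design where cluster-period cells are
exchangeable). α is re-estimated each quasi-score iteration by the moment
method on standardised Pearson residuals with the bias-adjusted
denominator φ(Σ_k m_k(m_k−1)/2 − p). The subject-level estimating
equations collapse exactly to cell-level sums (derived in the module
docstring). Two variance estimators are computed: the model-based
(working-covariance) variance and the Liang–Zeger sandwich. **The default
Wald test uses the model-based variance.** This was a deliberate choice:
the study this package reproduces describes estimating "the parameters and
their variances" through the exchangeable working structure, and only the
model-based choice reproduces its published GEE power values (the sandwich
gives systematically higher power and type I error at 3 clusters — the
well-known small-sample downward bias of the robust estimator). Users
wanting the conventional robust test set `variance_estimator="robust"`.
P-values use the standard normal. The marginal estimate is also reported
after the conversion β̂₁* = β̂₁/(1−ρ) to the approximate cluster-specific
scale; inside the harness ρ is the scenario's known design ICC (the
natural choice in a simulation), with the estimated working α as the
real-data fallback. The conversion rescales estimate and SE identically,
so p-values are unaffected.

**Fixed effects.** Ordinary logistic regression with intercept, treatment,
time terms and M−1 cluster indicators, by IRLS on the binomial counts.
A coefficient passing |β| > 15 on the logit scale is declared separated
(e.g. a cluster with no events), reported as converged = false. The Wald
test squares the statistic against chi-squared(1) with the model-based SE.

**Cluster summaries.** The cell proportions π_jk = events/n are modelled
by a linear mixed model with a cluster random intercept, fitted by REML.
Cells are unweighted — one row each, regardless of n_jk — matching the
method as used in practice, so β̂₁ is a risk difference. The REML
criterion is profiled down to a one-dimensional search over
λ = σ_u²/σ_e² (block-diagonal closed forms per cluster), with the λ = 0
boundary checked explicitly. Inference: Wald t with containment df
computed on cells (N_cells − rank([X Z])). A constant response returns
the exact degenerate solution (β̂₁ = 0, both variances 0, p undefined).
The model-based GLS standard error is reported; it can differ from
implementations that fold variance-parameter uncertainty into the SE by
a few per cent.

### Evaluation metrics

Per cent bias is 100(mean β̂₁ − β₁)/β₁ on each method's own scale: the
true conditional log OR for GLMM and fixed effects, the converted GEE
estimate against the same target, and the risk difference
expit(logit(μ) + β₁) − μ (0.1 for the three-step grid, ≈0.05 for the
six-step grid) for cluster summaries. Rejection uses strict p < 0.05; the
rate's MC standard error is √(r(1−r)/n_converged).

## Known behaviour and limitations

- The cluster-summary risk-difference estimator is genuinely biased under
  this generator: with a time trend present and linearly adjusted it
  overestimates by ≈ +20% at ICC 0.01, and even without a time trend a
  small negative gap (≈ −2%) remains from the nonlinearity of the
  logistic link averaged over the beta-distributed baselines. Tests that
  assert "recovery" for this method therefore sit close to their MC
  tolerance by nature.
- The GEE's sandwich variance is anti-conservative below ~40 clusters;
  no small-sample sandwich corrections are implemented.
- Convergence-failure *counts* are optimiser-specific. The package's
  failure patterns match the published study qualitatively (failures
  concentrate at 3 clusters with 5-subject cells; none at ≥18 clusters
  with ≥50-subject cells), but exact counts depend on convergence
  criteria and are not comparable across software.
- Scope: cross-sectional designs only (no subject-level serial
  correlation), equal cell sizes, no missing data, linear-in-logit true
  time trends, exchangeable within-cluster correlation, no additional
  random effects. Kenward–Roger/Satterthwaite df and bias-corrected
  sandwich estimators are out of scope.
- What passing simulations show is internal consistency under this
  generator's assumptions; real trials with unequal clusters,
  autoregressive correlation or nonlinear secular trends can behave
  differently, and none of the methods here is guaranteed to hold its
  level in those settings.
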