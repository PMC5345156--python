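"""Candidate analysis methods for stepped wedge trials with binary outcomes.

Four estimators, all sklearn-style (``fit`` + trailing-underscore fitted
attributes):

- :class:`RandomInterceptLogisticGLMM` — conditional log odds ratio,
  adaptive Gauss-Hermite quadrature, containment-df t-test.
- :class:`ExchangeableLogisticGEE` — marginal log odds ratio, sandwich
  variance, normal-reference Wald test, with a marginal-to-conditional
  conversion beta1/(1 - rho).
- :class:`FixedEffectsLogistic` — log odds ratio with cluster fixed
  effects, 1-df chi-squared Wald test.
- :class:`ClusterSummaryLMM` — risk difference from a linear mixed model
  on cell proportions, containment-df t-test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .base import (
    FitResult,
    as_cells,
    build_design,
    containment_df,
    marginal_to_conditional,
    wald_test,
)
from .gee import ExchangeableLogisticGEE
from .glm import FixedEffectsLogistic, fit_binomial_irls
from .glmm import RandomInterceptLogisticGLMM
from .lmm import ClusterSummaryLMM

METHODS = ("glmm", "gee", "fixed_effects", "cluster_summaries")

_ESTIMATORS = {
    "glmm": RandomInterceptLogisticGLMM,
    "gee": ExchangeableLogisticGEE,
    "fixed_effects": FixedEffectsLogistic,
    "cluster_summaries": ClusterSummaryLMM,
}


@dataclass(frozen=True)
class ModelSpec:
    """Choice of analysis method and its time adjustment.

    ``conversion_icc`` feeds the GEE marginal-to-conditional conversion;
    None means use the estimated working correlation.
    """

    method: str = "glmm"
    time_adjustment: str = "linear"
    conversion_icc: Optional[float] = None

    def __post_init__(self):
        if self.method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}")

    def make_estimator(self):
        cls = _ESTIMATORS[self.method]
        if self.method == "gee":
            return cls(time_adjustment=self.time_adjustment,
                       conversion_icc=self.conversion_icc)
        return cls(time_adjustment=self.time_adjustment)


def fit_method(data, spec: ModelSpec) -> FitResult:
    """Fit one analysis method to one trial dataset."""
    return spec.make_estimator().fit(data).to_result()


def fit_glmm(data, spec: Optional[ModelSpec] = None) -> FitResult:
    spec = spec or ModelSpec("glmm")
    return fit_method(data, ModelSpec("glmm", spec.time_adjustment))


def fit_gee(data, spec: Optional[ModelSpec] = None) -> FitResult:
    spec = spec or ModelSpec("gee")
    return fit_method(data, ModelSpec("gee", spec.time_adjustment,
                                      spec.conversion_icc))


def fit_fixed_effects(data, spec: Optional[ModelSpec] = None) -> FitResult:
    spec = spec or ModelSpec("fixed_effects")
    return fit_method(data, ModelSpec("fixed_effects", spec.time_adjustment))


def fit_cluster_lmm(data, spec: Optional[ModelSpec] = None) -> FitResult:
    spec = spec or ModelSpec("cluster_summaries")
    return fit_method(data, ModelSpec("cluster_summaries", spec.time_adjustment))


__all__ = [
    "METHODS",
    "ModelSpec",
    "FitResult",
    "RandomInterceptLogisticGLMM",
    "ExchangeableLogisticGEE",
    "FixedEffectsLogistic",
    "ClusterSummaryLMM",
    "fit_method",
    "fit_glmm",
    "fit_gee",
    "fit_fixed_effects",
    "fit_cluster_lmm",
    "fit_binomial_irls",
    "as_cells",
    "build_design",
    "containment_df",
    "marginal_to_conditional",
    "wald_test",
]
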