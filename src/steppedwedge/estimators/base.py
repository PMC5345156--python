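"""Shared machinery for the four candidate analysis methods.

All estimators operate on the cluster-period cell table (columns
``cluster, period, treatment, n, events``); subjects within a cell are
exchangeable so aggregated binomial counts carry the full likelihood.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

REQUIRED_COLUMNS = ("cluster", "period", "treatment", "n", "events")


@dataclass
class FitResult:
    """Flat record of one fitted intervention-effect analysis.

    ``estimate`` is the intervention effect on ``scale`` ("log-odds" for
    the GLMM, GEE and fixed-effects methods, "risk-difference" for the
    cluster-summary LMM). ``estimate_conditional`` carries the GEE
    marginal-to-conditional conversion beta1/(1 - rho) where applicable.
    """

    method: str
    estimate: float
    scale: str
    se: float
    df: float
    p_value: float
    converged: bool
    sigma_u: Optional[float] = None
    estimate_conditional: Optional[float] = None
    time_adjustment: str = "linear"
    n_obs: int = 0
    message: str = ""

    def to_dict(self) -> dict:
        return asdict(self)


def as_cells(data) -> pd.DataFrame:
    """Coerce a TrialDataset or DataFrame to a validated, ordered cell table."""
    cells = getattr(data, "cells", data)
    if not isinstance(cells, pd.DataFrame):
        raise TypeError("expected a TrialDataset or a cell-table DataFrame")
    missing = [c for c in REQUIRED_COLUMNS if c not in cells.columns]
    if missing:
        raise ValueError(f"cell table is missing columns {missing}")
    cells = cells.sort_values(["cluster", "period"], kind="stable").reset_index(
        drop=True
    )
    if (cells["events"] < 0).any() or (cells["events"] > cells["n"]).any():
        raise ValueError("event counts must lie in [0, n]")
    return cells


def time_columns(period: np.ndarray, time_adjustment: str) -> tuple[np.ndarray, list]:
    """Design columns for the period effect.

    linear: a single column equal to the period index j; categorical:
    periods - 1 indicators I(j = 1) ... I(j = J-1) with period 0 as
    reference; none: no columns.
    """
    if time_adjustment == "none":
        return np.empty((len(period), 0)), []
    if time_adjustment == "linear":
        return period.astype(float)[:, None], ["period"]
    if time_adjustment == "categorical":
        levels = np.unique(period)
        cols = [(period == lev).astype(float) for lev in levels[1:]]
        names = [f"period_{lev}" for lev in levels[1:]]
        if not cols:
            return np.empty((len(period), 0)), []
        return np.column_stack(cols), names
    raise ValueError(f"unknown time_adjustment {time_adjustment!r}")


def build_design(
    cells: pd.DataFrame,
    time_adjustment: str = "linear",
    cluster_effects: bool = False,
) -> tuple[np.ndarray, list]:
    """Fixed-effects design matrix: intercept, treatment, time terms and,
    optionally, M - 1 cluster indicators (first cluster as reference)."""
    n = len(cells)
    period = cells["period"].to_numpy()
    tcols, tnames = time_columns(period, time_adjustment)
    blocks = [np.ones((n, 1)), cells["treatment"].to_numpy(float)[:, None], tcols]
    names = ["intercept", "treatment"] + tnames
    if cluster_effects:
        clusters = np.unique(cells["cluster"])
        dummies = np.column_stack(
            [(cells["cluster"] == c).astype(float) for c in clusters[1:]]
        ) if len(clusters) > 1 else np.empty((n, 0))
        blocks.append(dummies)
        names += [f"cluster_{c}" for c in clusters[1:]]
    return np.column_stack(blocks), names


def cluster_indicator_matrix(cells: pd.DataFrame) -> np.ndarray:
    clusters = np.unique(cells["cluster"])
    return (cells["cluster"].to_numpy()[:, None] == clusters[None, :]).astype(float)


def containment_df(data, time_adjustment: str = "linear", per_subject: bool = True) -> float:
    """Containment degrees of freedom for effects varying within clusters.

    The treatment and time effects are not contained in the cluster random
    intercept, so their t-test degrees of freedom are
    ``N_obs - rank([X Z])`` where X is the fixed-effects design, Z the
    cluster-indicator random-effect design and N_obs the number of
    modelled rows: subjects for a subject-level model (``per_subject``),
    cluster-period cells for the cluster-summary model.
    """
    cells = as_cells(data)
    x, _ = build_design(cells, time_adjustment)
    z = cluster_indicator_matrix(cells)
    rank = np.linalg.matrix_rank(np.hstack([x, z]))
    n_obs = int(cells["n"].sum()) if per_subject else len(cells)
    df = n_obs - rank
    if df <= 0:
        raise ValueError(
            f"containment df is non-positive (N_obs={n_obs}, rank={rank}); "
            "the design has no residual degrees of freedom"
        )
    return float(df)


def wald_test(
    estimate: float,
    se: float,
    reference: str = "normal",
    df: Optional[float] = None,
) -> float:
    """Two-sided Wald p-value of estimate/se.

    reference: "normal" (standard normal), "t" (t with ``df`` degrees of
    freedom) or "chisq1" (the squared statistic against chi-squared(1),
    identical in value to the normal reference).
    """
    if not se > 0:
        raise ValueError(f"standard error must be positive, got {se}")
    z = estimate / se
    if reference == "normal":
        return float(2.0 * stats.norm.sf(abs(z)))
    if reference == "t":
        if df is None or df <= 0:
            raise ValueError("t reference requires positive df")
        return float(2.0 * stats.t.sf(abs(z), df))
    if reference == "chisq1":
        return float(stats.chi2.sf(z * z, 1))
    raise ValueError(f"unknown reference distribution {reference!r}")


def marginal_to_conditional(beta1_marginal: float, icc: float) -> float:
    """Inflate a marginal (population-average) log odds ratio to the
    approximate cluster-specific one: beta1* = beta1 / (1 - rho)."""
    if not 0.0 <= icc < 1.0:
        raise ValueError(f"icc must be in [0, 1), got {icc}")
    return beta1_marginal / (1.0 - icc)
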