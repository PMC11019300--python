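"""Moderator analyses: subgroup contrasts and weighted meta-regression.

Subgroup analysis pools the effects within each level of a categorical
moderator and tests for between-level differences with the fixed-effect
Q partition: with ``W_g`` the summed inverse-variance weights of level g and
``b_g`` its pooled estimate,

    Q_between = sum_g W_g * (b_g - b_overall)^2

is chi-square with ``m - 1`` degrees of freedom under the null of equal
level effects, and ``Q_total = Q_between + sum_g Q_within_g`` exactly under
the shared fixed-effect weights.

Meta-regression fits weighted least squares of the log response ratio on an
intercept plus one covariate (here, years of livestock exclusion).  With
known sampling variances the coefficient covariance is ``(X' W X)^{-1}``
(not rescaled by a residual mean square).  The method-of-moments variant
adds a residual between-effect variance tau^2 to every sampling variance
before weighting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd
from scipy import stats

from .errors import AnalysisError
from .pooling import PooledResult, Z_95, pool, pool_fixed

__all__ = [
    "SubgroupLevel",
    "SubgroupResult",
    "MetaRegressionResult",
    "subgroup_analysis",
    "meta_regression",
    "cross_response_regression",
]


@dataclass(frozen=True)
class SubgroupLevel:
    level: str
    n: int
    pooled: PooledResult
    flagged_small: bool  # n == 1: pooled but not meaningfully heterogeneous

    def to_dict(self) -> dict[str, Any]:
        return {
            "level": self.level,
            "n": self.n,
            "pooled": self.pooled.to_dict(),
            "flagged_small": self.flagged_small,
        }


@dataclass(frozen=True)
class SubgroupResult:
    response_variable: str
    moderator: str
    levels: list[SubgroupLevel]
    Q_between: float
    df_between: int
    p_subgroup: float
    model: str

    def to_dict(self) -> dict[str, Any]:
        return {
            "response_variable": self.response_variable,
            "moderator": self.moderator,
            "levels": [lv.to_dict() for lv in self.levels],
            "Q_between": self.Q_between,
            "df_between": self.df_between,
            "p_subgroup": self.p_subgroup,
            "model": self.model,
        }


@dataclass(frozen=True)
class MetaRegressionResult:
    response_variable: str
    covariate: str
    k: int
    intercept: float
    intercept_se: float
    intercept_ci: tuple[float, float]
    slope: float
    slope_se: float
    slope_ci: tuple[float, float]
    p_slope: float
    QM: float
    QE: float
    tau2: float
    method: str

    @property
    def significant(self) -> bool:
        """Slope p < .05 and its 95% CI excludes zero."""
        return self.p_slope < 0.05 and (self.slope_ci[0] > 0 or self.slope_ci[1] < 0)

    def to_dict(self) -> dict[str, Any]:
        return {
            "response_variable": self.response_variable,
            "covariate": self.covariate,
            "k": self.k,
            "intercept": self.intercept,
            "intercept_se": self.intercept_se,
            "intercept_ci": list(self.intercept_ci),
            "slope": self.slope,
            "slope_se": self.slope_se,
            "slope_ci": list(self.slope_ci),
            "p_slope": self.p_slope,
            "QM": self.QM,
            "QE": self.QE,
            "tau2": self.tau2,
            "method": self.method,
            "significant": self.significant,
        }


def subgroup_analysis(
    effects: pd.DataFrame, moderator: str, model: str = "fixed"
) -> SubgroupResult:
    """Pool within each level of ``moderator`` and test between-level
    differences with the fixed-effect Q partition.

    Rows with a missing moderator value are dropped with a warning (real
    extraction tables do not always classify every comparison).  Levels
    reduced to zero rows are dropped likewise; a single observed level is an
    error.  Levels with n == 1 are pooled but flagged.
    """
    if moderator not in effects.columns:
        raise AnalysisError(f"moderator column {moderator!r} not in effect table")
    mask = effects[moderator].notna()
    if (~mask).any():
        warnings.warn(
            f"dropping {(~mask).sum()} effect(s) with missing {moderator!r}",
            stacklevel=2,
        )
    sub = effects[mask]
    if sub.empty:
        raise AnalysisError(f"no effects with observed {moderator!r}")
    levels = sorted(sub[moderator].unique())
    if len(levels) < 2:
        raise AnalysisError(
            f"subgroup analysis needs >=2 observed levels of {moderator!r}, "
            f"found {levels}"
        )
    out_levels = []
    ests, Ws = [], []
    for lv in levels:
        grp = sub[sub[moderator] == lv]
        pooled = pool(grp, model) if not (model == "random" and len(grp) < 2) else pool(grp, "fixed")
        if model == "fixed":
            # exact Q partition under the shared fixed-effect weights
            ests.append(pool_fixed(grp).estimate)
            Ws.append((1.0 / grp["variance"].to_numpy()).sum())
        else:
            # mixed-effects variant: separate per-subgroup tau^2 in the weights
            ests.append(pooled.estimate)
            Ws.append(1.0 / pooled.se**2)
        out_levels.append(
            SubgroupLevel(
                level=str(lv), n=len(grp), pooled=pooled, flagged_small=len(grp) == 1
            )
        )
    ests_a, Ws_a = np.asarray(ests), np.asarray(Ws)
    overall_est = (Ws_a * ests_a).sum() / Ws_a.sum()
    Q_between = float((Ws_a * (ests_a - overall_est) ** 2).sum())
    df_between = len(levels) - 1
    p = float(stats.chi2.sf(Q_between, df_between))
    rv = sub["response_variable"].unique()
    return SubgroupResult(
        response_variable=rv[0] if len(rv) == 1 else "mixed",
        moderator=moderator,
        levels=out_levels,
        Q_between=float(Q_between),
        df_between=df_between,
        p_subgroup=p,
        model=model,
    )


def _mom_tau2(y: np.ndarray, v: np.ndarray, X: np.ndarray) -> float:
    """Method-of-moments residual tau^2 for a weighted regression design.

    Generalises DerSimonian-Laird to p > 1 columns:
    ``tau^2 = max(0, (QE - (k - p)) / (tr(W) - tr((X'WX)^{-1} X'W^2X)))``
    with W = diag(1/v) and QE the weighted residual sum of squares of the
    fixed-weights fit.
    """
    w = 1.0 / v
    W = np.diag(w)
    XtWX = X.T @ W @ X
    XtWX_inv = np.linalg.inv(XtWX)
    beta = XtWX_inv @ (X.T @ (w * y))
    resid = y - X @ beta
    QE = float((w * resid**2).sum())
    k, p = X.shape
    denom = w.sum() - np.trace(XtWX_inv @ (X.T @ np.diag(w**2) @ X))
    if denom <= 0:
        return 0.0
    return max(0.0, (QE - (k - p)) / denom)


def meta_regression(
    effects: pd.DataFrame,
    covariate: str,
    method: str = "fixed_wls",
    response_variable: str | None = None,
) -> MetaRegressionResult:
    """Weighted least squares of the log response ratio on one covariate.

    Parameters
    ----------
    effects
        Effect table with columns ``lrr``, ``variance`` and ``covariate``.
    covariate
        Name of a numeric column (e.g. ``duration_years``).
    method
        ``"fixed_wls"`` — weights 1/v with coefficient covariance
        ``(X'WX)^{-1}``; ``"mixed_mom"`` — add a method-of-moments residual
        tau^2 to every variance first.
    """
    if method not in ("fixed_wls", "mixed_mom"):
        raise AnalysisError(f"unknown meta-regression method {method!r}")
    if covariate not in effects.columns:
        raise AnalysisError(f"covariate column {covariate!r} not in effect table")
    y = effects["lrr"].to_numpy(dtype=float)
    v = effects["variance"].to_numpy(dtype=float)
    x = effects[covariate].to_numpy(dtype=float)
    k = y.size
    if k < 3:
        raise AnalysisError(f"meta-regression requires k >= 3 effects, got {k}")
    if np.unique(x).size < 2:
        raise AnalysisError(
            f"covariate {covariate!r} is constant; the design is rank-deficient"
        )
    if np.any(v <= 0):
        raise AnalysisError("all sampling variances must be > 0")
    X = np.column_stack([np.ones(k), x])
    tau2 = _mom_tau2(y, v, X) if method == "mixed_mom" else 0.0
    w = 1.0 / (v + tau2)
    XtWX = X.T @ (w[:, None] * X)
    cov = np.linalg.inv(XtWX)
    beta = cov @ (X.T @ (w * y))
    se = np.sqrt(np.diag(cov))
    resid = y - X @ beta
    QE = float((w * resid**2).sum())
    # QM: weighted model sum of squares about the weighted grand mean.
    ybar = (w * y).sum() / w.sum()
    QM = float((w * (X @ beta - ybar) ** 2).sum())
    z = beta[1] / se[1]
    p_slope = float(2.0 * stats.norm.sf(abs(z)))
    rv = effects["response_variable"].unique() if "response_variable" in effects else []
    return MetaRegressionResult(
        response_variable=(
            response_variable
            if response_variable is not None
            else (rv[0] if len(rv) == 1 else "mixed")
        ),
        covariate=covariate,
        k=k,
        intercept=float(beta[0]),
        intercept_se=float(se[0]),
        intercept_ci=(float(beta[0] - Z_95 * se[0]), float(beta[0] + Z_95 * se[0])),
        slope=float(beta[1]),
        slope_se=float(se[1]),
        slope_ci=(float(beta[1] - Z_95 * se[1]), float(beta[1] + Z_95 * se[1])),
        p_slope=p_slope,
        QM=QM,
        QE=QE,
        tau2=float(tau2),
        method=method,
    )


def cross_response_regression(
    effects_y: pd.DataFrame,
    effects_x: pd.DataFrame,
    join_on: str = "comparison_id",
    method: str = "fixed_wls",
    min_pairs: int = 5,
) -> MetaRegressionResult:
    """Regress one response variable's LRR on another's across comparisons
    where both were measured.

    The two effect tables are inner-joined on ``join_on``; the outcome
    table's sampling variances provide the weights.  Refuses to fit when
    fewer than ``min_pairs`` joined pairs exist — a handful of points cannot
    support a weighted regression slope.
    """
    yl = effects_y["response_variable"].unique()
    xl = effects_x["response_variable"].unique()
    xname = f"lrr_{xl[0] if len(xl) == 1 else 'x'}"
    joined = effects_y.merge(
        effects_x[[join_on, "lrr"]].rename(columns={"lrr": xname}),
        on=join_on,
        how="inner",
    )
    n = len(joined)
    if n < min_pairs:
        raise AnalysisError(
            f"only {n} joined pairs on {join_on!r}; need at least {min_pairs} "
            "for a cross-response regression (sample size too small)"
        )
    return meta_regression(
        joined, xname, method=method,
        response_variable=yl[0] if len(yl) == 1 else "y",
    )
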