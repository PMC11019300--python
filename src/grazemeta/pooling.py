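"""Inverse-variance pooling of log response ratios.

The fixed-effect (common-effect) summary is the inverse-variance weighted
mean

    RR++ = sum(w_i * y_i) / sum(w_i),   w_i = 1 / v_i

with weighted standard error ``S(RR++) = sqrt(1 / sum(w_i))`` and a 95%
confidence interval ``RR++ +/- 1.96 * S(RR++)``.  Heterogeneity is measured
by Cochran's Q, ``Q = sum(w_i * (y_i - RR++)^2)``, compared to a chi-square
with ``k - 1`` degrees of freedom, and summarised by Higgins & Thompson's

    I^2 = max(0, (Q - df) / Q) * 100   (percent).

The random-effects variant estimates the between-comparison variance tau^2
by the DerSimonian-Laird moment estimator and re-pools with weights
``1 / (v_i + tau^2)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Any

import numpy as np
from scipy import stats

from .errors import AnalysisError
from .effect_sizes import percent_change

__all__ = [
    "PooledResult",
    "pool_fixed",
    "pool_random",
    "heterogeneity",
    "pool",
]

#: Normal critical value used for all 95% intervals, as conventionally printed.
Z_95 = 1.96


@dataclass(frozen=True)
class PooledResult:
    """Weighted summary of a set of log response ratios."""

    estimate: float
    se: float
    ci_low: float
    ci_high: float
    z: float
    p: float
    k: int
    Q: float
    df: int
    I2: float
    tau2: float
    model: str
    percent_change: float

    @property
    def significant(self) -> bool:
        """Both conditions: p < .05 and the 95% CI excludes zero."""
        return self.p < 0.05 and (self.ci_low > 0 or self.ci_high < 0)

    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        d["significant"] = self.significant
        return d


def _extract(effects) -> tuple[np.ndarray, np.ndarray]:
    """Accept an effect-size DataFrame (columns lrr, variance) or a pair of
    array-likes ``(lrr, variance)``."""
    if hasattr(effects, "columns"):
        y = effects["lrr"].to_numpy(dtype=float)
        v = effects["variance"].to_numpy(dtype=float)
    else:
        y, v = effects
        y = np.asarray(y, dtype=float)
        v = np.asarray(v, dtype=float)
    if y.size == 0:
        raise AnalysisError("cannot pool an empty set of effects")
    if np.any(~np.isfinite(y)) or np.any(~np.isfinite(v)):
        raise AnalysisError("effects contain non-finite lrr or variance")
    if np.any(v <= 0):
        raise AnalysisError(
            "all sampling variances must be > 0 for inverse-variance pooling; "
            "zero-variance records cannot be weighted (check dispersion imputation)"
        )
    return y, v


def _summary(y, v, w, model, tau2) -> PooledResult:
    sw = w.sum()
    est = float((w * y).sum() / sw)
    se = float(np.sqrt(1.0 / sw))
    z = est / se
    p = 2.0 * stats.norm.sf(abs(z))
    # Q and I^2 always refer to the fixed-effect weights of the pooled set.
    wf = 1.0 / v
    mf = (wf * y).sum() / wf.sum()
    Q = float((wf * (y - mf) ** 2).sum())
    df = y.size - 1
    I2 = max(0.0, (Q - df) / Q) * 100.0 if Q > 0 else 0.0
    return PooledResult(
        estimate=est,
        se=se,
        ci_low=est - Z_95 * se,
        ci_high=est + Z_95 * se,
        z=float(z),
        p=float(p),
        k=int(y.size),
        Q=Q,
        df=df,
        I2=I2,
        tau2=float(tau2),
        model=model,
        percent_change=percent_change(est),
    )


def pool_fixed(effects) -> PooledResult:
    """Fixed-effect (common-effect) inverse-variance pooled estimate."""
    y, v = _extract(effects)
    return _summary(y, v, 1.0 / v, "fixed", 0.0)


def dersimonian_laird_tau2(y: np.ndarray, v: np.ndarray) -> float:
    """DerSimonian-Laird moment estimator of the between-effect variance.

    ``tau^2 = max(0, (Q - df) / C)`` with ``C = sum(w) - sum(w^2)/sum(w)``
    computed from the fixed-effect weights ``w = 1/v``.
    """
    w = 1.0 / v
    sw = w.sum()
    m = (w * y).sum() / sw
    Q = (w * (y - m) ** 2).sum()
    df = y.size - 1
    C = sw - (w**2).sum() / sw
    if C <= 0:
        return 0.0
    return float(max(0.0, (Q - df) / C))


def pool_random(effects) -> PooledResult:
    """DerSimonian-Laird random-effects pooled estimate.

    Requires k >= 2 (tau^2 is not estimable from one effect)."""
    y, v = _extract(effects)
    if y.size < 2:
        raise AnalysisError("random-effects pooling requires at least 2 effects")
    tau2 = dersimonian_laird_tau2(y, v)
    return _summary(y, v, 1.0 / (v + tau2), "random", tau2)


def pool(effects, model: str = "fixed") -> PooledResult:
    """Dispatch to :func:`pool_fixed` or :func:`pool_random`."""
    if model == "fixed":
        return pool_fixed(effects)
    if model == "random":
        return pool_random(effects)
    raise AnalysisError(f"unknown pooling model {model!r}; use 'fixed' or 'random'")


def heterogeneity(effects) -> tuple[float, int, float, float]:
    """Cochran's Q, its degrees of freedom, I^2 (percent) and the chi-square p.

    Returns ``(Q, df, I2, p)``; requires k >= 2.
    """
    y, v = _extract(effects)
    if y.size < 2:
        raise AnalysisError("heterogeneity requires at least 2 effects")
    w = 1.0 / v
    m = (w * y).sum() / w.sum()
    Q = float((w * (y - m) ** 2).sum())
    df = y.size - 1
    I2 = max(0.0, (Q - df) / Q) * 100.0 if Q > 0 else 0.0
    p = float(stats.chi2.sf(Q, df))
    return Q, df, I2, p
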