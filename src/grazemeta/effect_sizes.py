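"""Log response ratio effect sizes for grazed-vs-excluded comparisons.

The effect size used throughout is the log response ratio

    LRR = ln(Xt / Xc)

where ``Xt`` is the mean of the response variable under livestock exclusion
(treatment) and ``Xc`` the mean under continued grazing (control).  Its
sampling variance, from the delta method under within-arm normality, is

    v = st^2 / (nt * Xt^2) + sc^2 / (nc * Xc^2)

with ``s`` the arm standard deviations and ``n`` the arm sample sizes.  The
inverse-variance weight ``w = 1/v`` feeds the pooling stage.  A significant
pooled log ratio ``b`` is reported on the percent scale as
``(exp(b) - 1) * 100``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import AnalysisError, ValidationError

__all__ = [
    "lrr",
    "lrr_variance",
    "percent_change",
    "compute_effects",
    "EFFECT_COLUMNS",
]

#: Moderator columns carried from the comparison table into the effect table.
MODERATOR_COLUMNS = [
    "duration_years",
    "climatic_zone",
    "grazing_intensity",
    "grazing_history",
    "herbivore_type",
    "grassland_type",
]

EFFECT_COLUMNS = [
    "comparison_id",
    "study_id",
    "response_variable",
    "lrr",
    "variance",
    "weight",
] + MODERATOR_COLUMNS


def lrr(mean_excl, mean_graz):
    """Log response ratio ``ln(mean_excl / mean_graz)``.

    Parameters
    ----------
    mean_excl, mean_graz
        Arm means (scalar or array).  Both must be strictly positive: a
        ratio-scale effect size is undefined at or below zero.
    """
    xt = np.asarray(mean_excl, dtype=float)
    xc = np.asarray(mean_graz, dtype=float)
    if np.any(xt <= 0) or np.any(xc <= 0):
        raise ValidationError("lrr requires strictly positive arm means")
    out = np.log(xt / xc)
    return out.item() if out.ndim == 0 else out


def lrr_variance(sd_excl, n_excl, mean_excl, sd_graz, n_graz, mean_graz):
    """Delta-method sampling variance of the log response ratio.

    ``v = st^2/(nt*Xt^2) + sc^2/(nc*Xc^2)``; zero only when both arm SDs
    are zero.
    """
    st = np.asarray(sd_excl, dtype=float)
    sc = np.asarray(sd_graz, dtype=float)
    nt = np.asarray(n_excl, dtype=float)
    nc = np.asarray(n_graz, dtype=float)
    xt = np.asarray(mean_excl, dtype=float)
    xc = np.asarray(mean_graz, dtype=float)
    if np.any(xt <= 0) or np.any(xc <= 0):
        raise ValidationError("lrr_variance requires strictly positive arm means")
    if np.any(nt < 1) or np.any(nc < 1):
        raise ValidationError("lrr_variance requires arm sample sizes >= 1")
    if np.any(st < 0) or np.any(sc < 0):
        raise ValidationError("lrr_variance requires non-negative arm SDs")
    out = st**2 / (nt * xt**2) + sc**2 / (nc * xc**2)
    return out.item() if out.ndim == 0 else out


def percent_change(estimate):
    """Back-transform a pooled log ratio to percent change: ``(e^b - 1)*100``."""
    out = (np.exp(np.asarray(estimate, dtype=float)) - 1.0) * 100.0
    return out.item() if out.ndim == 0 else out


def compute_effects(
    comparisons: pd.DataFrame, small_sample_correction: bool = False
) -> pd.DataFrame:
    """Build the effect-size table from an imputed comparison table.

    Parameters
    ----------
    comparisons
        Long-format comparison table (one row per comparison x response
        variable) with both SD fields populated — run
        :func:`grazemeta.data_io.impute_dispersion` first.
    small_sample_correction
        If True, apply the second-order Taylor correction for the small-
        sample bias of the log of a sample mean,
        ``LRR + st^2/(2*nt*Xt^2) - sc^2/(2*nc*Xc^2)``.  Off by default: the
        plain ratio is the conventional estimator for this literature.

    Returns
    -------
    DataFrame with columns ``comparison_id, study_id, response_variable,
    lrr, variance, weight`` plus the moderator columns.
    """
    df = comparisons
    if df["sd_excl"].isna().any() or df["sd_graz"].isna().any():
        raise AnalysisError(
            "comparison table has missing SDs; apply impute_dispersion first"
        )
    y = lrr(df["mean_excl"].to_numpy(), df["mean_graz"].to_numpy())
    v = lrr_variance(
        df["sd_excl"].to_numpy(),
        df["n_excl"].to_numpy(),
        df["mean_excl"].to_numpy(),
        df["sd_graz"].to_numpy(),
        df["n_graz"].to_numpy(),
        df["mean_graz"].to_numpy(),
    )
    if small_sample_correction:
        y = y + 0.5 * (
            df["sd_excl"].to_numpy() ** 2
            / (df["n_excl"].to_numpy() * df["mean_excl"].to_numpy() ** 2)
            - df["sd_graz"].to_numpy() ** 2
            / (df["n_graz"].to_numpy() * df["mean_graz"].to_numpy() ** 2)
        )
    with np.errstate(divide="ignore"):
        w = np.where(v > 0, 1.0 / np.where(v > 0, v, 1.0), np.inf)
    out = pd.DataFrame(
        {
            "comparison_id": df["comparison_id"].to_numpy(),
            "study_id": df["study_id"].to_numpy(),
            "response_variable": df["response_variable"].to_numpy(),
            "lrr": np.atleast_1d(y),
            "variance": np.atleast_1d(v),
            "weight": np.atleast_1d(w),
        }
    )
    for col in MODERATOR_COLUMNS:
        out[col] = df[col].to_numpy() if col in df.columns else pd.NA
    return out
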