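"""End-to-end analysis pipeline: read -> impute -> harmonize -> effect
sizes -> pooling -> subgroups -> meta-regression -> sensitivity, with fixed
output layout and a manifest sufficient to re-run the identical analysis.
"""

from __future__ import annotations

import datetime
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .data_io import (
    RESPONSE_VARIABLES,
    harmonize_categories,
    impute_dispersion,
    read_comparisons,
    validation_report,
    write_comparisons,
)
from .effect_sizes import compute_effects
from .errors import AnalysisError, ConfigError, GrazemetaError
from .influence import exclude_and_refit, leave_one_out, metareg_fit, pooled_fit
from .moderators import cross_response_regression, meta_regression, subgroup_analysis
from .pooling import Z_95, pool_fixed, pool_random
from .synthetic_data import SyntheticConfig, default_paper_fixture, generate_comparisons

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    ``input_path`` may be a CSV path, the literal string ``"fixture"`` for
    the deterministic built-in table, or ``None`` with ``synthetic`` set.
    """

    input_path: str | None = "fixture"
    synthetic: SyntheticConfig | None = None
    response_variables: tuple[str, ...] = RESPONSE_VARIABLES
    model: str = "fixed"  # headline model: fixed | random
    moderators: tuple[str, ...] = ("climatic_zone", "grazing_intensity")
    covariates: tuple[str, ...] = ("duration_years",)
    metareg_method: str = "fixed_wls"
    cross_response: tuple[tuple[str, str], ...] = (
        ("species_richness", "aboveground_biomass"),
        ("shannon_diversity", "aboveground_biomass"),
    )
    min_cross_pairs: int = 5
    sensitivity_rule: str = "max-duration"
    influence_se_multiple: float = 1.0
    out_dir: str | Path = "grazemeta_out"
    seed: int = 0
    overwrite: bool = False


def _load(config: RunConfig) -> pd.DataFrame:
    if config.synthetic is not None:
        return generate_comparisons(config.synthetic)
    if config.input_path == "fixture" or config.input_path is None:
        return default_paper_fixture()
    return read_comparisons(config.input_path)


def _forest_table(effects: pd.DataFrame, pooled: dict) -> pd.DataFrame:
    rows = effects.assign(
        ci_low=effects["lrr"] - Z_95 * np.sqrt(effects["variance"]),
        ci_high=effects["lrr"] + Z_95 * np.sqrt(effects["variance"]),
        row_type="comparison",
    )[
        [
            "response_variable",
            "comparison_id",
            "study_id",
            "lrr",
            "variance",
            "weight",
            "ci_low",
            "ci_high",
            "row_type",
        ]
    ]
    summaries = []
    for var, models in pooled.items():
        for model, res in models.items():
            summaries.append(
                {
                    "response_variable": var,
                    "comparison_id": f"summary_{model}",
                    "study_id": "",
                    "lrr": res["estimate"],
                    "variance": res["se"] ** 2,
                    "weight": np.nan,
                    "ci_low": res["ci_low"],
                    "ci_high": res["ci_high"],
                    "row_type": f"summary_{model}",
                }
            )
    return pd.concat([rows, pd.DataFrame(summaries)], ignore_index=True)


def _bubble_table(effects_by_var: dict, metareg: dict, covariate: str) -> pd.DataFrame:
    """Plot-ready meta-regression export: one point per comparison (size
    proportional to weight) plus fitted-line and CI-band coordinates."""
    frames = []
    for var, eff in effects_by_var.items():
        res = metareg.get(var, {}).get(covariate)
        if res is None:
            continue
        pts = eff[["comparison_id", "lrr", "weight", covariate]].copy()
        pts["response_variable"] = var
        pts["row_type"] = "point"
        grid = np.linspace(eff[covariate].min(), eff[covariate].max(), 25)
        fit = res["intercept"] + res["slope"] * grid
        half = Z_95 * np.sqrt(
            res["intercept_se"] ** 2
            + (grid**2) * res["slope_se"] ** 2
        )
        line = pd.DataFrame(
            {
                "comparison_id": "",
                "lrr": fit,
                "weight": np.nan,
                covariate: grid,
                "response_variable": var,
                "row_type": "fit",
                "band_low": fit - half,
                "band_high": fit + half,
            }
        )
        frames.append(pts)
        frames.append(line)
    if not frames:
        return pd.DataFrame()
    return pd.concat(frames, ignore_index=True)


def run_pipeline(config: RunConfig) -> dict:
    """Execute every requested stage and write all exports; returns the
    manifest (also written as ``manifest.json``)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if (out / "manifest.json").exists() and not config.overwrite:
        raise ConfigError(
            f"output directory {out} already holds results; pass overwrite=True"
        )
    caught: list[str] = []
    with warnings.catch_warnings(record=True) as wrec:
        warnings.simplefilter("always")
        manifest = _run(config, out, caught)
        caught.extend(str(w.message) for w in wrec)
    manifest["warnings"] = caught
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest


def _run(config: RunConfig, out: Path, warnings_log: list[str]) -> dict:
    stage = "read"
    try:
        raw = _load(config)
        stage = "impute"
        imputed = impute_dispersion(raw)
        stage = "harmonize"
        clean = harmonize_categories(imputed)
        write_comparisons(clean, out / "comparisons_clean.csv")
        stage = "effect_sizes"
        effects = compute_effects(clean)
        for col in (*config.moderators, *config.covariates):
            if col not in effects.columns:
                raise ConfigError(
                    f"requested column {col!r} does not exist after harmonization"
                )
        effects.to_csv(out / "effects.csv", index=False)
        effects_by_var = {
            var: effects[effects["response_variable"] == var].reset_index(drop=True)
            for var in config.response_variables
            if (effects["response_variable"] == var).any()
        }
        for var in config.response_variables:
            if var not in effects_by_var:
                warnings_log.append(f"no comparisons for {var}; skipped")

        stage = "pooling"
        pooled = {
            var: {
                "fixed": pool_fixed(eff).to_dict(),
                "random": pool_random(eff).to_dict(),
            }
            for var, eff in effects_by_var.items()
        }
        with open(out / "pooled.json", "w") as fh:
            json.dump({"headline_model": config.model, "results": pooled}, fh, indent=2)
        _forest_table(effects, pooled).to_csv(out / "forest.csv", index=False)

        stage = "subgroups"
        subgroups: dict = {}
        for var, eff in effects_by_var.items():
            subgroups[var] = {}
            for mod in config.moderators:
                try:
                    subgroups[var][mod] = subgroup_analysis(
                        eff, mod, model=config.model
                    ).to_dict()
                except AnalysisError as exc:
                    subgroups[var][mod] = {"error": str(exc)}
                    warnings_log.append(f"subgroup {var}/{mod}: {exc}")
        with open(out / "subgroups.json", "w") as fh:
            json.dump(subgroups, fh, indent=2)

        stage = "meta_regression"
        metareg: dict = {}
        for var, eff in effects_by_var.items():
            metareg[var] = {}
            for cov in config.covariates:
                try:
                    metareg[var][cov] = meta_regression(
                        eff, cov, method=config.metareg_method
                    ).to_dict()
                except AnalysisError as exc:
                    metareg[var][cov] = {"error": str(exc)}
                    warnings_log.append(f"meta-regression {var}/{cov}: {exc}")
        cross: dict = {}
        for yvar, xvar in config.cross_response:
            key = f"{yvar}~{xvar}"
            if yvar in effects_by_var and xvar in effects_by_var:
                try:
                    cross[key] = cross_response_regression(
                        effects_by_var[yvar],
                        effects_by_var[xvar],
                        method=config.metareg_method,
                        min_pairs=config.min_cross_pairs,
                    ).to_dict()
                except AnalysisError as exc:
                    cross[key] = {"refused": str(exc)}
                    warnings_log.append(f"cross-response {key}: {exc}")
        with open(out / "metareg.json", "w") as fh:
            json.dump({"covariates": metareg, "cross_response": cross}, fh, indent=2)
        for cov in config.covariates:
            _bubble_table(effects_by_var, metareg, cov).to_csv(
                out / "bubble.csv", index=False
            )

        stage = "sensitivity"
        sensitivity: dict = {}
        for var, eff in effects_by_var.items():
            entry: dict = {}
            try:
                entry["leave_one_out_pooled"] = leave_one_out(
                    eff, pooled_fit(config.model), config.influence_se_multiple
                ).to_dict()
            except AnalysisError as exc:
                entry["leave_one_out_pooled"] = {"error": str(exc)}
            for cov in config.covariates:
                try:
                    entry[f"exclude_{config.sensitivity_rule}_{cov}"] = exclude_and_refit(
                        eff,
                        config.sensitivity_rule,
                        metareg_fit(cov, config.metareg_method),
                    ).to_dict()
                except AnalysisError as exc:
                    entry[f"exclude_{config.sensitivity_rule}_{cov}"] = {"error": str(exc)}
            sensitivity[var] = entry
        with open(out / "sensitivity.json", "w") as fh:
            json.dump(sensitivity, fh, indent=2)
    except GrazemetaError as exc:
        # keep the concrete error type; prefix the failing stage name
        raise type(exc)(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest = {
        "package_version": __version__,
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "seed": config.seed,
        "config": {
            "input_path": config.input_path,
            "synthetic": (
                None if config.synthetic is None else vars(config.synthetic)
            ),
            "response_variables": list(config.response_variables),
            "model": config.model,
            "moderators": list(config.moderators),
            "covariates": list(config.covariates),
            "metareg_method": config.metareg_method,
            "min_cross_pairs": config.min_cross_pairs,
            "sensitivity_rule": config.sensitivity_rule,
            "influence_se_multiple": config.influence_se_multiple,
        },
        "input_summary": validation_report(clean),
        "stage_row_counts": {
            "comparisons": int(len(raw)),
            "effects": int(len(effects)),
            **{f"effects_{v}": int(len(e)) for v, e in effects_by_var.items()},
        },
        "outputs": [
            "comparisons_clean.csv",
            "effects.csv",
            "pooled.json",
            "forest.csv",
            "subgroups.json",
            "metareg.json",
            "bubble.csv",
            "sensitivity.json",
            "manifest.json",
        ],
    }
    return manifest
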