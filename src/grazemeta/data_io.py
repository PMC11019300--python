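"""Read, validate and harmonize grazed-vs-excluded comparison tables.

The unit of analysis is one paired comparison: a fenced livestock-exclusion
plot against its adjacent grazed reference, measured for one response
variable (species richness, Shannon diversity or aboveground biomass).
Tables are long-format UTF-8 CSV, one header row, one row per
comparison x response variable.

Two harmonization steps mirror how such extraction tables are cleaned:

* **Dispersion imputation ladder** (per arm, in order of precedence):
  keep a reported SD; else reconstruct it from a reported SE as
  ``SD = SE * sqrt(n)``; else fall back to one tenth of the arm mean.
  Every imputed value carries a provenance flag (``reported_sd``,
  ``from_se``, ``tenth_of_mean``) so sensitivity analyses can down-weight
  or drop the crudest rung.

* **Categorical conversion**: qualitative intensity labels map onto the
  closed {low, moderate, high} vocabulary (``extensive`` -> low,
  ``overgrazing`` -> high); heterogeneous grassland names collapse to
  {tall_grassland, bofedal}; where the evolutionary grazing history is not
  stated it is derived from geography — camelid-dominated tropical sites
  have a long (millennial) grazing history, subtropical sites stocked with
  European livestock a short (<500 year) one.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import HarmonizationError, SchemaError, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "REQUIRED_COLUMNS",
    "RESPONSE_VARIABLES",
    "read_comparisons",
    "write_comparisons",
    "impute_dispersion",
    "harmonize_categories",
    "validation_report",
]

RESPONSE_VARIABLES = ("species_richness", "shannon_diversity", "aboveground_biomass")

#: Documented CSV schema, in column order.
REQUIRED_COLUMNS = [
    "comparison_id",
    "study_id",
    "response_variable",
    "mean_excl",
    "sd_excl",
    "se_excl",
    "n_excl",
    "mean_graz",
    "sd_graz",
    "se_graz",
    "n_graz",
    "duration_years",
    "climatic_zone",
    "grazing_intensity",
    "grazing_history",
    "herbivore_type",
    "grassland_type",
]

OPTIONAL_COLUMNS = ["dispersion_source_excl", "dispersion_source_graz"]

_NUMERIC = [
    "mean_excl",
    "sd_excl",
    "se_excl",
    "mean_graz",
    "sd_graz",
    "se_graz",
    "duration_years",
]
_INTEGER = ["n_excl", "n_graz"]

INTENSITY_MAP = {
    "low": "low",
    "moderate": "moderate",
    "high": "high",
    "extensive": "low",
    "overgrazing": "high",
}

GRASSLAND_MAP = {
    "tall_grassland": "tall_grassland",
    "bofedal": "bofedal",
    "pampa": "tall_grassland",
    "jarillal": "tall_grassland",
    "mountain grassland": "tall_grassland",
    "pastizal en filo": "tall_grassland",
    "meadow": "bofedal",
    "peatland": "bofedal",
}

CLIMATIC_ZONES = ("tropical", "subtropical")
HISTORY_LEVELS = ("short", "long")
CAMELID_LABELS = ("camelid", "llama", "alpaca", "vicuna")


def read_comparisons(path: str | Path) -> pd.DataFrame:
    """Read and validate a comparison CSV.

    Unknown columns are preserved untouched; row numbers (1-based data rows)
    are used in error messages.
    """
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"input file not found: {path}")
    df = pd.read_csv(
        path,
        dtype={"comparison_id": str, "study_id": str},
        float_precision="round_trip",  # bit-exact write->read for finite values
    )
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    if df.empty:
        logger.warning("comparison table %s is empty (header only)", path)
        return df
    for col in _NUMERIC:
        try:
            df[col] = pd.to_numeric(df[col], errors="raise")
        except (ValueError, TypeError) as exc:
            bad = pd.to_numeric(df[col], errors="coerce")
            rows = df.index[bad.isna() & df[col].notna()] + 1
            raise SchemaError(
                f"non-numeric value in column {col!r} at row(s) "
                f"{list(rows)}"
            ) from exc
    for col in _INTEGER:
        df[col] = pd.to_numeric(df[col], errors="coerce")
        if df[col].isna().any():
            rows = list(df.index[df[col].isna()] + 1)
            raise SchemaError(f"non-numeric value in column {col!r} at row(s) {rows}")
        df[col] = df[col].astype(int)
    _validate_values(df)
    return df


def _validate_values(df: pd.DataFrame) -> None:
    for col in ("mean_excl", "mean_graz"):
        bad = df.index[~(df[col] > 0)]
        if len(bad):
            raise ValidationError(
                f"{col} must be strictly positive; violated at row(s) "
                f"{list(bad + 1)} (log response ratios are undefined for "
                "non-positive means)"
            )
    for col in ("sd_excl", "sd_graz", "se_excl", "se_graz"):
        bad = df.index[df[col].notna() & (df[col] < 0)]
        if len(bad):
            raise ValidationError(f"{col} negative at row(s) {list(bad + 1)}")
    for col in _INTEGER:
        bad = df.index[df[col] < 1]
        if len(bad):
            raise ValidationError(f"{col} must be >= 1; violated at row(s) {list(bad + 1)}")
    bad = df.index[~np.isfinite(df["duration_years"]) | (df["duration_years"] < 0)]
    if len(bad):
        raise ValidationError(f"duration_years invalid at row(s) {list(bad + 1)}")
    unknown = set(df["response_variable"].dropna()) - set(RESPONSE_VARIABLES)
    if unknown:
        raise ValidationError(
            f"unknown response_variable value(s) {sorted(unknown)}; "
            f"accepted: {list(RESPONSE_VARIABLES)}"
        )


def write_comparisons(df: pd.DataFrame, path: str | Path) -> None:
    """Write a comparison table as UTF-8, comma-separated, period-decimal CSV."""
    cols = [c for c in REQUIRED_COLUMNS + OPTIONAL_COLUMNS if c in df.columns]
    cols += [c for c in df.columns if c not in cols]
    df.to_csv(path, index=False, columns=cols, encoding="utf-8")


def impute_dispersion(df: pd.DataFrame) -> pd.DataFrame:
    """Fill missing arm SDs by the fixed precedence ladder, with provenance.

    Per arm and per row: a present SD is kept (``reported_sd``); otherwise a
    present SE is scaled by that arm's own sqrt(n) (``from_se``); otherwise
    the SD is set to one tenth of the arm mean (``tenth_of_mean``).  The
    ladder always terminates, never touches means, sample sizes or
    moderators, and is idempotent.
    """
    out = df.copy()
    for arm in ("excl", "graz"):
        sd, se, n, mean = (f"sd_{arm}", f"se_{arm}", f"n_{arm}", f"mean_{arm}")
        src = f"dispersion_source_{arm}"
        if src in out.columns:
            flags = out[src].astype("object").copy()
        else:
            flags = pd.Series(pd.NA, index=out.index, dtype="object")
        has_sd = out[sd].notna()
        has_se = out[se].notna()
        flags[has_sd & flags.isna()] = "reported_sd"
        use_se = ~has_sd & has_se
        out.loc[use_se, sd] = out.loc[use_se, se] * np.sqrt(out.loc[use_se, n])
        flags[use_se] = "from_se"
        use_tenth = ~has_sd & ~has_se
        out.loc[use_tenth, sd] = out.loc[use_tenth, mean] / 10.0
        flags[use_tenth] = "tenth_of_mean"
        out[src] = flags
        for idx in out.index[use_se | use_tenth]:
            logger.info(
                "imputed %s for row %s (%s): %s", sd, idx + 1,
                out.at[idx, "comparison_id"] if "comparison_id" in out else "?",
                flags[idx],
            )
    return out


def harmonize_categories(df: pd.DataFrame) -> pd.DataFrame:
    """Map raw categorical labels onto the closed analysis vocabularies.

    Already-clean labels pass through unchanged (the function is
    idempotent).  An unmappable label raises with the accepted vocabulary.
    Missing grazing history is derived where geography determines it;
    otherwise it stays missing and is excluded from subgroup analyses of
    that moderator.
    """
    out = df.copy()

    def _map(col: str, mapping: dict[str, str], accepted: str) -> None:
        raw = out[col].astype("object")
        mapped = []
        for i, val in enumerate(raw):
            if pd.isna(val):
                mapped.append(pd.NA)
                continue
            key = str(val).strip().lower()
            if key not in mapping:
                raise HarmonizationError(
                    f"cannot harmonize {col}={val!r} at row {i + 1}; "
                    f"accepted: {accepted}"
                )
            mapped.append(mapping[key])
        out[col] = mapped

    _map(
        "grazing_intensity",
        INTENSITY_MAP,
        "low, moderate, high, extensive (->low), overgrazing (->high)",
    )
    _map("grassland_type", GRASSLAND_MAP, ", ".join(sorted(set(GRASSLAND_MAP))))
    _map(
        "climatic_zone",
        {z: z for z in CLIMATIC_ZONES},
        ", ".join(CLIMATIC_ZONES),
    )

    hist = out["grazing_history"].astype("object")
    for i in out.index:
        val = hist[i]
        if not pd.isna(val):
            key = str(val).strip().lower()
            if key not in HISTORY_LEVELS:
                raise HarmonizationError(
                    f"cannot harmonize grazing_history={val!r} at row {i + 1}; "
                    f"accepted: {', '.join(HISTORY_LEVELS)}"
                )
            hist[i] = key
            continue
        zone = out.at[i, "climatic_zone"]
        herb = out.at[i, "herbivore_type"]
        herb_key = str(herb).strip().lower() if not pd.isna(herb) else ""
        if zone == "tropical" and herb_key in CAMELID_LABELS:
            hist[i] = "long"
        elif zone == "subtropical":
            hist[i] = "short"
    out["grazing_history"] = hist
    return out


def validation_report(df: pd.DataFrame) -> dict:
    """JSON-serialisable summary of a (possibly imputed) comparison table."""
    rep: dict = {
        "n_rows": int(len(df)),
        "n_comparisons": int(df["comparison_id"].nunique()),
        "n_studies": int(df["study_id"].nunique()),
        "rows_per_response_variable": {
            k: int(v) for k, v in df["response_variable"].value_counts().items()
        },
        "duration_years": {
            "min": float(df["duration_years"].min()) if len(df) else None,
            "median": float(df["duration_years"].median()) if len(df) else None,
            "max": float(df["duration_years"].max()) if len(df) else None,
        },
    }
    for arm in ("excl", "graz"):
        src = f"dispersion_source_{arm}"
        if src in df.columns:
            rep[src] = {
                str(k): int(v) for k, v in df[src].value_counts(dropna=True).items()
            }
    return rep
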