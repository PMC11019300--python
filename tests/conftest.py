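import numpy as np
import pandas as pd
import pytest

from grazemeta import (
    compute_effects,
    default_paper_fixture,
    harmonize_categories,
    impute_dispersion,
)


@pytest.fixture(scope="session")
def fixture_raw() -> pd.DataFrame:
    return default_paper_fixture()


@pytest.fixture(scope="session")
def fixture_effects(fixture_raw) -> pd.DataFrame:
    return compute_effects(harmonize_categories(impute_dispersion(fixture_raw)))


@pytest.fixture(scope="session")
def richness_effects(fixture_effects) -> pd.DataFrame:
    return fixture_effects[
        fixture_effects["response_variable"] == "species_richness"
    ].reset_index(drop=True)


@pytest.fixture(scope="session")
def biomass_effects(fixture_effects) -> pd.DataFrame:
    return fixture_effects[
        fixture_effects["response_variable"] == "aboveground_biomass"
    ].reset_index(drop=True)


@pytest.fixture(scope="session")
def shannon_effects(fixture_effects) -> pd.DataFrame:
    return fixture_effects[
        fixture_effects["response_variable"] == "shannon_diversity"
    ].reset_index(drop=True)


def random_effects_frame(rng: np.random.Generator, k: int) -> pd.DataFrame:
    """Small randomized effect table for oracle-equivalence checks."""
    return pd.DataFrame(
        {
            "comparison_id": [f"c{i}" for i in range(k)],
            "response_variable": "species_richness",
            "lrr": rng.normal(0.0, 0.6, k),
            "variance": rng.uniform(0.003, 0.08, k),
            "duration_years": rng.uniform(0.0, 12.0, k),
            "group": rng.choice(["a", "b", "c"], k),
        }
    ).assign(weight=lambda d: 1.0 / d["variance"])
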