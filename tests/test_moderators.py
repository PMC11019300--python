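"""Subgroup contrasts, meta-regression and the cross-response regression,
checked against brute-force partition and linear-algebra oracles."""

import math
import warnings

import numpy as np
import pandas as pd
import pytest

from grazemeta import (
    AnalysisError,
    cross_response_regression,
    meta_regression,
    pool_fixed,
    subgroup_analysis,
)
from conftest import random_effects_frame


def brute_force_wls(y, x, w):
    """Solve the weighted normal equations directly (independent oracle)."""
    X = np.column_stack([np.ones(len(y)), x])
    A = X.T @ np.diag(w) @ X
    beta = np.linalg.solve(A, X.T @ np.diag(w) @ y)
    cov = np.linalg.inv(A)
    return beta, np.sqrt(np.diag(cov))


class TestSubgroupAnalysis:
    def test_identical_level_estimates_give_zero_q_between(self):
        eff = pd.DataFrame(
            {
                "comparison_id": list("abcd"),
                "response_variable": "species_richness",
                "lrr": [0.2, 0.2, 0.2, 0.2],
                "variance": [0.01, 0.03, 0.01, 0.03],
                "zone": ["t", "t", "s", "s"],
            }
        )
        res = subgroup_analysis(eff, "zone")
        assert res.Q_between == pytest.approx(0.0, abs=1e-12)
        assert res.p_subgroup == pytest.approx(1.0)

    def test_q_partition_identity_brute_force(self):
        rng = np.random.default_rng(23)
        for _ in range(60):
            eff = random_effects_frame(rng, int(rng.integers(6, 20)))
            if eff["group"].nunique() < 2:
                continue
            res = subgroup_analysis(eff, "group")
            Q_total = pool_fixed(eff).Q
            Q_within = sum(
                pool_fixed(eff[eff["group"] == g]).Q for g in eff["group"].unique()
            )
            assert res.Q_between == pytest.approx(Q_total - Q_within, abs=1e-8)

    def test_three_effect_hand_case(self):
        eff = pd.DataFrame(
            {
                "comparison_id": list("abc"),
                "response_variable": "species_richness",
                "lrr": [0.1, 0.3, 0.6],
                "variance": [0.02, 0.04, 0.05],
                "m": ["A", "A", "B"],
            }
        )
        res = subgroup_analysis(eff, "m")
        Q_total = pool_fixed(eff).Q
        Q_within = pool_fixed(eff[eff["m"] == "A"]).Q  # B has one effect: Q=0
        assert res.Q_between == pytest.approx(Q_total - Q_within, rel=1e-10)
        assert res.levels[1].flagged_small  # the n=1 level is flagged

    def test_fixture_richness_zone_sizes(self, richness_effects):
        res = subgroup_analysis(richness_effects, "climatic_zone")
        sizes = {lv.level: lv.n for lv in res.levels}
        assert sizes == {"subtropical": 11, "tropical": 4}
        assert sum(lv.n for lv in res.levels) == len(richness_effects)

    def test_fixture_biomass_intensity_sizes(self, biomass_effects):
        res = subgroup_analysis(biomass_effects, "grazing_intensity")
        assert {lv.level: lv.n for lv in res.levels} == {"high": 11, "low": 8}

    def test_single_level_is_error(self):
        eff = pd.DataFrame(
            {
                "comparison_id": list("ab"),
                "response_variable": "species_richness",
                "lrr": [0.1, 0.2],
                "variance": [0.01, 0.01],
                "m": ["A", "A"],
            }
        )
        with pytest.raises(AnalysisError):
            subgroup_analysis(eff, "m")

    def test_missing_moderator_rows_dropped_with_warning(self):
        eff = pd.DataFrame(
            {
                "comparison_id": list("abcd"),
                "response_variable": "species_richness",
                "lrr": [0.1, 0.2, 0.4, 0.5],
                "variance": [0.01] * 4,
                "m": ["A", "B", None, "B"],
            }
        )
        with pytest.warns(UserWarning, match="missing"):
            res = subgroup_analysis(eff, "m")
        assert sum(lv.n for lv in res.levels) == 3


class TestMetaRegression:
    def test_constant_outcome_gives_zero_slope(self):
        eff = pd.DataFrame(
            {
                "comparison_id": list("abcd"),
                "response_variable": "species_richness",
                "lrr": [0.3] * 4,
                "variance": [0.01, 0.02, 0.03, 0.04],
                "x": [0.0, 1.0, 2.0, 5.0],
            }
        )
        res = meta_regression(eff, "x")
        assert res.slope == pytest.approx(0.0, abs=1e-12)
        assert res.QE == pytest.approx(0.0, abs=1e-12)

    def test_interpolates_two_distinct_points(self):
        # three effects, two x values would be rank-sufficient; use an exact
        # line so QE = 0 and the line passes through both
        eff = pd.DataFrame(
            {
                "comparison_id": list("abc"),
                "response_variable": "species_richness",
                "lrr": [0.1, 0.3, 0.5],
                "variance": [0.01, 0.02, 0.01],
                "x": [0.0, 1.0, 2.0],
            }
        )
        res = meta_regression(eff, "x")
        assert res.slope == pytest.approx(0.2, rel=1e-10)
        assert res.intercept == pytest.approx(0.1, rel=1e-10)
        assert res.QE == pytest.approx(0.0, abs=1e-10)

    def test_matches_brute_force_normal_equations(self):
        rng = np.random.default_rng(31)
        for _ in range(80):
            eff = random_effects_frame(rng, int(rng.integers(4, 15)))
            res = meta_regression(eff, "duration_years")
            beta, se = brute_force_wls(
                eff["lrr"].to_numpy(),
                eff["duration_years"].to_numpy(),
                1.0 / eff["variance"].to_numpy(),
            )
            assert res.intercept == pytest.approx(beta[0], rel=1e-9, abs=1e-12)
            assert res.slope == pytest.approx(beta[1], rel=1e-9, abs=1e-12)
            assert res.intercept_se == pytest.approx(se[0], rel=1e-9)
            assert res.slope_se == pytest.approx(se[1], rel=1e-9)

    def test_matches_frozen_metafor_moderator_fit(self):
        # rma(yi, vi, mods=~xi, method="FE") on this instance
        eff = pd.DataFrame(
            {
                "comparison_id": list("abcde"),
                "response_variable": "v",
                "lrr": [0.12, -0.34, 0.05, 0.48, -0.21],
                "variance": [0.02, 0.015, 0.03, 0.01, 0.025],
                "x": [1.0, 2.0, 4.0, 7.0, 10.0],
            }
        )
        res = meta_regression(eff, "x")
        assert res.intercept == pytest.approx(-0.086371022343, abs=1e-10)
        assert res.slope == pytest.approx(0.035045362221, abs=1e-10)
        assert res.intercept_se == pytest.approx(0.109005475256, abs=1e-10)
        assert res.slope_se == pytest.approx(0.018799443948, abs=1e-10)
        assert res.QE == pytest.approx(27.752111035884, abs=1e-8)
        assert res.QM == pytest.approx(3.475130343427, abs=1e-8)

    def test_statsmodels_wls_agrees_on_coefficients(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(13)
        eff = random_effects_frame(rng, 12)
        res = meta_regression(eff, "duration_years")
        X = sm.add_constant(eff["duration_years"].to_numpy())
        fit = sm.WLS(eff["lrr"].to_numpy(), X, weights=1 / eff["variance"]).fit()
        assert res.intercept == pytest.approx(fit.params[0], rel=1e-9)
        assert res.slope == pytest.approx(fit.params[1], rel=1e-9)

    def test_centering_covariate_moves_intercept_not_slope(self):
        rng = np.random.default_rng(17)
        eff = random_effects_frame(rng, 10)
        res = meta_regression(eff, "duration_years")
        centered = eff.assign(
            duration_years=eff["duration_years"] - eff["duration_years"].mean()
        )
        res_c = meta_regression(centered, "duration_years")
        assert res_c.slope == pytest.approx(res.slope, rel=1e-9)
        assert res_c.intercept != pytest.approx(res.intercept, abs=1e-6)

    def test_intercept_only_equivalence_via_dummy(self):
        # regression on a 0/1 dummy reproduces the fixed-weights subgroup
        # Q_between as QM
        rng = np.random.default_rng(41)
        eff = random_effects_frame(rng, 14)
        eff["group"] = np.where(np.arange(14) % 2 == 0, "a", "b")
        eff["dummy"] = (eff["group"] == "b").astype(float)
        sg = subgroup_analysis(eff, "group")
        mr = meta_regression(eff, "dummy")
        assert mr.QM == pytest.approx(sg.Q_between, rel=1e-8)

    def test_constant_covariate_is_rank_deficient_error(self):
        eff = pd.DataFrame(
            {
                "comparison_id": list("abc"),
                "response_variable": "v",
                "lrr": [0.1, 0.2, 0.3],
                "variance": [0.01] * 3,
                "x": [2.0, 2.0, 2.0],
            }
        )
        with pytest.raises(AnalysisError, match="rank"):
            meta_regression(eff, "x")

    def test_mixed_mom_tau2_widens_intervals(self, richness_effects):
        fe = meta_regression(richness_effects, "duration_years")
        mm = meta_regression(richness_effects, "duration_years", method="mixed_mom")
        assert mm.tau2 > 0
        assert mm.slope_se > fe.slope_se


class TestCrossResponse:
    def _mk(self, ids, lrrs, var_label, variances=None):
        return pd.DataFrame(
            {
                "comparison_id": ids,
                "response_variable": var_label,
                "lrr": lrrs,
                "variance": variances if variances is not None else [0.01] * len(ids),
            }
        )

    def test_collinear_pairs_recover_exact_slope(self):
        x = self._mk(list("abcdef"), [0.2, 0.4, -0.1, 0.8, 0.5, -0.3], "biomass")
        y = self._mk(
            list("abcdef"), [-0.75 * v for v in x["lrr"]], "richness"
        )
        res = cross_response_regression(y, x)
        assert res.slope == pytest.approx(-0.75, rel=1e-10)
        assert res.QE == pytest.approx(0.0, abs=1e-9)

    def test_fixture_joins(self, richness_effects, biomass_effects, shannon_effects):
        res = cross_response_regression(richness_effects, biomass_effects)
        assert res.k == 8  # comparisons measuring both variables
        with pytest.raises(AnalysisError, match="4 joined pairs"):
            cross_response_regression(shannon_effects, biomass_effects)

    def test_null_relation_slope_ci_covers_zero_at_nominal_rate(self):
        rng = np.random.default_rng(97)
        covered = 0
        reps = 400
        for _ in range(reps):
            k = 12
            ids = [f"c{i}" for i in range(k)]
            x = self._mk(ids, rng.normal(0, 0.5, k), "biomass")
            v = np.full(k, 0.04)
            y = self._mk(ids, rng.normal(0, 0.2, k), "richness", v)
            res = cross_response_regression(y, x)
            if res.slope_ci[0] <= 0 <= res.slope_ci[1]:
                covered += 1
        # binomial 3-sigma band around 0.95
        assert abs(covered / reps - 0.95) < 3 * math.sqrt(0.95 * 0.05 / reps)
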