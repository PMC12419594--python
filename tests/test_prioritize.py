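"""Richness stacking, min-max scaling, and the three priority surfaces."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import spearmanr

from musselscape.errors import DataError, DegenerateInputError
from musselscape.prioritize import (
    binary_map,
    interspecies_correlation,
    minmax_scale,
    protection_priority,
    protection_vs_protected_correlation,
    ranked_priority,
    restoration_priority,
    stack_richness,
    state_summaries,
    survey_priority,
)


def series(vals, ids=None):
    ids = ids or [f"c{i}" for i in range(len(vals))]
    return pd.Series(vals, index=ids, dtype=float)


class TestBinaryMap:
    def test_threshold_above_max_gives_all_zero(self):
        assert binary_map(series([0.1, 0.5]), 0.9).sum() == 0

    def test_threshold_at_min_gives_all_one(self):
        assert binary_map(series([0.1, 0.5]), 0.1).sum() == 2

    def test_inclusive_at_threshold(self):
        assert binary_map(series([0.1, 0.5, 0.9]), 0.5).tolist() == [0, 1, 1]


class TestRichness:
    def test_hand_summed_stack(self):
        maps = {
            "a": series([1, 1, 0]),
            "b": series([1, 0, 0]),
            "c": series([1, 0, 1]),
        }
        ranks = {"a": "very_high", "b": "not_listed", "c": "not_listed"}
        rich = stack_richness(maps, ranks)
        assert rich["overall_richness"].tolist() == [3, 1, 1]
        assert rich["rsgcn_richness"].tolist() == [1, 1, 0]

    def test_rsgcn_never_exceeds_overall(self):
        rng = np.random.default_rng(0)
        maps = {f"s{i}": series(rng.integers(0, 2, 20)) for i in range(6)}
        ranks = {f"s{i}": ["very_high", "high", "moderate", "not_listed"][i % 4] for i in range(6)}
        rich = stack_richness(maps, ranks)
        assert (rich["rsgcn_richness"] <= rich["overall_richness"]).all()
        # conservation: overall equals the per-catchment sum of binary maps
        assert (rich["overall_richness"] == sum(maps.values())).all()

    def test_mismatched_catchments_rejected(self):
        maps = {"a": series([1, 0]), "b": series([1], ids=["c0"])}
        with pytest.raises(DataError, match="different catchment"):
            stack_richness(maps, {"a": "not_listed", "b": "not_listed"})


class TestMinmaxScale:
    def test_simple_example(self):
        assert minmax_scale(series([2, 4, 6])).tolist() == [0.0, 0.5, 1.0]

    def test_constant_maps_to_zero(self):
        assert minmax_scale(series([3, 3, 3])).tolist() == [0.0, 0.0, 0.0]

    def test_idempotent_on_unit_span(self):
        s = series([0.0, 0.25, 1.0])
        assert minmax_scale(s).tolist() == s.tolist()

    def test_nan_propagates(self):
        out = minmax_scale(series([0.0, np.nan, 2.0]))
        assert np.isnan(out.iloc[1]) and out.iloc[2] == 1.0

    def test_empty_rejected(self):
        with pytest.raises(DegenerateInputError):
            minmax_scale(series([]))

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(st.lists(st.floats(-1e6, 1e6), min_size=2, max_size=30, unique=True))
    def test_output_attains_zero_and_one(self, vals):
        out = minmax_scale(np.array(vals))
        assert out.min() == 0.0 and out.max() == 1.0


def richness_df(overall, rsgcn=None, ids=None):
    ids = ids or [f"c{i}" for i in range(len(overall))]
    return pd.DataFrame(
        {
            "overall_richness": overall,
            "rsgcn_richness": rsgcn or [0] * len(overall),
        },
        index=ids,
    )


class TestSurveyPriority:
    def test_unsurveyed_max_richness_scores_one(self):
        rich = richness_df([5, 2, 0])
        out = survey_priority(rich, surveyed_since={"c1"})
        assert out["c0"] == 1.0

    def test_surveyed_min_richness_scores_zero(self):
        rich = richness_df([5, 2, 0])
        out = survey_priority(rich, surveyed_since={"c2"})
        assert out["c2"] == 0.0

    def test_all_surveyed_equal_richness_all_zero(self):
        rich = richness_df([2, 2, 2])
        out = survey_priority(rich, surveyed_since={"c0", "c1", "c2"})
        assert (out == 0.0).all()

    def test_raising_richness_never_lowers_priority(self):
        rich = richness_df([4, 2, 1, 0])
        out1 = survey_priority(rich, surveyed_since={"c1"})
        rich2 = richness_df([4, 3, 1, 0])
        out2 = survey_priority(rich2, surveyed_since={"c1"})
        assert out2["c1"] >= out1["c1"]


class TestRestorationPriority:
    def test_extremes_and_eligibility(self, nested_frame):
        ids = [f"c{i}" for i in range(8)]
        protected = series([100, 0, 50, 20, 10, 5, 0, 30], ids)
        forest = series([90, 10, 50, 40, 30, 20, 0, 60], ids)
        change = series([0, 40, 10, 5, 20, 30, 40, 0], ids)
        presences = {"sp": {"c0"}}  # huc8 00000000 only
        out = restoration_priority(
            protected, forest, change, presences, nested_frame, {"sp": "very_high"}
        )["sp"]
        assert out["c0"] == 1.0  # best in every input, eligible
        assert out.loc[["c1", "c2", "c3"]].notna().all()
        assert out.loc[["c4", "c5", "c6", "c7"]].isna().all()  # other huc8: no score

    def test_moderate_rank_gets_no_surface(self, nested_frame):
        ids = [f"c{i}" for i in range(8)]
        z = series(np.arange(8.0), ids)
        out = restoration_priority(z, z, z, {"sp": {"c0"}}, nested_frame, {"sp": "moderate"})
        assert out == {}

    def test_presence_in_every_huc8_makes_all_eligible(self, nested_frame):
        ids = [f"c{i}" for i in range(8)]
        z = series(np.arange(8.0), ids)
        out = restoration_priority(
            z, z, z, {"sp": {"c0", "c7"}}, nested_frame, {"sp": "high"}
        )["sp"]
        assert out.notna().all()


class TestProtectionPriority:
    def test_extremes(self):
        rich = richness_df([4, 0, 2])
        forest = series([80, 0, 40])
        wetland = series([30, 0, 10])
        resilience = series([0.9, 0.1, 0.4])
        out = protection_priority(rich, forest, wetland, resilience)
        assert out["c0"] == 1.0 and out["c1"] == 0.0

    def test_hand_built_recomputation(self):
        rich = richness_df([0, 1, 2, 4])
        forest = series([0, 50, 100, 25])
        wetland = series([10, 0, 5, 10])
        resilience = series([0.2, 0.2, 0.6, 1.0])
        out = protection_priority(rich, forest, wetland, resilience)
        # spreadsheet-style: scale each, sum, rescale
        total = np.array([
            0 + 0 + 1.0 + 0,
            0.25 + 0.5 + 0 + 0,
            0.5 + 1.0 + 0.5 + 0.5,
            1.0 + 0.25 + 1.0 + 1.0,
        ])
        expected = (total - total.min()) / (total.max() - total.min())
        assert np.allclose(out.to_numpy(), expected)

    def test_scaling_invariance_of_ranked_list(self):
        rng = np.random.default_rng(1)
        rich = richness_df(rng.integers(0, 10, 50).tolist())
        forest = series(rng.random(50) * 100)
        wetland = series(rng.random(50) * 100)
        resilience = series(rng.random(50))
        base = protection_priority(rich, forest, wetland, resilience)
        # affine transform of one input leaves the composition unchanged
        shifted = protection_priority(rich, forest * 3.0 + 7.0, wetland, resilience)
        assert ranked_priority(base)["catchment_id"].tolist() == ranked_priority(shifted)["catchment_id"].tolist()


class TestCorrelations:
    def test_identical_surfaces_correlate_perfectly(self):
        rng = np.random.default_rng(2)
        x = rng.random(30)
        preds = pd.DataFrame({"a": x, "b": x, "c": -x})
        rho = interspecies_correlation(preds)
        assert rho.loc["a", "b"] == pytest.approx(1.0)
        assert rho.loc["a", "c"] == pytest.approx(-1.0)

    def test_matches_rank_formula_oracle(self):
        rng = np.random.default_rng(3)
        preds = pd.DataFrame(rng.random((20, 3)), columns=list("abc"))
        rho = interspecies_correlation(preds)
        for a in "abc":
            for b in "abc":
                assert rho.loc[a, b] == pytest.approx(
                    spearmanr(preds[a], preds[b]).statistic, abs=1e-12
                )

    def test_protection_vs_protected_identical_ranks(self):
        x = series(np.arange(10.0))
        assert protection_vs_protected_correlation(x, x * 2)["region"] == pytest.approx(1.0)

    def test_protection_vs_protected_null(self):
        rng = np.random.default_rng(4)
        a = series(rng.random(1000))
        b = series(rng.random(1000))
        assert abs(protection_vs_protected_correlation(a, b)["region"]) < 0.1

    def test_constant_input_flagged(self):
        with pytest.raises(DegenerateInputError):
            protection_vs_protected_correlation(series([1, 1, 1]), series([1, 2, 3]))


class TestStateSummaries:
    def test_uniform_state_has_zero_se(self, nested_frame):
        ids = [f"c{i}" for i in range(8)]
        rich = richness_df([2] * 8, ids=ids)
        surveys = pd.DataFrame({"catchment_id": ["c0", "c4"], "year": [2000, 2001]})
        survey_surface = series([0.5] * 8, ids)
        protection = series([0.25] * 8, ids)
        out = state_summaries(nested_frame, rich, surveys, survey_surface, protection)
        assert set(out["state"]) == {"ME", "VT"}
        row = out.set_index("state").loc["VT"]
        assert row["mean_richness"] == 2.0
        assert row["survey_priority_se"] == 0.0
        assert row["n_surveys"] == 1

    def test_statewide_ineligible_species_is_na(self, nested_frame):
        ids = [f"c{i}" for i in range(8)]
        rich = richness_df(list(range(8)), ids=ids)
        surveys = pd.DataFrame({"catchment_id": [], "year": []})
        surface = series(np.linspace(0, 1, 8), ids)
        resto = {"sp": series([np.nan] * 4 + [0.5] * 4, ids)}  # VT all-NaN
        out = state_summaries(
            nested_frame, rich, surveys, surface, surface, resto
        ).set_index("state")
        assert np.isnan(out.loc["VT", "restoration_sp_mean"])
        assert out.loc["ME", "restoration_sp_mean"] == 0.5

    def test_two_state_means_match_manual_computation(self, nested_frame):
        ids = [f"c{i}" for i in range(8)]
        rich = richness_df([1, 2, 3, 4, 5, 6, 7, 8], ids=ids)
        surveys = pd.DataFrame({"catchment_id": ["c0"], "year": [2000]})
        surface = series(np.zeros(8), ids)
        out = state_summaries(nested_frame, rich, surveys, surface, surface).set_index("state")
        assert out.loc["VT", "mean_richness"] == pytest.approx(2.5)  # c0..c3
        assert out.loc["ME", "mean_richness"] == pytest.approx(6.5)  # c4..c7


def test_ranked_priority_breaks_ties_by_catchment_id():
    s = series([0.5, 0.9, 0.5], ids=["cB", "cA", "cC"])
    ranked = ranked_priority(s)
    assert ranked["catchment_id"].tolist() == ["cA", "cB", "cC"]
    assert ranked["rank"].tolist() == [1, 2, 3]
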