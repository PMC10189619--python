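import math

import numpy as np
import pandas as pd
import pytest

from oice.graph import CausalGraph
from oice.metrics import (BOTH, DOWN, UP, PISDecomposition, classify_behavior,
                          cost_of_impact, impact_score, pure_impact_scores,
                          select_important, summarize_cohort,
                          weighted_impact_score)
from oice.pos_features import FeatureStats
from oice.search import CounterfactualExample


def make_cfe(feature, deltas, record_id="r", value=0):
    deltas = pd.Series(deltas)
    return CounterfactualExample(
        record_id=record_id, feature=feature, value=value,
        counterfactual=deltas * 0, probability=0.9, distance=1.0, deltas=deltas)


def make_stats(features, ranges, mads=None):
    ranges = pd.Series(ranges, index=features, dtype=float)
    mads = pd.Series(mads if mads is not None else 1.0, index=features, dtype=float)
    return FeatureStats(list(features), ranges * 0.0, ranges, mads)


class TestImpactScore:
    def test_all_samples_flip(self):
        assert impact_score(10, 10) == 1.0

    def test_cohort_proportion(self):
        assert impact_score(96, 210) == pytest.approx(0.457, abs=5e-4)

    def test_no_flips(self):
        assert impact_score(0, 50) == 0.0

    def test_zero_cohort_rejected(self):
        with pytest.raises(ValueError):
            impact_score(1, 0)


class TestCostOfImpact:
    def test_single_change(self):
        ci, direction, up, down = cost_of_impact([3.0], 10.0)
        assert ci == pytest.approx(0.3)
        assert direction == UP and up == pytest.approx(0.3) and math.isnan(down)

    def test_mean_of_changes(self):
        ci, *_ = cost_of_impact([2.0, 4.0], 10.0)
        assert ci == pytest.approx(0.3)

    def test_mixed_directions(self):
        ci, direction, up, down = cost_of_impact([2.0, -4.0], 10.0)
        assert direction == BOTH
        assert up == pytest.approx(0.2) and down == pytest.approx(0.4)
        assert ci == pytest.approx(0.3)

    def test_empty_flip_set_is_nan(self):
        ci, direction, *_ = cost_of_impact([], 10.0)
        assert math.isnan(ci) and direction is None

    def test_zero_range_undefined(self):
        with pytest.raises(ValueError):
            cost_of_impact([1.0], 0.0)


class TestWeightedImpactScore:
    @pytest.mark.parametrize("is_k, ci_pct, expected", [
        (0.243, 30.0, 0.81),   # NNS
        (0.553, 16.5, 3.35),   # JJ
        (1.0, 29.5, 3.39),     # NNP
        (0.824, 49.6, 1.66),   # RB
        (0.886, 37.1, 2.39),   # VBD
    ])
    def test_printed_table_arithmetic(self, is_k, ci_pct, expected):
        """Published IS and CI values reproduce the published wIS to 2 d.p."""
        wis, _, _ = weighted_impact_score(is_k, ci_pct / 100.0, UP)
        assert round(wis, 2) == expected

    def test_uniform_direction_fills_matching_slot(self):
        wis, up, down = weighted_impact_score(0.5, 0.25, DOWN)
        assert wis == pytest.approx(2.0)
        assert down == pytest.approx(2.0) and up == 0.0

    def test_zero_impact(self):
        assert weighted_impact_score(0.0, math.nan) == (0.0, 0.0, 0.0)

    def test_mixed_directions_averaged(self):
        wis, up, down = weighted_impact_score(
            0.5, 0.3, BOTH, is_up=0.3, ci_up=0.2, is_down=0.2, ci_down=0.4)
        assert up == pytest.approx(1.5) and down == pytest.approx(0.5)
        assert wis == pytest.approx(1.0)

    def test_zero_cost_with_impact_impossible(self):
        with pytest.raises(ValueError):
            weighted_impact_score(0.5, 0.0, UP)


class TestPureImpactScores:
    def test_childless_feature_owns_everything(self):
        graph = CausalGraph(["RB"], [])
        stats = make_stats(["RB"], {"RB": 10.0})
        cfes = [make_cfe("RB", {"RB": 3}) for _ in range(4)]
        dec = pure_impact_scores("RB", cfes, graph, {}, stats, n=4)
        assert dec.own == pytest.approx(dec.is_k)
        assert dec.own_pct == pytest.approx(100.0)

    def test_decomposition_sums_to_is(self):
        graph = CausalGraph(["K", "M1", "M2"], [("K", "M1"), ("K", "M2")])
        stats = make_stats(["K", "M1", "M2"], {"K": 10, "M1": 10, "M2": 10})
        cfes = [make_cfe("K", {"K": 2, "M1": 1, "M2": -1}) for _ in range(3)]
        wis_signed = {"M1": (1.2, 0.0), "M2": (0.0, 0.7)}
        dec = pure_impact_scores("K", cfes, graph, wis_signed, stats, n=6)
        assert dec.own + sum(dec.children.values()) == pytest.approx(dec.is_k, abs=1e-15)
        assert dec.own_pct + sum(dec.children_pct.values()) == pytest.approx(100.0)

    def test_aligned_child_contributes_unmoved_child_does_not(self):
        graph = CausalGraph(["K", "M1", "M2"], [("K", "M1"), ("K", "M2")])
        stats = make_stats(["K", "M1", "M2"], {"K": 10, "M1": 10, "M2": 10})
        # M1 moves up, and up is M1's own flip direction; M2 never moves
        cfes = [make_cfe("K", {"K": 2, "M1": 2, "M2": 0}) for _ in range(2)]
        wis_signed = {"M1": (1.5, 0.0), "M2": (0.4, 0.0)}
        dec = pure_impact_scores("K", cfes, graph, wis_signed, stats, n=2)
        assert dec.children["M1"] == pytest.approx(1.5 * 2 / 10)
        assert dec.children["M2"] == 0.0
        assert dec.own == pytest.approx(dec.is_k - dec.children["M1"])

    def test_opposed_child_contributes_negatively(self):
        graph = CausalGraph(["K", "M"], [("K", "M")])
        stats = make_stats(["K", "M"], {"K": 10, "M": 10})
        # M moves down, but M's own flips only ever go up
        cfes = [make_cfe("K", {"K": 2, "M": -2})]
        dec = pure_impact_scores("K", cfes, graph, {"M": (1.5, 0.0)}, stats, n=1)
        assert dec.children["M"] == pytest.approx(-1.5 * 2 / 10)

    def test_changing_child_without_wis_rejected(self):
        graph = CausalGraph(["K", "M"], [("K", "M")])
        stats = make_stats(["K", "M"], {"K": 10, "M": 10})
        cfes = [make_cfe("K", {"K": 2, "M": 1})]
        with pytest.raises(ValueError, match="M"):
            pure_impact_scores("K", cfes, graph, {}, stats, n=1)


class TestClassifyBehavior:
    @pytest.mark.parametrize("own, kids, expected", [
        (100.0, {}, "dominant"),
        (-20.0, {"m": 120.0}, "inverse"),
        (45.0, {"m": 55.0}, "cooperative"),
        (5.0, {"m": 95.0}, "idling"),
    ])
    def test_taxonomy(self, own, kids, expected):
        dec = PISDecomposition("k", 1.0, own / 100.0,
                               {m: v / 100.0 for m, v in kids.items()})
        assert classify_behavior(dec).label == expected

    def test_thresholds_reported(self):
        dec = PISDecomposition("k", 1.0, 1.0, {})
        b = classify_behavior(dec, low=5.0, high=60.0)
        assert (b.low_pct, b.high_pct) == (5.0, 60.0)


class TestSelectImportant:
    def test_double_top_ranked_first(self):
        report = pd.DataFrame({"IS": [1.0, 0.5, 0.2], "wIS": [3.0, 2.0, 1.0]},
                              index=["a", "b", "c"])
        assert select_important(report, t=3)[0] == "a"

    def test_high_wis_low_is_excluded(self):
        report = pd.DataFrame(
            {"IS": [0.9, 0.8, 0.01], "wIS": [1.0, 0.9, 99.0]},
            index=["a", "b", "rare"])
        assert "rare" not in select_important(report, t=2)

    def test_zero_budget(self):
        report = pd.DataFrame({"IS": [1.0], "wIS": [1.0]}, index=["a"])
        assert select_important(report, t=0) == []


class TestSummarizeCohort:
    @pytest.fixture
    def cohort_report(self):
        graph = CausalGraph(["K", "M"], [("K", "M")])
        stats = make_stats(["K", "M"], {"K": 10.0, "M": 10.0})
        cfes = {
            "r1": [make_cfe("K", {"K": 2, "M": 1}, "r1"),
                   make_cfe("M", {"K": 0, "M": 3}, "r1")],
            "r2": [make_cfe("M", {"K": 0, "M": 1}, "r2")],
        }
        return summarize_cohort(cfes, stats, graph)

    def test_is_values(self, cohort_report):
        assert cohort_report.table.loc["K", "IS"] == pytest.approx(0.5)
        assert cohort_report.table.loc["M", "IS"] == pytest.approx(1.0)

    def test_no_normalization_across_features(self, cohort_report):
        # several features may flip the same sample; IS need not sum to 1
        assert cohort_report.table["IS"].sum() > 1.0

    def test_wis_identity_for_uniform_direction(self, cohort_report):
        t = cohort_report.table
        for k in ("K", "M"):
            assert t.loc[k, "wIS"] == pytest.approx(t.loc[k, "IS"] / t.loc[k, "CI"])

    def test_pis_matrix_rows_sum_to_100(self, cohort_report):
        mat = cohort_report.pis_matrix()
        for k in cohort_report.decompositions:
            assert mat.loc[k].sum() == pytest.approx(100.0)
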