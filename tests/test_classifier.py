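"""Tests of the rule-based dormancy classifier: the documented side of every
category threshold, rule precedence, the viability decision tree, and
monotonicity of calls in germination means."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from dormscreen.classifier import (
    Category,
    ClassifierConfig,
    ViabilityTimeline,
    classify_initial,
    classify_panel,
    classify_refined,
    summarize_panel,
    viability_decision,
)
from dormscreen.germination import GerminationAssay, TreatmentSpec


def _means(nt, a01, a1, a10):
    return {"NT": nt, "ABA0.1": a01, "ABA1": a1, "ABA10": a10}


def _assay(code, counts, variety="V", sown=10):
    return GerminationAssay(variety, TreatmentSpec.parse(code),
                            [(sown, g) for g in counts])


class TestInitialRules:
    @pytest.mark.parametrize("means,responsive,expected", [
        (_means(0.10, 0.08, 0.05, 0.00), False, Category.SD),
        (_means(0.96, 0.92, 0.88, 0.80), False, Category.ND),
        (_means(0.40, 0.35, 0.25, 0.10), True, Category.MD),
        (_means(0.70, 0.65, 0.50, 0.30), True, Category.WD),
    ])
    def test_reference_assignments(self, means, responsive, expected):
        call = classify_initial("V", means, responsive)
        assert call.category == expected
        assert not call.ambiguous

    def test_missing_treatment_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            classify_initial("V", {"NT": 0.5, "ABA10": 0.2}, True)

    def test_rule_provenance_recorded(self):
        call = classify_initial("V", _means(0.1, 0.1, 0.1, 0.1), False)
        assert call.rule_fired.startswith("initial:SD")

    def test_determinism(self):
        a = classify_initial("V", _means(0.6, 0.5, 0.4, 0.3), True)
        b = classify_initial("V", _means(0.6, 0.5, 0.4, 0.3), True)
        assert (a.category, a.rule_fired, a.ambiguous) == (
            b.category, b.rule_fired, b.ambiguous)


class TestInitialBoundaries:
    """Each protocol threshold lands on its documented side: "0-24%" means
    strictly below 0.25, "above 50%"/"above 75%" are strict."""

    def test_just_below_quarter_is_sd(self):
        call = classify_initial("V", _means(0.24999, 0.2, 0.2, 0.2), False)
        assert call.category == Category.SD and not call.ambiguous

    def test_exactly_quarter_is_not_sd_rule(self):
        call = classify_initial("V", _means(0.25, 0.2, 0.2, 0.2), False)
        assert call.rule_fired != "initial:SD(all<25%)"

    def test_just_above_three_quarters_is_nd(self):
        call = classify_initial("V", _means(0.76, 0.76, 0.76, 0.75001), False)
        assert call.category == Category.ND and not call.ambiguous

    def test_exactly_three_quarters_is_not_nd_rule(self):
        call = classify_initial("V", _means(0.76, 0.76, 0.76, 0.75), False)
        assert call.ambiguous

    def test_just_above_half_with_response_is_wd(self):
        call = classify_initial("V", _means(0.50001, 0.45, 0.4, 0.3), True)
        assert call.category == Category.WD and not call.ambiguous

    def test_exactly_half_satisfies_no_rule(self):
        call = classify_initial("V", _means(0.50, 0.45, 0.4, 0.3), True)
        assert call.ambiguous

    def test_just_below_half_decreasing_is_md(self):
        call = classify_initial("V", _means(0.49999, 0.45, 0.4, 0.3), True)
        assert call.category == Category.MD and not call.ambiguous

    def test_md_needs_five_point_total_drop(self):
        ok = classify_initial("V", _means(0.40, 0.38, 0.36, 0.35), True)
        assert ok.category == Category.MD and not ok.ambiguous
        short = classify_initial("V", _means(0.40, 0.39, 0.38, 0.36), True)
        assert short.ambiguous

    def test_strict_nd_variant(self):
        cfg = ClassifierConfig(strict_nd=True)
        means = _means(0.90, 0.85, 0.82, 0.80)
        default = classify_initial("V", means, False)
        strict = classify_initial("V", means, False, cfg)
        assert default.category == Category.ND and not default.ambiguous
        assert strict.ambiguous  # NT not above 95%


class TestRefinedRules:
    @pytest.mark.parametrize("means,responsive,expected", [
        ({"NT": 0.10, "ABA10": 0.00, "GA10": 0.20}, False, Category.SD),
        ({"NT": 0.35, "ABA10": 0.10, "GA10": 0.80}, True, Category.MD),
        ({"NT": 0.60, "ABA10": 0.25, "GA10": 0.90}, True, Category.WD),
    ])
    def test_reference_assignments(self, means, responsive, expected):
        call = classify_refined("V", means, responsive)
        assert call.category == expected
        assert not call.ambiguous

    def test_missing_ga_arm_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            classify_refined("V", {"NT": 0.1, "ABA10": 0.1}, False)

    def test_ga_boundary_at_thirty_percent(self):
        below = classify_refined("V", {"NT": 0.1, "ABA10": 0.05, "GA10": 0.29999},
                                 False)
        assert below.category == Category.SD and not below.ambiguous
        at = classify_refined("V", {"NT": 0.1, "ABA10": 0.05, "GA10": 0.30},
                              False)
        assert at.rule_fired != "refined:SD(NT,ABA<25%,GA<30%)"

    def test_md_ga_boundary_inclusive_at_half(self):
        call = classify_refined("V", {"NT": 0.45, "ABA10": 0.1, "GA10": 0.50},
                                True)
        assert call.category == Category.MD and not call.ambiguous

    def test_wd_fires_on_either_nt_or_ga_above_half(self):
        by_nt = classify_refined("V", {"NT": 0.55, "ABA10": 0.2, "GA10": 0.45},
                                 True)
        assert by_nt.category == Category.WD and not by_nt.ambiguous
        # GA above 50% with NT at 50%+ responsive but not MD (NT not < 0.5)
        by_ga = classify_refined("V", {"NT": 0.50, "ABA10": 0.2, "GA10": 0.80},
                                 True)
        assert by_ga.category == Category.WD and not by_ga.ambiguous


class TestMonotonicity:
    @given(
        st.lists(st.floats(0, 1), min_size=4, max_size=4),
        st.floats(0, 1),
        st.booleans(),
    )
    def test_raising_every_mean_never_moves_toward_sd(self, base, frac, resp):
        """With responsiveness held fixed, uniformly raising all means can
        only keep the category or move it toward ND."""
        delta = frac * (1 - max(base))
        lo = classify_initial("V", _means(*base), resp)
        hi = classify_initial("V", _means(*(m + delta for m in base)), resp)
        assert hi.category <= lo.category


def _timeline(refined_cat, refined_nt, ar1, scr=None, lar3=None):
    from dormscreen.classifier import DormancyCall

    call = DormancyCall("V", refined_cat, "refined")
    return ViabilityTimeline("V", call, refined_nt, ar1, scr, lar3)


class TestViabilityTree:
    def test_after_ripening_release_is_embryo_imposed(self):
        tl = _timeline(Category.SD, _assay("NT", [1, 1, 0]),
                       {"NT": _assay("AR1-NT", [9, 9, 8]),
                        "GA10": _assay("AR1-GA10", [10, 9, 9])})
        call = viability_decision(tl)
        assert call.mechanism == "embryo"
        assert call.viable == "yes"
        assert call.stage == "post_AR"
        assert call.category == Category.SD  # maturity category retained

    def test_scarification_rescue_is_seedcoat_imposed(self):
        tl = _timeline(
            Category.SD, _assay("NT", [1, 0, 1]),
            {"NT": _assay("AR1-NT", [2, 1, 1]),
             "GA10": _assay("AR1-GA10", [2, 2, 1])},
            scr=_assay("AR1-SCR", [9, 8, 8]),
        )
        call = viability_decision(tl)
        assert call.mechanism == "seedcoat"
        assert call.viable == "yes"

    def test_long_after_ripening_release_is_embryo_imposed(self):
        tl = _timeline(
            Category.SD, _assay("NT", [1, 0, 1]),
            {"NT": _assay("AR1-NT", [1, 1, 2]),
             "GA10": _assay("AR1-GA10", [2, 1, 1])},
            scr=_assay("AR1-SCR", [2, 1, 2]),
            lar3={"NT": _assay("LAR3-NT", [8, 9, 8])},
        )
        call = viability_decision(tl)
        assert call.mechanism == "embryo"
        assert call.stage == "post_LAR"

    def test_nothing_rescues_flags_viability_concern(self):
        tl = _timeline(
            Category.SD, _assay("NT", [1, 0, 1]),
            {"NT": _assay("AR1-NT", [1, 1, 0]),
             "GA10": _assay("AR1-GA10", [1, 0, 1])},
            scr=_assay("AR1-SCR", [1, 2, 1]),
            lar3={"NT": _assay("LAR3-NT", [2, 1, 1]),
                  "SCR": _assay("LAR3-SCR", [2, 2, 1])},
        )
        call = viability_decision(tl)
        assert call.viable == "concern"
        assert call.mechanism == "undetermined"

    def test_tree_requires_ar_data(self):
        tl = _timeline(Category.SD, _assay("NT", [1, 1, 0]), {})
        with pytest.raises(ValueError, match="after-ripened"):
            viability_decision(tl)

    def test_tree_rejects_non_dormant_entrants(self):
        tl = _timeline(Category.WD, _assay("NT", [6, 7, 7]),
                       {"NT": _assay("AR1-NT", [9, 9, 9])})
        with pytest.raises(ValueError, match="SD/MD"):
            viability_decision(tl)


class TestPanelSummary:
    def test_empty_panel_gives_zero_counts(self):
        counts, _ = summarize_panel(pd.DataFrame(
            columns=["variety_id", "category_label"]))
        assert list(counts.index) == ["ND", "WD", "MD", "SD"]
        assert counts.sum() == 0

    def test_duplicate_varieties_rejected(self):
        calls = pd.DataFrame({
            "variety_id": ["A", "A"],
            "category_label": ["ND", "SD"],
        })
        with pytest.raises(ValueError, match="duplicate"):
            summarize_panel(calls)

    def test_color_crosstab(self):
        calls = pd.DataFrame({
            "variety_id": ["A", "B", "C"],
            "category_label": ["ND", "ND", "SD"],
        })
        colors = pd.Series(["beige", "black", "beige"],
                           index=["A", "B", "C"])
        counts, crosstab = summarize_panel(calls, colors)
        assert counts["ND"] == 2 and counts["SD"] == 1
        assert crosstab.loc["beige", "SD"] == 1
        assert crosstab.loc["black", "ND"] == 1


class TestPanelClassification:
    def test_one_call_per_variety_with_valid_fields(self, panel_calls,
                                                    default_panel):
        _, traits = default_panel
        assert len(panel_calls) == len(traits)
        assert panel_calls["variety_id"].is_unique
        assert set(panel_calls["category_label"]) <= {"ND", "WD", "MD", "SD"}
        assert set(panel_calls["stage"]) <= {
            "initial", "refined", "post_AR", "post_LAR"}
        assert (panel_calls["category_code"].between(1, 4)).all()

    def test_mechanism_only_for_viability_tree_entrants(self, panel_calls):
        determined = panel_calls["mechanism"] != "undetermined"
        assert set(panel_calls.loc[determined, "stage"]) <= {
            "post_AR", "post_LAR"}

    def test_classification_deterministic(self, panel_assays, panel_calls):
        again = classify_panel(panel_assays)
        pd.testing.assert_frame_equal(panel_calls, again)
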