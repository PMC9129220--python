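"""Scoring engine: dichotomization, group logic, penalties, invariants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import icuqa
from icuqa.assessment import IndicatorResponse, ResponseStatus
from icuqa.scoring import ScoringConfig, Verdict, evaluate_rule, score_item

from _oracle import oracle_score
from conftest import (
    FAIL_VALUES,
    MISSING,
    NA,
    PASS_VALUES,
    SCORED_CODES,
    make_assessment,
)


def answered(code, value):
    return IndicatorResponse(indicator_code=code, status="answered", value=value)


class TestEvaluateRule:
    @pytest.mark.parametrize(
        "code,value,verdict",
        [
            ("C08", 15, Verdict.passed),     # <=15 passes at the boundary
            ("C08", 16, Verdict.failed),
            ("A01", 0.5, Verdict.passed),    # >=0.5 passes at the boundary
            ("A01", 0.49, Verdict.failed),
            ("B01", 12, Verdict.failed),     # strict >12 fails at 12
            ("B01", 13, Verdict.passed),
            ("A17", 80.0, Verdict.passed),
            ("A17", 79.9, Verdict.failed),
            ("A18", 1, Verdict.passed),
            ("A18", 0, Verdict.failed),
            ("A19", 0, Verdict.passed),      # zero unattended alarms
            ("A19", 1, Verdict.failed),
            ("A15", False, Verdict.passed),  # "1p if no"
            ("A15", True, Verdict.failed),
            ("C14", True, Verdict.passed),
            ("C14", False, Verdict.failed),
        ],
    )
    def test_boundary_inclusivity_as_printed(self, reg, code, value, verdict):
        assert evaluate_rule(reg.rule_for(code), answered(code, value)) is verdict

    def test_missing_and_na_propagate(self, reg):
        rule = reg.rule_for("A17")
        m = IndicatorResponse(indicator_code="A17", status="missing")
        n = IndicatorResponse(indicator_code="A17", status="not_applicable")
        assert evaluate_rule(rule, m) is Verdict.missing
        assert evaluate_rule(rule, n) is Verdict.not_applicable

    def test_code_mismatch_rejected(self, reg):
        with pytest.raises(ValueError, match="applied to"):
            evaluate_rule(reg.rule_for("A01"), answered("C04", 0.5))

    def test_type_mismatch_rejected(self, reg):
        with pytest.raises(TypeError):
            evaluate_rule(reg.rule_for("C14"), answered("C14", "sometimes"))
        with pytest.raises(TypeError):
            evaluate_rule(reg.rule_for("A01"), answered("A01", True))


class TestScoreItem:
    def item(self, reg, item_id):
        return next(i for i in reg.items if i.item_id == item_id)

    def test_group_passes_only_if_all_pass(self, reg):
        a = make_assessment({"A01": 0.5, "C04": 0.5, "C05": 0.6})
        s = score_item(self.item(reg, "STA2"), a)
        assert (s.points, s.penalty) == (1, 0)

    def test_group_fails_on_one_member(self, reg):
        a = make_assessment({"A01": 0.5, "C04": 0.4, "C05": 0.6})
        s = score_item(self.item(reg, "STA2"), a)
        assert (s.points, s.penalty) == (0, 0)

    def test_missing_member_zeroes_and_penalizes(self, reg):
        a = make_assessment({"B01": MISSING})
        s = score_item(self.item(reg, "CLM3"), a)
        assert (s.points, s.penalty) == (0, 1)
        assert s.member_verdicts["B01"] is Verdict.missing

    def test_per_indicator_penalty_counts_each_missing_member(self, reg):
        a = make_assessment({"B01": MISSING, "B02": MISSING})
        s = score_item(
            self.item(reg, "CLM3"), a, ScoringConfig(penalty="per_indicator")
        )
        assert (s.points, s.penalty) == (0, 2)

    def test_na_vacuously_passes_by_default(self, reg):
        a = make_assessment({"A17": NA})
        s = score_item(self.item(reg, "CLM1"), a)
        assert (s.points, s.excluded) == (1, False)
        assert s.member_verdicts["A17"] is Verdict.not_applicable

    def test_na_excluded_mode_drops_the_item(self, reg):
        a = make_assessment({"A17": NA})
        s = score_item(self.item(reg, "CLM1"), a, ScoringConfig(na="exclude"))
        assert s.excluded and s.points == 0 and s.penalty == 0


class TestScoreAssessment:
    def test_all_pass_scores_maximum(self, reg, all_pass):
        r = icuqa.score_assessment(all_pass, reg)
        assert (r.total_points, r.max_points, r.percentage) == (26, 26, 100.0)
        assert r.gap_list == ()

    def test_all_fail_scores_zero(self, reg, all_fail):
        r = icuqa.score_assessment(all_fail, reg)
        assert (r.total_points, r.percentage) == (0, 0.0)
        assert len(r.gap_list) == 26

    def test_single_missing_standalone_costs_two_points(self, reg):
        a = make_assessment({"B05": MISSING})
        r = icuqa.score_assessment(a, reg)
        assert r.total_points == 24  # lost point + one-point deduction
        assert r.percentage == round(100 * 24 / 26, 1)

    def test_all_missing_floors_at_zero(self, reg):
        a = make_assessment({c: MISSING for c in PASS_VALUES})
        r = icuqa.score_assessment(a, reg)
        assert (r.total_points, r.percentage) == (0, 0.0)

    def test_domain_subscores_sum_to_item_points(self, reg):
        a = make_assessment({"A13": FAIL_VALUES["A13"], "B05": MISSING})
        r = icuqa.score_assessment(a, reg)
        earned = sum(e for e, _ in r.domain_subscores.values())
        assert earned == sum(s.points for s in r.item_scores)
        assert sum(m for _, m in r.domain_subscores.values()) == r.max_points

    def test_exclude_mode_reduces_denominator(self, reg):
        a = make_assessment({"A17": NA})
        r = icuqa.score_assessment(a, reg, ScoringConfig(na="exclude"))
        assert (r.total_points, r.max_points, r.percentage) == (25, 25, 100.0)

    def test_report_serializes_and_reloads(self, reg, all_pass):
        r = icuqa.score_assessment(all_pass, reg)
        again = icuqa.ScoreReport.model_validate_json(r.model_dump_json())
        assert again == r
        assert len(r.to_frame()) == 26


# -- randomized invariants ---------------------------------------------------

state = st.sampled_from(["pass", "fail", "missing", "na"])


def build(states: dict[str, str]):
    overrides = {}
    for code, s in states.items():
        if s == "fail":
            overrides[code] = FAIL_VALUES[code]
        elif s == "missing":
            overrides[code] = MISSING
        elif s == "na":
            overrides[code] = NA
    return make_assessment(overrides)


states_strategy = st.fixed_dictionaries({c: state for c in SCORED_CODES})


class TestInvariants:
    @given(states=states_strategy)
    @settings(max_examples=150, derandomize=True, deadline=None)
    def test_bounds_and_item_contract(self, reg, states):
        r = icuqa.score_assessment(build(states), reg)
        assert 0 <= r.total_points <= r.max_points == 26
        for s in r.item_scores:
            has_missing = Verdict.missing in s.member_verdicts.values()
            assert (s.penalty == 1) == has_missing
            if s.penalty:
                assert s.points == 0

    @given(states=states_strategy, data=st.data())
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_fixing_a_failing_indicator_never_lowers_the_total(
        self, reg, states, data
    ):
        code = data.draw(st.sampled_from(SCORED_CODES))
        states = dict(states)
        states[code] = "fail"
        before = icuqa.score_assessment(build(states), reg).total_points
        states[code] = "pass"
        after = icuqa.score_assessment(build(states), reg).total_points
        assert after >= before

    @given(states=states_strategy, data=st.data())
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_losing_an_answer_drops_the_total_by_at_most_two(
        self, reg, states, data
    ):
        code = data.draw(st.sampled_from(SCORED_CODES))
        states = dict(states)
        states[code] = "pass"
        before = icuqa.score_assessment(build(states), reg).total_points
        states[code] = "missing"
        after = icuqa.score_assessment(build(states), reg).total_points
        assert before - 2 <= after <= before

    @given(states=states_strategy, seed=st.integers(0, 2**16))
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_response_order_never_matters(self, reg, states, seed):
        a = build(states)
        rng = np.random.default_rng(seed)
        codes = list(a.responses)
        rng.shuffle(codes)
        shuffled = a.model_copy(
            update={"responses": {c: a.responses[c] for c in codes}}
        )
        assert icuqa.score_assessment(shuffled, reg) == icuqa.score_assessment(a, reg)


class TestOracleEquivalence:
    """The engine must agree item-for-item with a literal protocol walk."""

    @pytest.mark.parametrize(
        "penalty,na",
        [("per_item", "vacuous"), ("per_indicator", "vacuous"),
         ("per_item", "exclude"), ("per_indicator", "exclude")],
    )
    def test_matches_brute_force_on_random_assessments(self, reg, penalty, na):
        rng = np.random.default_rng(20210301)
        from conftest import random_state_assessment

        config = ScoringConfig(penalty=penalty, na=na)
        for _ in range(500):
            a = random_state_assessment(rng, p_missing=0.15, p_na=0.15)
            r = icuqa.score_assessment(a, reg, config)
            total, points, pens, max_points = oracle_score(a, penalty, na)
            assert r.total_points == total
            assert r.max_points == max_points
            assert [s.points for s in r.item_scores] == points
            assert [s.penalty for s in r.item_scores] == pens
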