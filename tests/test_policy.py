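import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pedflow.policy import (
    Action,
    ActionType,
    DeptState,
    PatientState,
    PolicyError,
    Role,
    ROLE_FOR_ACTION,
    awaiting_senior,
    is_overcrowded,
    next_action,
    optimum_rank,
    pending_actions,
    standard_rank,
    status_color,
    StatusColor,
)

from conftest import random_department

PCTS = (50.0, 75.0, 95.0)


class TestStatusColor:
    @pytest.mark.parametrize(
        "los,expected",
        [
            (0.0, StatusColor.GREEN),
            (49.999, StatusColor.GREEN),
            (50.0, StatusColor.YELLOW),
            (74.999, StatusColor.YELLOW),
            (75.0, StatusColor.RED),
            (95.0, StatusColor.RED),
            (95.001, StatusColor.DARK_RED),
            (96.0, StatusColor.DARK_RED),
        ],
    )
    def test_boundaries(self, los, expected):
        assert status_color(los, PCTS) is expected

    def test_unordered_percentiles_raise(self):
        with pytest.raises(PolicyError):
            status_color(10.0, (75.0, 50.0, 95.0))

    def test_negative_los_raises(self):
        with pytest.raises(PolicyError):
            status_color(-1.0, PCTS)

    @given(
        los=st.lists(st.floats(0, 500), min_size=2, max_size=10),
        p50=st.floats(10, 100),
        d1=st.floats(0, 100),
        d2=st.floats(0, 100),
    )
    @settings(max_examples=100, deadline=None)
    def test_monotone_in_los(self, los, p50, d1, d2):
        pcts = (p50, p50 + d1, p50 + d1 + d2)
        colors = [status_color(x, pcts) for x in sorted(los)]
        assert all(a <= b for a, b in zip(colors, colors[1:]))

    def test_total_order(self):
        assert StatusColor.GREEN < StatusColor.YELLOW < StatusColor.RED < StatusColor.DARK_RED


def fresh_patient(pid="p1", arrival=0.0, **kw) -> PatientState:
    defaults = dict(reason="fever", priority="moderate")
    defaults.update(kw)
    return PatientState(patient_id=pid, arrival=arrival, **defaults)


class TestPendingActions:
    def test_fresh_arrival_gets_triage_only(self):
        actions = pending_actions(fresh_patient(), clock=5.0)
        assert [a.action_type for a in actions] == [ActionType.TRIAGE]
        assert actions[0].required_role is Role.NURSE

    def test_triaged_gets_first_eval(self):
        p = fresh_patient()
        p.triage_time = 10.0
        actions = pending_actions(p, clock=20.0)
        assert [a.action_type for a in actions] == [ActionType.FIRST_MEDICAL_EVAL]

    def test_plan_complete_gets_final_decision(self):
        p = fresh_patient()
        p.triage_time, p.first_eval_time = 10.0, 30.0
        actions = pending_actions(p, clock=40.0)
        assert [a.action_type for a in actions] == [ActionType.FINAL_DECISION]
        assert actions[0].required_role is Role.SENIOR

    def test_mid_stay_actions_enabled_exactly(self):
        p = fresh_patient(n_blood_tests=1, n_imaging=1, n_specialist=1, n_treatment_lines=1)
        p.triage_time, p.first_eval_time = 10.0, 30.0
        p.imaging_ready = 1
        kinds = {a.action_type for a in pending_actions(p, clock=60.0)}
        assert kinds == {
            ActionType.BLOOD_DRAW,
            ActionType.IMAGING_REVIEW,
            ActionType.SPECIALIST_REVIEW,
            ActionType.TREATMENT_ADMIN,
        }

    def test_blood_review_waits_for_turnaround(self):
        p = fresh_patient(n_blood_tests=1)
        p.triage_time, p.first_eval_time = 10.0, 30.0
        p.blood_drawn = 1  # result not back yet
        kinds = {a.action_type for a in pending_actions(p, clock=60.0)}
        assert ActionType.BLOOD_RESULT_REVIEW not in kinds
        p.blood_results_ready = 1
        kinds = {a.action_type for a in pending_actions(p, clock=60.0)}
        assert kinds == {ActionType.BLOOD_RESULT_REVIEW}

    def test_discharged_patient_raises(self):
        p = fresh_patient()
        p.triage_time, p.first_eval_time = 10.0, 30.0
        p.final_decision_time, p.end_of_care_time, p.discharge_time = 40.0, 45.0, 50.0
        with pytest.raises(PolicyError):
            pending_actions(p, clock=60.0)

    def test_inconsistent_milestones_raise(self):
        p = fresh_patient()
        p.first_eval_time = 30.0  # first eval without triage
        with pytest.raises(PolicyError):
            pending_actions(p, clock=40.0)

    def test_ready_times_respect_arrival(self):
        p = fresh_patient(arrival=100.0)
        (a,) = pending_actions(p, clock=200.0)
        assert a.ready_time >= p.arrival


class TestAwaitingSenior:
    def test_pending_imaging_blocks(self):
        p = fresh_patient(n_imaging=1)
        p.triage_time, p.first_eval_time = 10.0, 30.0
        assert not awaiting_senior(p)

    def test_empty_plan_after_first_eval(self):
        p = fresh_patient()
        p.triage_time, p.first_eval_time = 10.0, 30.0
        assert awaiting_senior(p)

    def test_discharged_is_false(self):
        p = fresh_patient()
        p.triage_time, p.first_eval_time = 10.0, 30.0
        p.final_decision_time, p.end_of_care_time, p.discharge_time = 40.0, 45.0, 50.0
        assert not awaiting_senior(p)

    def test_outstanding_senior_eval_blocks(self):
        p = fresh_patient(n_senior_evals=1)
        p.triage_time, p.first_eval_time = 10.0, 30.0
        assert not awaiting_senior(p)
        p.senior_done = 1
        assert awaiting_senior(p)


class TestOvercrowding:
    def test_empty_department(self, reference):
        dept = DeptState(clock=0.0, patients={}, reference=reference)
        assert not is_overcrowded(dept)

    def test_one_patient_past_p95(self, reference):
        p = fresh_patient(reason="fever", arrival=0.0)
        dept = DeptState(clock=381.0, patients={"p1": p}, reference=reference)
        assert is_overcrowded(dept)  # fever p95 = 380

    def test_all_green(self, reference):
        patients = {f"p{i}": fresh_patient(pid=f"p{i}", arrival=90.0) for i in range(5)}
        dept = DeptState(clock=100.0, patients=patients, reference=reference)
        assert not is_overcrowded(dept)


def _dept(reference, clock, patients):
    return DeptState(clock=clock, patients={p.patient_id: p for p in patients}, reference=reference)


class TestOptimumRank:
    def test_high_priority_first_eval_outranks_low(self, reference):
        a = fresh_patient("a", arrival=90.0, priority="high")
        b = fresh_patient("b", arrival=90.0, priority="low")
        for p in (a, b):
            p.triage_time = 95.0
        dept = _dept(reference, 100.0, [a, b])
        act_a = pending_actions(a, 100.0)[0]
        act_b = pending_actions(b, 100.0)[0]
        assert optimum_rank(act_a, dept) < optimum_rank(act_b, dept)

    def test_moderate_outranks_low_same_tier_same_color(self, reference):
        a = fresh_patient("a", arrival=90.0, priority="moderate", n_treatment_lines=1)
        b = fresh_patient("b", arrival=90.0, priority="low", n_treatment_lines=1)
        for p in (a, b):
            p.triage_time, p.first_eval_time = 92.0, 95.0
        dept = _dept(reference, 100.0, [a, b])
        act_a = pending_actions(a, 100.0)[0]
        act_b = pending_actions(b, 100.0)[0]
        assert optimum_rank(act_a, dept) < optimum_rank(act_b, dept)

    def test_dark_red_low_priority_lifted(self, reference):
        # low-priority patient past fever p95 (380) vs fresh green patient, same tier
        old = fresh_patient("old", arrival=0.0, priority="low", n_treatment_lines=1)
        young = fresh_patient("young", arrival=395.0, priority="moderate", n_treatment_lines=1)
        for p in (old, young):
            p.triage_time = p.arrival + 2
            p.first_eval_time = p.arrival + 4
        dept = _dept(reference, 400.0, [old, young])
        act_old = pending_actions(old, 400.0)[0]
        act_young = pending_actions(young, 400.0)[0]
        assert optimum_rank(act_old, dept) < optimum_rank(act_young, dept)

    def test_low_priority_gets_no_yellow_or_red_boost(self, reference):
        # a red low-priority patient ranks as if green, so a yellow moderate wins
        red_low = fresh_patient("rl", arrival=0.0, priority="low", n_treatment_lines=1)
        yellow_mod = fresh_patient("ym", arrival=70.0, priority="moderate", n_treatment_lines=1)
        for p in (red_low, yellow_mod):
            p.triage_time = p.arrival + 1
            p.first_eval_time = p.arrival + 2
        dept = _dept(reference, 200.0, [red_low, yellow_mod])  # fever: 200 red, 130 yellow
        act_rl = pending_actions(red_low, 200.0)[0]
        act_ym = pending_actions(yellow_mod, 200.0)[0]
        assert optimum_rank(act_ym, dept) < optimum_rank(act_rl, dept)

    def test_overcrowding_flips_discharge_above_intake(self, reference):
        stuck = fresh_patient("stuck", arrival=0.0)
        stuck.triage_time, stuck.first_eval_time = 2.0, 4.0  # awaiting senior, dark red at 400
        newbie = fresh_patient("new", arrival=399.0, priority="high")
        dept = _dept(reference, 400.0, [stuck, newbie])
        assert is_overcrowded(dept)
        act_final = pending_actions(stuck, 400.0)[0]
        act_triage = pending_actions(newbie, 400.0)[0]
        assert act_final.action_type is ActionType.FINAL_DECISION
        assert act_triage.action_type is ActionType.TRIAGE
        assert optimum_rank(act_final, dept) < optimum_rank(act_triage, dept)

    def test_disabled_action_raises(self, reference):
        p = fresh_patient("p", arrival=0.0)
        dept = _dept(reference, 10.0, [p])
        bogus = Action.make(ActionType.FINAL_DECISION, "p", 0.0)
        with pytest.raises(PolicyError):
            optimum_rank(bogus, dept)


class TestStandardRank:
    def test_fifo_within_priority(self, reference):
        early = fresh_patient("e", arrival=540.0)
        late = fresh_patient("l", arrival=600.0)
        dept = _dept(reference, 700.0, [early, late])
        a_e = pending_actions(early, 700.0)[0]
        a_l = pending_actions(late, 700.0)[0]
        assert standard_rank(a_e, dept) < standard_rank(a_l, dept)

    def test_acuity_beats_arrival(self, reference):
        early_low = fresh_patient("e", arrival=540.0, priority="low")
        late_high = fresh_patient("l", arrival=600.0, priority="high")
        dept = _dept(reference, 700.0, [early_low, late_high])
        a_e = pending_actions(early_low, 700.0)[0]
        a_l = pending_actions(late_high, 700.0)[0]
        assert standard_rank(a_l, dept) < standard_rank(a_e, dept)

    def test_identical_keys_stable_by_patient_id(self, reference):
        a = fresh_patient("a", arrival=100.0)
        b = fresh_patient("b", arrival=100.0)
        dept = _dept(reference, 200.0, [a, b])
        act_a = pending_actions(a, 200.0)[0]
        act_b = pending_actions(b, 200.0)[0]
        assert standard_rank(act_a, dept) < standard_rank(act_b, dept)

    def test_no_percentile_logic(self, reference):
        # dark-red low patient still loses to a fresh high-priority under standard
        old_low = fresh_patient("o", arrival=0.0, priority="low")
        new_high = fresh_patient("n", arrival=399.0, priority="high")
        dept = _dept(reference, 400.0, [old_low, new_high])
        a_o = pending_actions(old_low, 400.0)[0]
        a_n = pending_actions(new_high, 400.0)[0]
        assert standard_rank(a_n, dept) < standard_rank(a_o, dept)


# --- independent re-statement of the ranking rules, used as the oracle -------

_PRIO = {"high": 0, "moderate": 1, "low": 2}
_TIER_OF = {
    "TRIAGE": 0,
    "FIRST_MEDICAL_EVAL": 0,
    "SENIOR_EVAL": 1,
    "BLOOD_DRAW": 1,
    "BLOOD_RESULT_REVIEW": 1,
    "IMAGING_REVIEW": 1,
    "SPECIALIST_REVIEW": 1,
    "TREATMENT_ADMIN": 1,
    "FINAL_DECISION": 2,
    "DISCHARGE_PROCESS": 2,
}


def oracle_best(role, dept, policy):
    """Literal nested-if restatement of the ranking rules."""
    candidates = []
    crowded = any(
        dept.color_of(p) is StatusColor.DARK_RED for p in dept.patients.values() if p.present
    )
    for state in dept.patients.values():
        if not state.present or state.visible_since > dept.clock:
            continue
        for action in pending_actions(state, dept.clock):
            if action.required_role is not role or action.ready_time > dept.clock:
                continue
            tier = _TIER_OF[action.action_type.name]
            if policy == "optimum":
                if crowded:
                    tier = 2 - tier
                color = dept.color_of(state)
                if state.priority == "low" and color is not StatusColor.DARK_RED:
                    color = StatusColor.GREEN
                key = (
                    tier,
                    -int(color),
                    _PRIO[state.priority],
                    action.ready_time,
                    action.patient_id,
                    int(action.action_type),
                )
            else:
                key = (
                    _PRIO[state.priority],
                    state.arrival,
                    action.ready_time,
                    action.patient_id,
                    int(action.action_type),
                )
            candidates.append((key, action))
    if not candidates:
        return None
    return min(candidates, key=lambda ka: ka[0])[1]


class TestNextAction:
    def test_none_when_no_actions(self, reference):
        dept = DeptState(clock=100.0, patients={}, reference=reference)
        assert next_action(Role.NURSE, dept, "optimum") is None

    def test_single_enabled_action(self, reference):
        p = fresh_patient("p", arrival=50.0)
        dept = _dept(reference, 100.0, [p])
        act = next_action(Role.NURSE, dept, "standard")
        assert act is not None and act.action_type is ActionType.TRIAGE

    def test_invisible_patient_skipped(self, reference):
        p = fresh_patient("p", arrival=50.0)
        p.visible_since = 200.0
        dept = _dept(reference, 100.0, [p])
        assert next_action(Role.NURSE, dept, "optimum") is None

    def test_unknown_policy_rejected(self, reference):
        dept = DeptState(clock=0.0, patients={}, reference=reference)
        with pytest.raises(PolicyError):
            next_action(Role.NURSE, dept, "magic")

    @pytest.mark.parametrize("policy", ["optimum", "standard"])
    def test_agrees_with_brute_force_oracle(self, reference, policy):
        rng = np.random.default_rng(42 if policy == "optimum" else 43)
        for _ in range(500):
            dept = random_department(rng, reference, int(rng.integers(1, 11)))
            for role in Role:
                got = next_action(role, dept, policy)
                want = oracle_best(role, dept, policy)
                assert got == want, (policy, role, got, want)

    def test_pure_given_same_snapshot(self, reference):
        rng = np.random.default_rng(7)
        dept = random_department(rng, reference, 8)
        first = [next_action(r, dept, "optimum") for r in Role]
        second = [next_action(r, dept, "optimum") for r in Role]
        assert first == second
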