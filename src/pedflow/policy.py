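"""Secondary-triage decision logic and the standard-dashboard baseline.

Two ranking policies operate over the same department snapshot:

* ``optimum`` — tiered action classes (triage/first eval, then nurse care and
  physician reviews, then the final senior step), modulated by a per-patient
  status color derived from LOS reference percentiles, with an overcrowding
  mode that flips the queue towards discharging, and an escalation rule that
  lifts low-priority patients only once they pass their reason's 95th LOS
  percentile.
* ``standard`` — acuity first, then order of arrival; no percentile logic.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

from .calibration import LOSReferenceTable

__all__ = [
    "StatusColor",
    "ActionType",
    "Role",
    "Action",
    "PatientState",
    "DeptState",
    "status_color",
    "pending_actions",
    "awaiting_senior",
    "is_overcrowded",
    "optimum_rank",
    "standard_rank",
    "next_action",
    "ROLE_FOR_ACTION",
]


class PolicyError(ValueError):
    pass


class StatusColor(enum.IntEnum):
    """LOS status relative to same-reason reference percentiles; totally ordered."""

    GREEN = 0
    YELLOW = 1
    RED = 2
    DARK_RED = 3


class ActionType(enum.IntEnum):
    TRIAGE = 0
    FIRST_MEDICAL_EVAL = 1
    SENIOR_EVAL = 2
    BLOOD_DRAW = 3
    BLOOD_RESULT_REVIEW = 4
    IMAGING_REVIEW = 5
    SPECIALIST_REVIEW = 6
    TREATMENT_ADMIN = 7
    FINAL_DECISION = 8
    DISCHARGE_PROCESS = 9


class Role(str, enum.Enum):
    NURSE = "nurse"
    JUNIOR = "junior"
    SENIOR = "senior"
    SPECIALIST = "specialist"


ROLE_FOR_ACTION: dict[ActionType, Role] = {
    ActionType.TRIAGE: Role.NURSE,
    ActionType.FIRST_MEDICAL_EVAL: Role.JUNIOR,
    ActionType.SENIOR_EVAL: Role.SENIOR,
    ActionType.BLOOD_DRAW: Role.NURSE,
    ActionType.BLOOD_RESULT_REVIEW: Role.JUNIOR,
    ActionType.IMAGING_REVIEW: Role.JUNIOR,
    ActionType.SPECIALIST_REVIEW: Role.SPECIALIST,
    ActionType.TREATMENT_ADMIN: Role.NURSE,
    ActionType.FINAL_DECISION: Role.SENIOR,
    ActionType.DISCHARGE_PROCESS: Role.NURSE,
}

# Action-class tiers: new-patient intake, then mid-stay care/review work
# (treated as one group), then the final senior step and discharge.
_TIER: dict[ActionType, int] = {
    ActionType.TRIAGE: 0,
    ActionType.FIRST_MEDICAL_EVAL: 0,
    ActionType.BLOOD_DRAW: 1,
    ActionType.BLOOD_RESULT_REVIEW: 1,
    ActionType.IMAGING_REVIEW: 1,
    ActionType.SPECIALIST_REVIEW: 1,
    ActionType.TREATMENT_ADMIN: 1,
    ActionType.SENIOR_EVAL: 1,
    ActionType.FINAL_DECISION: 2,
    ActionType.DISCHARGE_PROCESS: 2,
}

_PRIORITY_ORDER = {"high": 0, "moderate": 1, "low": 2}


@dataclass(frozen=True)
class Action:
    """One unit of work a staff member can pick up."""

    action_type: ActionType
    patient_id: str
    required_role: Role
    ready_time: float

    @classmethod
    def make(cls, action_type: ActionType, patient_id: str, ready_time: float) -> "Action":
        return cls(action_type, patient_id, ROLE_FOR_ACTION[action_type], ready_time)


@dataclass
class PatientState:
    """A patient's progress through the stage graph, as the policy sees it."""

    patient_id: str
    arrival: float
    reason: str
    priority: str
    n_blood_tests: int = 0
    n_imaging: int = 0
    n_specialist: int = 0
    n_treatment_lines: int = 0
    n_senior_evals: int = 0
    visible_since: float = 0.0

    triage_time: Optional[float] = None
    first_eval_time: Optional[float] = None
    blood_drawn: int = 0
    blood_results_ready: int = 0   # lab turnaround complete, awaiting review
    blood_reviewed: int = 0
    imaging_ready: int = 0         # acquisition complete, awaiting review
    imaging_reviewed: int = 0
    specialist_done: int = 0
    treatment_done: int = 0
    senior_done: int = 0
    final_decision_time: Optional[float] = None
    end_of_care_time: Optional[float] = None
    discharge_time: Optional[float] = None
    reneged: bool = False
    # ready_time bookkeeping for mid-stay items (earliest outstanding instance)
    ready_times: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.visible_since < self.arrival:
            self.visible_since = self.arrival
        for n in (
            self.n_blood_tests,
            self.n_imaging,
            self.n_specialist,
            self.n_treatment_lines,
            self.n_senior_evals,
        ):
            if n < 0:
                raise PolicyError(f"{self.patient_id}: negative plan count")

    @property
    def discharged(self) -> bool:
        return self.discharge_time is not None

    @property
    def present(self) -> bool:
        return not self.discharged and not self.reneged

    def los(self, clock: float) -> float:
        return max(0.0, clock - self.arrival)

    def _check_consistency(self) -> None:
        if self.first_eval_time is not None and self.triage_time is None:
            raise PolicyError(f"{self.patient_id}: first eval recorded before triage")
        if self.blood_reviewed > self.blood_results_ready or self.blood_results_ready > self.blood_drawn:
            raise PolicyError(f"{self.patient_id}: blood counters out of order")
        if self.blood_drawn > self.n_blood_tests or self.imaging_reviewed > self.n_imaging:
            raise PolicyError(f"{self.patient_id}: plan counters exceed the care plan")
        if self.discharge_time is not None and self.final_decision_time is None:
            raise PolicyError(f"{self.patient_id}: discharge recorded before final decision")


def status_color(los: float, percentiles: tuple[float, float, float]) -> StatusColor:
    """Map a LOS to its status band given (p50, p75, p95) reference percentiles.

    Bands are lower-inclusive; DARK_RED requires LOS strictly above p95.
    """
    p50, p75, p95 = percentiles
    if not (p50 <= p75 <= p95):
        raise PolicyError(f"unordered percentiles ({p50}, {p75}, {p95})")
    if los < 0:
        raise PolicyError(f"negative LOS {los}")
    if los < p50:
        return StatusColor.GREEN
    if los < p75:
        return StatusColor.YELLOW
    if los <= p95:
        return StatusColor.RED
    return StatusColor.DARK_RED


def awaiting_senior(state: PatientState) -> bool:
    """True once every other step is complete and only the senior decision remains."""
    if state.discharged or state.reneged or state.final_decision_time is not None:
        return False
    return (
        state.triage_time is not None
        and state.first_eval_time is not None
        and state.blood_reviewed == state.n_blood_tests
        and state.imaging_reviewed == state.n_imaging
        and state.specialist_done == state.n_specialist
        and state.treatment_done == state.n_treatment_lines
        and state.senior_done == state.n_senior_evals
    )


def pending_actions(state: PatientState, clock: float) -> list[Action]:
    """All actions the stage graph currently enables for one patient."""
    if state.discharged:
        raise PolicyError(f"{state.patient_id}: patient already discharged")
    if state.reneged:
        return []
    state._check_consistency()
    rt = state.ready_times
    if state.triage_time is None:
        return [Action.make(ActionType.TRIAGE, state.patient_id, rt.get("triage", state.arrival))]
    if state.first_eval_time is None:
        return [
            Action.make(
                ActionType.FIRST_MEDICAL_EVAL, state.patient_id, rt.get("first_eval", state.triage_time)
            )
        ]
    out: list[Action] = []
    base = state.first_eval_time
    if state.blood_drawn < state.n_blood_tests:
        out.append(Action.make(ActionType.BLOOD_DRAW, state.patient_id, rt.get("blood_draw", base)))
    if state.blood_reviewed < state.blood_results_ready:
        out.append(
            Action.make(ActionType.BLOOD_RESULT_REVIEW, state.patient_id, rt.get("blood_review", base))
        )
    if state.imaging_reviewed < state.imaging_ready:
        out.append(
            Action.make(ActionType.IMAGING_REVIEW, state.patient_id, rt.get("imaging_review", base))
        )
    if state.specialist_done < state.n_specialist:
        out.append(
            Action.make(ActionType.SPECIALIST_REVIEW, state.patient_id, rt.get("specialist", base))
        )
    if state.treatment_done < state.n_treatment_lines:
        out.append(Action.make(ActionType.TREATMENT_ADMIN, state.patient_id, rt.get("treatment", base)))
    if state.senior_done < state.n_senior_evals:
        out.append(Action.make(ActionType.SENIOR_EVAL, state.patient_id, rt.get("senior", base)))
    if awaiting_senior(state):
        out.append(Action.make(ActionType.FINAL_DECISION, state.patient_id, rt.get("final", base)))
    if state.end_of_care_time is not None and state.final_decision_time is not None:
        out.append(
            Action.make(
                ActionType.DISCHARGE_PROCESS, state.patient_id, rt.get("discharge", state.end_of_care_time)
            )
        )
    return out


@dataclass
class DeptState:
    """Department-wide snapshot a policy ranks over."""

    clock: float
    patients: dict[str, PatientState]
    reference: LOSReferenceTable
    idle_roles: dict = field(default_factory=dict)

    def color_of(self, state: PatientState) -> StatusColor:
        return status_color(state.los(self.clock), self.reference.percentiles(state.reason))


def is_overcrowded(dept: DeptState) -> bool:
    """Overcrowding = at least one present patient past their reason's p95."""
    return any(
        dept.color_of(p) is StatusColor.DARK_RED for p in dept.patients.values() if p.present
    )


def _effective_color(color: StatusColor, priority: str) -> StatusColor:
    # low-priority patients get no color escalation until they go dark red
    if priority == "low" and color is not StatusColor.DARK_RED:
        return StatusColor.GREEN
    return color


def optimum_rank(action: Action, dept: DeptState) -> tuple:
    """Sortable key for the secondary-triage policy (smaller ranks first)."""
    state = dept.patients.get(action.patient_id)
    if state is None or not state.present:
        raise PolicyError(f"action for absent patient {action.patient_id}")
    enabled = {a.action_type for a in pending_actions(state, dept.clock)}
    if action.action_type not in enabled:
        raise PolicyError(f"{action.patient_id}: {action.action_type.name} is not enabled")
    tier = _TIER[action.action_type]
    if is_overcrowded(dept):
        # discharge-side work outranks intake of new patients
        tier = {0: 2, 1: 1, 2: 0}[tier]
    color = _effective_color(dept.color_of(state), state.priority)
    return (
        tier,
        -int(color),
        _PRIORITY_ORDER[state.priority],
        action.ready_time,
        action.patient_id,
        int(action.action_type),
    )


def standard_rank(action: Action, dept: DeptState) -> tuple:
    """Acuity-then-arrival key of the standard dashboard; no percentile logic."""
    state = dept.patients.get(action.patient_id)
    if state is None or not state.present:
        raise PolicyError(f"action for absent patient {action.patient_id}")
    enabled = {a.action_type for a in pending_actions(state, dept.clock)}
    if action.action_type not in enabled:
        raise PolicyError(f"{action.patient_id}: {action.action_type.name} is not enabled")
    return (
        _PRIORITY_ORDER[state.priority],
        state.arrival,
        action.ready_time,
        action.patient_id,
        int(action.action_type),
    )


_RANKERS = {"optimum": optimum_rank, "standard": standard_rank}


def next_action(role: Role, dept: DeptState, policy: str) -> Optional[Action]:
    """Best-ranked enabled action for a role among patients visible to the policy."""
    try:
        ranker = _RANKERS[policy]
    except KeyError:
        raise PolicyError(f"unknown policy {policy!r}") from None
    candidates: list[Action] = []
    for state in dept.patients.values():
        if not state.present or state.visible_since > dept.clock:
            continue
        for action in pending_actions(state, dept.clock):
            if action.required_role is role and action.ready_time <= dept.clock:
                candidates.append(action)
    if not candidates:
        return None
    return min(candidates, key=lambda a: ranker(a, dept))
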