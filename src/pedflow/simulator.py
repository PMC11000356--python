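"""Discrete-event simulation of a pediatric emergency department.

The simulator doubles as the synthetic-data source for the analysis pipeline.
Two execution modes exist:

* ``passthrough`` (default) — stage intervals are sampled directly from the
  calibrated distributions and composed into trajectories; no queueing.  This
  is the mode used for calibration and parameter-recovery checks, because the
  published interval summaries already include waiting time.
* ``mechanistic`` — a resource-constrained event loop in which idle staff ask
  the active policy for their next action; task times are a configurable
  fraction of the printed intervals and waits emerge from contention.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from . import calibration as cal
from .calibration import (
    CaseMix,
    LognormalParams,
    LOSReferenceTable,
    StageIntervalSpec,
    build_los_reference,
    fit_stage,
)
from .policy import (
    Action,
    ActionType,
    DeptState,
    PatientState,
    Role,
    next_action,
)

__all__ = [
    "PatientProfile",
    "SimConfig",
    "EventLog",
    "sample_arrival_times",
    "sample_patient",
    "sample_stage_duration",
    "sample_transfer_latency",
    "run_simulation",
    "run_trial",
    "TrialResult",
    "default_reference_table",
    "EVENT_COLUMNS",
    "PROFILE_COLUMNS",
]

MINUTES_PER_DAY = 1440.0

EVENT_COLUMNS = ["patient_id", "day", "arm", "event", "t_minutes"]
PROFILE_COLUMNS = [
    "patient_id",
    "day",
    "arm",
    "arrival_minutes",
    "age_months",
    "sex",
    "reason",
    "priority",
    "n_blood_tests",
    "n_imaging",
    "n_specialist",
    "n_treatment_lines",
    "n_senior_evals",
    "disposition",
]

# Milestone vocabulary.  Repeatable events may occur once per care-plan item.
UNIQUE_EVENTS = (
    "arrival",
    "triage",
    "first_eval",
    "junior_eval",
    "final_decision",
    "end_of_care",
    "discharge",
    "lwbs",
)
REPEATABLE_EVENTS = (
    "senior_eval",
    "blood_presc",
    "blood_draw",
    "blood_result_review",
    "imaging_presc",
    "imaging_result_review",
    "specialist_presc",
    "specialist_eval",
    "treatment_presc",
    "treatment_admin",
)
KNOWN_EVENTS = frozenset(UNIQUE_EVENTS) | frozenset(REPEATABLE_EVENTS)


class SimulationError(ValueError):
    pass


class LogLintError(ValueError):
    """An event log violates the stage-graph ordering rules."""


@dataclass(frozen=True)
class PatientProfile:
    """Immutable per-patient attributes and care plan drawn from the case mix."""

    patient_id: str
    arrival_time: float          # absolute minutes from simulation start
    age_months: float
    sex: str                     # 'male' | 'female'
    reason: str
    priority: str                # 'high' | 'moderate' | 'low'
    n_blood_tests: int
    n_imaging: int
    n_specialist: int
    n_treatment_lines: int
    n_senior_evals: int
    disposition: str

    def __post_init__(self) -> None:
        if self.reason not in cal.REASONS:
            raise SimulationError(f"unknown reason {self.reason!r}")
        if self.priority not in cal.PRIORITIES:
            raise SimulationError(f"unknown priority {self.priority!r}")
        if self.disposition not in cal.DISPOSITIONS:
            raise SimulationError(f"unknown disposition {self.disposition!r}")


@dataclass
class SimConfig:
    """Everything a seeded run needs; ``seed`` is mandatory."""

    seed: int
    n_days: int = 1
    arm: str = "control"                  # selects stage specs + policy defaults
    policy: Optional[str] = None          # 'optimum' | 'standard'; default from arm
    mode: str = "passthrough"             # 'passthrough' | 'mechanistic'
    arrivals_per_day: float = 78.0
    overnight_fraction: float = 0.23
    overnight_end: float = 600.0
    resources: dict = field(
        default_factory=lambda: {"nurse": 2, "junior": 2, "senior": 2, "specialist": 1}
    )
    case_mix: Optional[CaseMix] = None
    stage_specs: Optional[dict] = None
    latency_params: Optional[LognormalParams] = None
    reference: Optional[LOSReferenceTable] = None
    lwbs_patience: float = 120.0
    task_fraction: float = 0.35           # mechanistic task time as share of interval
    final_decision_task: float = 5.0
    start_day: int = 0
    male_fraction: float = 0.526

    def __post_init__(self) -> None:
        if self.seed is None:
            raise SimulationError("seed is mandatory")
        if self.n_days < 0:
            raise SimulationError("n_days must be >= 0")
        if not 0.0 <= self.overnight_fraction < 1.0:
            raise SimulationError("overnight_fraction must be in [0, 1)")
        if self.arm not in ("control", "optimum"):
            raise SimulationError(f"unknown arm {self.arm!r}")
        if self.mode not in ("passthrough", "mechanistic"):
            raise SimulationError(f"unknown mode {self.mode!r}")
        if any(v < 0 for v in self.resources.values()):
            raise SimulationError("resource counts must be >= 0")
        if self.policy is None:
            self.policy = "optimum" if self.arm == "optimum" else "standard"

    def resolve(self) -> "SimConfig":
        """Fill in calibrated defaults for any component left unset."""
        cfg = replace(self)
        if cfg.case_mix is None:
            cfg.case_mix = cal.default_case_mix()
        if cfg.stage_specs is None:
            cfg.stage_specs = cal.default_stage_specs(cfg.arm)
        if cfg.latency_params is None and cfg.arm == "optimum":
            cfg.latency_params = cal.default_latency_model()
        if cfg.reference is None:
            cfg.reference = default_reference_table()
        return cfg


@dataclass
class EventLog:
    """Timestamped milestone records plus the per-patient profile sidecar."""

    events: pd.DataFrame
    profiles: pd.DataFrame

    @classmethod
    def from_records(cls, events: list, profiles: list) -> "EventLog":
        ev = pd.DataFrame(events, columns=EVENT_COLUMNS)
        pr = pd.DataFrame(profiles, columns=PROFILE_COLUMNS)
        ev = ev.sort_values(["patient_id", "t_minutes", "event"], kind="stable").reset_index(drop=True)
        return cls(events=ev, profiles=pr)

    def __len__(self) -> int:
        return len(self.events)

    def patient_ids(self) -> list:
        return self.profiles["patient_id"].tolist()

    def concat(self, other: "EventLog") -> "EventLog":
        return EventLog(
            events=pd.concat([self.events, other.events], ignore_index=True),
            profiles=pd.concat([self.profiles, other.profiles], ignore_index=True),
        )

    def lint(self) -> None:
        """Check stage-graph consistency of every trajectory; raise on violation."""
        ev = self.events
        unknown = set(ev["event"]) - KNOWN_EVENTS
        if unknown:
            raise LogLintError(f"unknown event names: {sorted(unknown)}")
        for pid, grp in ev.groupby("patient_id", sort=False):
            t = {name: sub["t_minutes"].to_numpy() for name, sub in grp.groupby("event", sort=False)}
            for name in UNIQUE_EVENTS:
                if name in t and len(t[name]) > 1:
                    raise LogLintError(f"{pid}: duplicate {name}")
            if "arrival" not in t:
                raise LogLintError(f"{pid}: missing arrival")
            arr = t["arrival"][0]
            if np.any(grp["t_minutes"].to_numpy() < arr - 1e-9):
                raise LogLintError(f"{pid}: event precedes arrival")
            if "lwbs" in t:
                allowed = {"arrival", "triage", "lwbs"}
                extra = set(t) - allowed
                if extra:
                    raise LogLintError(f"{pid}: events after leaving without being seen: {sorted(extra)}")
                continue

            def first(name):
                return t[name].min() if name in t else None

            order_chain = ["arrival", "triage", "first_eval"]
            last = arr
            for name in order_chain[1:]:
                v = first(name)
                if v is None:
                    # truncated trajectory: nothing downstream may exist
                    downstream = set(t) - {"arrival", "triage"}
                    if name == "triage" and downstream:
                        raise LogLintError(f"{pid}: events recorded before triage")
                    break
                if v < last - 1e-9:
                    raise LogLintError(f"{pid}: {name} precedes its predecessor")
                last = v
            fe = first("first_eval")
            if fe is not None:
                for name in REPEATABLE_EVENTS:
                    if name in t and np.any(t[name] < fe - 1e-9):
                        raise LogLintError(f"{pid}: {name} precedes first medical evaluation")
                for presc, done in (
                    ("blood_presc", "blood_draw"),
                    ("imaging_presc", "imaging_result_review"),
                    ("specialist_presc", "specialist_eval"),
                    ("treatment_presc", "treatment_admin"),
                ):
                    if done in t and presc not in t:
                        raise LogLintError(f"{pid}: {done} without {presc}")
                if "blood_result_review" in t and "blood_draw" not in t:
                    raise LogLintError(f"{pid}: blood result without a draw")
            fd = first("final_decision")
            if fd is not None:
                mid = [v for name in REPEATABLE_EVENTS if name in t for v in t[name]]
                if mid and max(mid) > fd + 1e-9:
                    raise LogLintError(f"{pid}: care event after the final decision")
                eoc = first("end_of_care")
                if eoc is not None and eoc < fd - 1e-9:
                    raise LogLintError(f"{pid}: end of care precedes the final decision")
                dis = first("discharge")
                if dis is not None:
                    if eoc is None or dis < eoc - 1e-9:
                        raise LogLintError(f"{pid}: discharge out of order")
            elif "discharge" in t or "end_of_care" in t:
                raise LogLintError(f"{pid}: departure without a final decision")


def default_reference_table(
    n: int = 2000, seed: int = 20210315, arm: str = "control"
) -> LOSReferenceTable:
    """Reason-specific LOS percentiles from a seeded synthetic reference cohort.

    Stands in for the tool's historical visit database, which was never
    published; visits are drawn from the calibrated case mix and total-LOS
    distribution so percentile ordering and scale are realistic.
    """
    rng = np.random.default_rng(seed)
    mix = cal.default_case_mix()
    los_model = cal.fit_lognormal_from_quantiles(167, 108, 254)
    reasons = rng.choice(
        list(mix.reason_probs), size=n, p=list(mix.reason_probs.values())
    )
    los = los_model.sample(rng, size=n)
    return build_los_reference(zip(reasons.tolist(), los.tolist()))


def sample_arrival_times(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """One day's arrival times (minutes of day, sorted).

    Piecewise-constant-intensity Poisson process: total count is Poisson with
    mean ``arrivals_per_day``; each arrival falls overnight
    ([0, overnight_end)) with probability ``overnight_fraction``, uniformly
    within its piece.
    """
    n = rng.poisson(config.arrivals_per_day)
    overnight = rng.random(n) < config.overnight_fraction
    u = rng.random(n)
    times = np.where(
        overnight,
        u * config.overnight_end,
        config.overnight_end + u * (MINUTES_PER_DAY - config.overnight_end),
    )
    return np.sort(times)


def _draw_cat(dist: dict, rng: np.random.Generator):
    keys = list(dist)
    return keys[rng.choice(len(keys), p=list(dist.values()))]


def sample_patient(
    case_mix: CaseMix,
    rng: np.random.Generator,
    *,
    patient_id: str = "p0",
    arrival_time: float = 0.0,
    age_model: Optional[LognormalParams] = None,
    male_fraction: float = 0.526,
) -> PatientProfile:
    """Draw a patient from the case-mix marginals (attributes independent)."""
    if age_model is None:
        age_model = cal.default_age_model()
    return PatientProfile(
        patient_id=patient_id,
        arrival_time=arrival_time,
        age_months=float(age_model.sample(rng)),
        sex="male" if rng.random() < male_fraction else "female",
        reason=_draw_cat(case_mix.reason_probs, rng),
        priority=_draw_cat(case_mix.priority_probs, rng),
        n_blood_tests=int(_draw_cat(case_mix.blood_test_count_probs, rng)),
        n_imaging=int(_draw_cat(case_mix.imaging_count_probs, rng)),
        n_specialist=int(_draw_cat(case_mix.specialist_count_probs, rng)),
        n_treatment_lines=int(_draw_cat(case_mix.treatment_line_probs, rng)),
        n_senior_evals=int(_draw_cat(case_mix.senior_eval_count_probs, rng)),
        disposition=_draw_cat(case_mix.disposition_probs, rng),
    )


def sample_stage_duration(
    stage: str, specs: dict, rng: np.random.Generator, *, fitted_cache: Optional[dict] = None
) -> float:
    """One draw from the (zero-inflated) log-normal fitted to a stage's spec."""
    if stage not in specs:
        raise SimulationError(f"unknown stage {stage!r}")
    if fitted_cache is not None:
        params = fitted_cache.get(stage)
        if params is None:
            params = fitted_cache[stage] = fit_stage(specs[stage])
    else:
        params = fit_stage(specs[stage])
    return float(params.sample(rng))


def sample_transfer_latency(latency_params: LognormalParams, rng: np.random.Generator) -> float:
    """Minutes until a new arrival becomes visible to the secondary-triage tool."""
    return float(latency_params.sample(rng))


# ---------------------------------------------------------------------------
# trajectory generation

def _profile_row(p: PatientProfile, day: int, arm: str) -> list:
    return [
        p.patient_id,
        day,
        arm,
        p.arrival_time,
        p.age_months,
        p.sex,
        p.reason,
        p.priority,
        p.n_blood_tests,
        p.n_imaging,
        p.n_specialist,
        p.n_treatment_lines,
        p.n_senior_evals,
        p.disposition,
    ]


def _passthrough_trajectory(
    p: PatientProfile, fitted: dict, rng: np.random.Generator, cfg: SimConfig
) -> list[tuple[str, float]]:
    """Compose one trajectory by sampling each printed interval directly."""

    def d(stage: str) -> float:
        return float(fitted[stage].sample(rng))

    t0 = p.arrival_time
    out = [("arrival", t0)]
    if p.disposition == "lwbs":
        out.append(("lwbs", t0 + cfg.lwbs_patience))
        return out
    triage = t0 + d("admission_to_triage")
    first_eval = triage + d("triage_to_first_eval")
    junior = first_eval + d("first_eval_to_junior_eval")
    out += [("triage", triage), ("first_eval", first_eval), ("junior_eval", junior)]
    completions = [junior]
    for _ in range(p.n_blood_tests):
        draw = first_eval + d("blood_presc_to_draw")
        result = draw + d("blood_draw_to_result")
        out += [("blood_presc", first_eval), ("blood_draw", draw), ("blood_result_review", result)]
        completions.append(result)
    for _ in range(p.n_imaging):
        result = first_eval + d("imaging_presc_to_result")
        out += [("imaging_presc", first_eval), ("imaging_result_review", result)]
        completions.append(result)
    for _ in range(p.n_specialist):
        seen = first_eval + d("specialist_presc_to_eval")
        out += [("specialist_presc", first_eval), ("specialist_eval", seen)]
        completions.append(seen)
    for _ in range(p.n_treatment_lines):
        admin = first_eval + d("treatment_presc_to_admin")
        out += [("treatment_presc", first_eval), ("treatment_admin", admin)]
        completions.append(admin)
    senior_t = None
    for k in range(p.n_senior_evals):
        if k == 0:
            senior_t = max(first_eval, t0 + d("admission_to_senior_eval"))
        else:
            senior_t = senior_t + d("first_eval_to_junior_eval")
        out.append(("senior_eval", senior_t))
        completions.append(senior_t)
    final = max(completions)
    end_of_care = final + d("final_senior_to_end_of_care")
    discharge = end_of_care + d("end_of_care_to_discharge")
    out += [("final_decision", final), ("end_of_care", end_of_care), ("discharge", discharge)]
    return out


# ---------------------------------------------------------------------------
# mechanistic engine

_TASK_STAGE = {
    ActionType.TRIAGE: "admission_to_triage",
    ActionType.FIRST_MEDICAL_EVAL: "triage_to_first_eval",
    ActionType.SENIOR_EVAL: "first_eval_to_junior_eval",
    ActionType.BLOOD_DRAW: "blood_presc_to_draw",
    ActionType.BLOOD_RESULT_REVIEW: "blood_draw_to_result",
    ActionType.IMAGING_REVIEW: "imaging_presc_to_result",
    ActionType.SPECIALIST_REVIEW: "specialist_presc_to_eval",
    ActionType.TREATMENT_ADMIN: "treatment_presc_to_admin",
    ActionType.DISCHARGE_PROCESS: "end_of_care_to_discharge",
}


class _Engine:
    """heapq-driven event loop; waits emerge from staff contention."""

    def __init__(self, cfg: SimConfig, fitted: dict, rng: np.random.Generator):
        self.cfg = cfg
        self.fitted = fitted
        self.rng = rng
        self.heap: list = []
        self.seq = 0
        self.dept = DeptState(clock=0.0, patients={}, reference=cfg.reference)
        self.idle = {Role(r): int(n) for r, n in cfg.resources.items()}
        self.in_service: set[str] = set()
        self.records: list[tuple[str, str, float]] = []  # (patient_id, event, t)

    def push(self, t: float, kind: str, payload) -> None:
        heapq.heappush(self.heap, (t, self.seq, kind, payload))
        self.seq += 1

    def stamp(self, pid: str, event: str, t: float) -> None:
        self.records.append((pid, event, t))

    def d(self, stage: str) -> float:
        return float(self.fitted[stage].sample(self.rng))

    def task_time(self, action: Action) -> float:
        if action.action_type is ActionType.FINAL_DECISION:
            return self.cfg.final_decision_task
        return self.cfg.task_fraction * self.d(_TASK_STAGE[action.action_type])

    def add_patient(self, profile: PatientProfile, latency: float) -> None:
        state = PatientState(
            patient_id=profile.patient_id,
            arrival=profile.arrival_time,
            reason=profile.reason,
            priority=profile.priority,
            n_blood_tests=profile.n_blood_tests,
            n_imaging=profile.n_imaging,
            n_specialist=profile.n_specialist,
            n_treatment_lines=profile.n_treatment_lines,
            n_senior_evals=profile.n_senior_evals,
            visible_since=profile.arrival_time + latency,
        )
        self.dept.patients[profile.patient_id] = state
        self.stamp(profile.patient_id, "arrival", profile.arrival_time)
        if latency > 0:
            self.push(state.visible_since, "wake", None)
        if profile.disposition == "lwbs":
            self.push(profile.arrival_time + self.cfg.lwbs_patience, "renege", profile.patient_id)

    def run(self) -> None:
        while self.heap:
            t, _, kind, payload = heapq.heappop(self.heap)
            self.dept.clock = t
            if kind == "arrival":
                profile, latency = payload
                self.add_patient(profile, latency)
            elif kind == "renege":
                state = self.dept.patients[payload]
                if (
                    state.present
                    and state.first_eval_time is None
                    and payload not in self.in_service
                ):
                    state.reneged = True
                    self.stamp(payload, "lwbs", t)
            elif kind == "ready":
                self._apply_ready(t, payload)
            elif kind == "complete":
                self._apply_complete(t, payload)
            # 'wake' needs no state change; it just triggers a dispatch pass
            self.dispatch(t)

    def _apply_ready(self, t: float, payload) -> None:
        pid, what = payload
        state = self.dept.patients[pid]
        if not state.present:
            return
        if what == "blood_result":
            state.blood_results_ready += 1
            state.ready_times.setdefault("blood_review", t)
        elif what == "imaging":
            state.imaging_ready += 1
            state.ready_times.setdefault("imaging_review", t)
        elif what == "end_of_care":
            state.end_of_care_time = t
            state.ready_times["discharge"] = t
            self.stamp(pid, "end_of_care", t)

    def _apply_complete(self, t: float, payload) -> None:
        action: Action = payload
        pid = action.patient_id
        state = self.dept.patients[pid]
        self.in_service.discard(pid)
        self.idle[action.required_role] += 1
        at = action.action_type
        if at is ActionType.TRIAGE:
            state.triage_time = t
            self.stamp(pid, "triage", t)
        elif at is ActionType.FIRST_MEDICAL_EVAL:
            state.first_eval_time = t
            self.stamp(pid, "first_eval", t)
            for _ in range(state.n_blood_tests):
                self.stamp(pid, "blood_presc", t)
            for _ in range(state.n_imaging):
                self.stamp(pid, "imaging_presc", t)
                turnaround = (1.0 - self.cfg.task_fraction) * self.d("imaging_presc_to_result")
                self.push(t + turnaround, "ready", (pid, "imaging"))
            for _ in range(state.n_specialist):
                self.stamp(pid, "specialist_presc", t)
            for _ in range(state.n_treatment_lines):
                self.stamp(pid, "treatment_presc", t)
        elif at is ActionType.BLOOD_DRAW:
            state.blood_drawn += 1
            self.stamp(pid, "blood_draw", t)
            turnaround = (1.0 - self.cfg.task_fraction) * self.d("blood_draw_to_result")
            self.push(t + turnaround, "ready", (pid, "blood_result"))
        elif at is ActionType.BLOOD_RESULT_REVIEW:
            state.blood_reviewed += 1
            self.stamp(pid, "blood_result_review", t)
        elif at is ActionType.IMAGING_REVIEW:
            state.imaging_reviewed += 1
            self.stamp(pid, "imaging_result_review", t)
        elif at is ActionType.SPECIALIST_REVIEW:
            state.specialist_done += 1
            self.stamp(pid, "specialist_eval", t)
        elif at is ActionType.TREATMENT_ADMIN:
            state.treatment_done += 1
            self.stamp(pid, "treatment_admin", t)
        elif at is ActionType.SENIOR_EVAL:
            state.senior_done += 1
            self.stamp(pid, "senior_eval", t)
        elif at is ActionType.FINAL_DECISION:
            state.final_decision_time = t
            self.stamp(pid, "final_decision", t)
            self.push(t + self.d("final_senior_to_end_of_care"), "ready", (pid, "end_of_care"))
        elif at is ActionType.DISCHARGE_PROCESS:
            state.discharge_time = t
            self.stamp(pid, "discharge", t)

    def dispatch(self, t: float) -> None:
        # one staff member per patient at a time: hide in-service patients from
        # the (pure) policy by pushing their visibility past the clock
        hidden: dict[str, float] = {}
        try:
            for pid in self.in_service:
                state = self.dept.patients[pid]
                hidden[pid] = state.visible_since
                state.visible_since = math.inf
            for role in list(self.idle):
                while self.idle[role] > 0:
                    action = next_action(role, self.dept, self.cfg.policy)
                    if action is None:
                        break
                    self.idle[role] -= 1
                    self.in_service.add(action.patient_id)
                    state = self.dept.patients[action.patient_id]
                    hidden[action.patient_id] = state.visible_since
                    state.visible_since = math.inf
                    self.push(t + self.task_time(action), "complete", action)
        finally:
            for pid, vis in hidden.items():
                self.dept.patients[pid].visible_since = vis


# ---------------------------------------------------------------------------
# top-level runs

def _fit_all(specs: dict) -> dict:
    return {stage: fit_stage(spec) for stage, spec in specs.items()}


def run_simulation(config: SimConfig) -> EventLog:
    """Simulate ``config.n_days`` consecutive days under one arm and policy."""
    cfg = config.resolve()
    fitted = _fit_all(cfg.stage_specs)
    root = np.random.SeedSequence(cfg.seed)
    day_seeds = root.spawn(max(cfg.n_days, 1))
    events: list = []
    profiles: list = []
    age_model = cal.default_age_model()
    pid_counter = 0
    engine = None
    if cfg.mode == "mechanistic":
        engine_rng = np.random.default_rng(root.spawn(1)[0])
        engine = _Engine(cfg, fitted, engine_rng)
    for local_day in range(cfg.n_days):
        day = cfg.start_day + local_day
        rng = np.random.default_rng(day_seeds[local_day])
        times = sample_arrival_times(cfg, rng)
        for tod in times:
            pid = f"d{day:03d}p{pid_counter:05d}"
            pid_counter += 1
            abs_t = day * MINUTES_PER_DAY + float(tod)
            profile = sample_patient(
                cfg.case_mix,
                rng,
                patient_id=pid,
                arrival_time=abs_t,
                age_model=age_model,
                male_fraction=cfg.male_fraction,
            )
            profiles.append(_profile_row(profile, day, cfg.arm))
            if cfg.arm == "optimum" and cfg.latency_params is not None:
                latency = sample_transfer_latency(cfg.latency_params, rng)
            else:
                latency = 0.0
            if cfg.mode == "passthrough":
                for event, t in _passthrough_trajectory(profile, fitted, rng, cfg):
                    events.append([pid, day, cfg.arm, event, t])
            else:
                engine.push(abs_t, "arrival", (profile, latency))
    if cfg.mode == "mechanistic":
        engine.run()
        day_of = {row[0]: row[1] for row in profiles}
        for pid, event, t in engine.records:
            events.append([pid, day_of[pid], cfg.arm, event, t])
    log = EventLog.from_records(events, profiles)
    _check_conservation(log)
    return log


def _check_conservation(log: EventLog) -> None:
    """Admitted = discharged + reneged + still-present; every run must balance."""
    admitted = set(log.profiles["patient_id"])
    ev = log.events
    discharged = set(ev.loc[ev["event"] == "discharge", "patient_id"])
    reneged = set(ev.loc[ev["event"] == "lwbs", "patient_id"])
    arrived = set(ev.loc[ev["event"] == "arrival", "patient_id"])
    if arrived != admitted:
        raise SimulationError("event log and profile sidecar disagree on admissions")
    if discharged & reneged:
        raise SimulationError("a patient both discharged and reneged")
    still_present = admitted - discharged - reneged
    if len(admitted) != len(discharged) + len(reneged) + len(still_present):
        raise SimulationError("patient conservation violated")


@dataclass(frozen=True)
class TrialResult:
    """Paired logs plus the stratified day-to-arm assignment."""

    log: EventLog
    assignment: dict           # day -> arm
    strata: dict               # day -> 'weekday' | 'weekend'


def assign_days(
    n_days: int, rng: np.random.Generator, *, start_weekday: int = 0
) -> tuple[dict, dict]:
    """Randomize days to arms separately within weekday/weekend strata.

    Balanced within each stratum to ±1; deterministic given the generator.
    """
    strata = {
        day: ("weekend" if (start_weekday + day) % 7 >= 5 else "weekday")
        for day in range(n_days)
    }
    assignment: dict = {}
    for stratum in ("weekday", "weekend"):
        days = [d for d in range(n_days) if strata[d] == stratum]
        half = len(days) // 2
        arms = ["optimum"] * half + ["control"] * (len(days) - half)
        if len(days) % 2 == 1 and rng.random() < 0.5:
            arms = ["control"] * half + ["optimum"] * (len(days) - half)
        rng.shuffle(arms)
        assignment.update(dict(zip(days, arms)))
    return assignment, strata


def run_trial(config: SimConfig, seed: Optional[int] = None) -> TrialResult:
    """Simulate a day-randomized two-arm trial.

    Each day is simulated under its assigned arm's policy and stage specs;
    ``config.arm`` is ignored.
    """
    if config.n_days < 2:
        raise SimulationError("a trial needs at least 2 days")
    if seed is None:
        seed = config.seed
    root = np.random.SeedSequence(seed)
    assign_seq, *day_seqs = root.spawn(1 + config.n_days)
    assignment, strata = assign_days(config.n_days, np.random.default_rng(assign_seq))
    log: Optional[EventLog] = None
    for day in range(config.n_days):
        arm = assignment[day]
        day_cfg = replace(
            config,
            seed=int(np.random.default_rng(day_seqs[day]).integers(2**31 - 1)),
            n_days=1,
            arm=arm,
            policy=None,
            stage_specs=None,
            latency_params=None,
            start_day=day,
        )
        day_log = run_simulation(day_cfg)
        log = day_log if log is None else log.concat(day_log)
    return TrialResult(log=log, assignment=assignment, strata=strata)


def filter_analysis_window(
    log: EventLog,
    *,
    start_minute: float = 600.0,
    end_minute: float = MINUTES_PER_DAY,
    exclude_dispositions: Iterable[str] = ("lwbs",),
) -> EventLog:
    """Keep patients arriving within [start, end) of their day; drop exclusions."""
    prof = log.profiles
    tod = prof["arrival_minutes"].to_numpy() % MINUTES_PER_DAY
    keep = (tod >= start_minute) & (tod < end_minute)
    keep &= ~prof["disposition"].isin(list(exclude_dispositions)).to_numpy()
    kept_ids = set(prof.loc[keep, "patient_id"])
    return EventLog(
        events=log.events[log.events["patient_id"].isin(kept_ids)].reset_index(drop=True),
        profiles=prof[keep].reset_index(drop=True),
    )
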