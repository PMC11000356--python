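import numpy as np
import pytest

from pedflow.calibration import LOSReferenceTable
from pedflow.policy import DeptState, PatientState

REASON_PCTS = {
    "fever": (120.0, 200.0, 380.0),
    "respiratory": (150.0, 240.0, 420.0),
    "digestive": (140.0, 220.0, 400.0),
    "trauma": (100.0, 170.0, 330.0),
    "other": (160.0, 260.0, 460.0),
}


@pytest.fixture
def reference():
    return LOSReferenceTable(table=REASON_PCTS)


def random_patient_state(rng: np.random.Generator, pid: str, clock: float) -> PatientState:
    """A structurally consistent patient at a random point in the stage graph."""
    arrival = float(rng.uniform(0, clock)) if clock > 0 else 0.0
    state = PatientState(
        patient_id=pid,
        arrival=arrival,
        reason=str(rng.choice(list(REASON_PCTS))),
        priority=str(rng.choice(["high", "moderate", "low"])),
        n_blood_tests=int(rng.integers(0, 3)),
        n_imaging=int(rng.integers(0, 3)),
        n_specialist=int(rng.integers(0, 2)),
        n_treatment_lines=int(rng.integers(0, 2)),
        n_senior_evals=int(rng.integers(0, 3)),
        visible_since=arrival,
    )
    phase = rng.integers(0, 5)  # 0 untri, 1 triaged, 2 mid-stay, 3 ready-final, 4 post-decision
    if phase == 0:
        return state
    state.triage_time = arrival + float(rng.uniform(1, 30))
    if phase == 1:
        return state
    state.first_eval_time = state.triage_time + float(rng.uniform(1, 60))
    if phase >= 3:
        state.blood_drawn = state.n_blood_tests
        state.blood_results_ready = state.n_blood_tests
        state.blood_reviewed = state.n_blood_tests
        state.imaging_ready = state.n_imaging
        state.imaging_reviewed = state.n_imaging
        state.specialist_done = state.n_specialist
        state.treatment_done = state.n_treatment_lines
        state.senior_done = state.n_senior_evals
        if phase == 4:
            state.final_decision_time = state.first_eval_time + float(rng.uniform(1, 120))
            state.end_of_care_time = state.final_decision_time + float(rng.uniform(0, 60))
        return state
    # mid-stay: partial, internally ordered progress on each plan item
    state.blood_drawn = int(rng.integers(0, state.n_blood_tests + 1))
    state.blood_results_ready = int(rng.integers(0, state.blood_drawn + 1))
    state.blood_reviewed = int(rng.integers(0, state.blood_results_ready + 1))
    state.imaging_ready = int(rng.integers(0, state.n_imaging + 1))
    state.imaging_reviewed = int(rng.integers(0, state.imaging_ready + 1))
    state.specialist_done = int(rng.integers(0, state.n_specialist + 1))
    state.treatment_done = int(rng.integers(0, state.n_treatment_lines + 1))
    state.senior_done = int(rng.integers(0, state.n_senior_evals + 1))
    return state


def random_department(rng: np.random.Generator, reference, n_patients: int, clock: float = 600.0):
    patients = {}
    for i in range(n_patients):
        pid = f"p{i:03d}"
        patients[pid] = random_patient_state(rng, pid, clock)
    return DeptState(clock=clock, patients=patients, reference=reference)
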