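"""Random session generator for detector/oracle equivalence testing.

Generates structurally valid but behaviourally arbitrary event streams over
a small four-diagnosis domain, including deletions, links, incomplete cases
and confidence marks, so the detectors are exercised well outside the
simulator's tidy patterns.
"""

import numpy as np

from dxbias.case_sequence import SequencePlan
from dxbias.knowledge_base import CaseDefinition
from dxbias.session_log import ActionEvent, CaseRecord, EventKind, Session

FINDINGS = ["g1", "g2", "g3", "g4", "g5", "g6"]
DIAGNOSES = ["A", "B", "C", "D"]

MICRO_CASES = {
    c.case_id: c
    for c in [
        CaseDefinition("x1", "X", frozenset({"A"}), frozenset({"g1", "g2"})),
        CaseDefinition("x2", "X", frozenset({"A"}), frozenset({"g1"})),
        CaseDefinition("x3", "X", frozenset({"A"}), frozenset({"g2"})),
        CaseDefinition("x4", "X", frozenset({"B"}), frozenset({"g3"})),
        CaseDefinition("x5", "X", frozenset({"B"}), frozenset({"g2", "g3"})),
        CaseDefinition("x6", "X", frozenset({"C"}), frozenset({"g4"})),
        CaseDefinition("x7", "X", frozenset({"D"}), frozenset({"g5"})),
        CaseDefinition("x8", "X", frozenset({"A", "B"}), frozenset({"g1", "g3"})),
    ]
}


def random_plan(rng: np.random.Generator, n_cases: int = 6) -> SequencePlan:
    ids = list(MICRO_CASES)
    rng.shuffle(ids)
    return SequencePlan(sequences={"X": tuple(ids[:n_cases])})


def random_case_record(rng: np.random.Generator, case_id: str, max_events: int = 12) -> CaseRecord:
    events = []
    seq = 0

    def emit(kind, payload=None):
        nonlocal seq
        seq += 1
        events.append(ActionEvent(seq, kind, payload))

    completed = rng.random() < 0.9
    # Reserve room for the mandatory hypothesis/diagnosis and CLOSE.
    n_body = int(rng.integers(1, max_events - 3))
    kinds = rng.choice(
        ["F", "H", "D", "DEL", "LINK"], size=n_body, p=[0.40, 0.18, 0.24, 0.08, 0.10]
    )
    for k in kinds:
        if k == "F":
            emit(EventKind.ADD_FINDING, str(rng.choice(FINDINGS)))
        elif k == "H":
            emit(EventKind.ADD_HYPOTHESIS, str(rng.choice(DIAGNOSES)))
        elif k == "D":
            emit(EventKind.ADD_DIAGNOSIS, str(rng.choice(DIAGNOSES)))
        elif k == "DEL":
            item = str(rng.choice(["finding", "hypothesis", "diagnosis"]))
            pool = FINDINGS if item == "finding" else DIAGNOSES
            emit(EventKind.DELETE_ITEM, {"item": item, "label": str(rng.choice(pool))})
        else:
            emit(
                EventKind.ADD_LINK,
                {
                    "finding": str(rng.choice(FINDINGS)),
                    "hypothesis": str(rng.choice(DIAGNOSES)),
                    "polarity": str(rng.choice(["support", "refute"])),
                },
            )
    if completed:
        present = {e.kind for e in events}
        if EventKind.ADD_HYPOTHESIS not in present:
            emit(EventKind.ADD_HYPOTHESIS, str(rng.choice(DIAGNOSES)))
        if EventKind.ADD_DIAGNOSIS not in present:
            emit(EventKind.ADD_DIAGNOSIS, str(rng.choice(DIAGNOSES)))
        emit(EventKind.CLOSE_CASE)
        for label in list(dict.fromkeys(e.payload for e in events if e.kind is EventKind.ADD_FINDING))[:2]:
            emit(
                EventKind.MARK_CONFIDENCE,
                {"item": "finding", "label": label,
                 "rating": str(rng.choice(["sure", "unsure"]))},
            )
    return CaseRecord(case_id=case_id, events=tuple(events))


def random_session(rng: np.random.Generator, pid: str, plan: SequencePlan) -> Session:
    records = tuple(
        random_case_record(rng, cid) for sub in plan.sequences for cid in plan.sequences[sub]
    )
    return Session(participant_id=pid, level=int(rng.integers(1, 4)), case_records=records)
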