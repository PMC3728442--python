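import pytest
from hypothesis import HealthCheck, settings

from dxbias.knowledge_base import build_kb, study_case_library, study_kb
from dxbias.case_sequence import build_default_plan
from dxbias.session_log import ActionEvent, CaseRecord, EventKind, Session

settings.register_profile(
    "ci", derandomize=True, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def kb():
    return study_kb()


@pytest.fixture(scope="session")
def cases(kb):
    return study_case_library(kb)


@pytest.fixture(scope="session")
def plan(cases):
    return build_default_plan(cases, seed=0)


@pytest.fixture(scope="session")
def micro_kb():
    """Four-diagnosis knowledge base for randomized oracle comparisons."""
    return build_kb(
        findings=["g1", "g2", "g3", "g4", "g5", "g6"],
        diagnoses=["A", "B", "C", "D"],
        relations=[
            ("g1", "A", "support"),
            ("g2", "A", "support"),
            ("g2", "B", "support"),
            ("g3", "B", "support"),
            ("g4", "C", "support"),
            ("g5", "D", "support"),
            ("g6", "A", "refute"),
        ],
        taught_pairs=[("g1", "A"), ("g3", "B"), ("g4", "C")],
    )


# -- event-stream shorthand ----------------------------------------------

_KINDS = {
    "F": EventKind.ADD_FINDING,
    "H": EventKind.ADD_HYPOTHESIS,
    "D": EventKind.ADD_DIAGNOSIS,
}


def make_record(case_id, *steps):
    """Build a CaseRecord from compact step tuples.

    ("F"|"H"|"D", label), ("LINK", finding, hypothesis, polarity),
    ("DEL", item_kind, label), ("MARK", item_kind, label, rating), ("CLOSE",).
    """
    events = []
    for seq, step in enumerate(steps, start=1):
        op = step[0]
        if op in _KINDS:
            events.append(ActionEvent(seq, _KINDS[op], step[1]))
        elif op == "LINK":
            events.append(
                ActionEvent(
                    seq,
                    EventKind.ADD_LINK,
                    {"finding": step[1], "hypothesis": step[2], "polarity": step[3]},
                )
            )
        elif op == "DEL":
            events.append(
                ActionEvent(seq, EventKind.DELETE_ITEM, {"item": step[1], "label": step[2]})
            )
        elif op == "MARK":
            events.append(
                ActionEvent(
                    seq,
                    EventKind.MARK_CONFIDENCE,
                    {"item": step[1], "label": step[2], "rating": step[3]},
                )
            )
        elif op == "CLOSE":
            events.append(ActionEvent(seq, EventKind.CLOSE_CASE))
        else:
            raise ValueError(f"unknown step {step!r}")
    return CaseRecord(case_id=case_id, events=tuple(events))


def make_session(pid, records, level=1):
    return Session(participant_id=pid, level=level, case_records=tuple(records))
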