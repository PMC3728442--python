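import numpy as np

from dxbias.case_sequence import SequencePlan
from dxbias.detectors import (
    Label,
    detect_all,
    detect_anchoring,
    detect_availability,
    detect_confirmation,
    detect_gamblers,
    detect_representativeness,
    detect_satisficing,
)
from dxbias.knowledge_base import CaseDefinition
from dxbias.session_log import evaluate_case, evaluate_session

from conftest import make_record, make_session
from oracles import (
    brute_anchoring,
    brute_confirmation,
    brute_representativeness,
    brute_satisficing,
    brute_sequence_biases,
)
from session_gen import MICRO_CASES, random_plan, random_session

BP_CASE = CaseDefinition(
    "bp", "SVD", frozenset({"bullous pemphigoid"}), frozenset({"blister"})
)


def _labels(detections):
    return {d.label for d in detections}


# -- anchoring -----------------------------------------------------------


def test_anchoring_heuristic_on_supported_nonadjustment(kb):
    record = make_record(
        "bp",
        ("H", "bullous pemphigoid"),
        ("F", "blister"),
        ("D", "bullous pemphigoid"),
        ("CLOSE",),
    )
    ec = evaluate_case(record, kb, BP_CASE)
    assert _labels(detect_anchoring(ec, kb)) == {Label.ANCHOR_HEURISTIC}


def test_no_episode_when_finding_precedes_hypothesis(kb):
    record = make_record(
        "bp",
        ("F", "blister"),
        ("H", "bullous pemphigoid"),
        ("D", "bullous pemphigoid"),
        ("CLOSE",),
    )
    ec = evaluate_case(record, kb, BP_CASE)
    assert detect_anchoring(ec, kb) == []


def test_anchoring_bias_on_unsupported_diagnosis(kb):
    # sarcoidal granulomas support sarcoidosis only; diagnosing leprosy
    # without adjustment is the bias.
    case = CaseDefinition(
        "n1", "NDD", frozenset({"sarcoidosis"}), frozenset({"sarcoidal naked granulomas"})
    )
    record = make_record(
        "n1",
        ("H", "sarcoidosis"),
        ("F", "sarcoidal naked granulomas"),
        ("D", "lepromatous leprosy"),
        ("CLOSE",),
    )
    ec = evaluate_case(record, kb, case)
    assert _labels(detect_anchoring(ec, kb)) == {Label.ANCHOR_BIAS}
    assert _labels(detect_anchoring(ec, kb)) == brute_anchoring(record, kb)


def test_anchoring_bias_averted_by_later_adjustment(kb):
    case = CaseDefinition(
        "n1", "NDD", frozenset({"sarcoidosis"}), frozenset({"sarcoidal naked granulomas"})
    )
    record = make_record(
        "n1",
        ("H", "lupus vulgaris"),
        ("F", "sarcoidal naked granulomas"),
        ("D", "lepromatous leprosy"),
        ("D", "sarcoidosis"),  # supported by the episode finding
        ("CLOSE",),
    )
    ec = evaluate_case(record, kb, case)
    # The second diagnosis is itself a supported episode (heuristic), and its
    # presence rescues the first from the bias clause.
    assert _labels(detect_anchoring(ec, kb)) == {Label.ANCHOR_HEURISTIC}


# -- confirmation --------------------------------------------------------


def test_confirmation_fires_on_supported_wrong_diagnosis(kb):
    record = make_record(
        "bp",
        ("H", "pemphigoid gestationis"),
        ("D", "pemphigoid gestationis"),
        ("F", "eosinophils in blister cavity"),
        ("CLOSE",),
    )
    ec = evaluate_case(record, kb, BP_CASE)
    det = detect_confirmation(ec, kb)
    assert det is not None and det.label is Label.CONFIRMATION_BIAS


def test_confirmation_requires_incorrect_diagnosis(kb):
    record = make_record(
        "bp",
        ("H", "bullous pemphigoid"),
        ("D", "bullous pemphigoid"),
        ("F", "blister"),
        ("CLOSE",),
    )
    ec = evaluate_case(record, kb, BP_CASE)
    assert detect_confirmation(ec, kb) is None


def test_confirmation_window_sensitivity(kb):
    # An intervening hypothesis breaks immediacy but not the any_later variant.
    record = make_record(
        "bp",
        ("D", "pemphigoid gestationis"),
        ("H", "bullous pemphigoid"),
        ("F", "eosinophils in blister cavity"),
        ("D", "bullous pemphigoid"),
        ("CLOSE",),
    )
    ec = evaluate_case(record, kb, BP_CASE)
    assert detect_confirmation(ec, kb, window="next") is None
    assert detect_confirmation(ec, kb, window="any_later") is not None
    for window in ("next", "any_later"):
        got = detect_confirmation(ec, kb, window=window) is not None
        assert got == brute_confirmation(record, BP_CASE, kb, window=window)


# -- satisficing ---------------------------------------------------------


def test_satisficing_on_incorrect_immediate_close(kb):
    case = CaseDefinition(
        "n1", "NDD", frozenset({"sarcoidosis"}), frozenset({"sarcoidal naked granulomas"})
    )
    record = make_record(
        "n1",
        ("F", "sarcoidal naked granulomas"),
        ("H", "acne conglobata"),
        ("D", "acne conglobata"),
        ("CLOSE",),
    )
    ec = evaluate_case(record, kb, case)
    det = detect_satisficing(ec)
    assert det is not None and det.label is Label.SATISFICING_BIAS


def test_satisficing_blocked_by_intervening_finding(kb):
    record = make_record(
        "bp",
        ("H", "pemphigoid gestationis"),
        ("F", "blister"),
        ("D", "pemphigoid gestationis"),
        ("CLOSE",),
    )
    ec = evaluate_case(record, kb, BP_CASE)
    assert detect_satisficing(ec) is None


def test_satisficing_on_correct_but_incomplete_differential(kb):
    case = CaseDefinition(
        "svd", "SVD",
        frozenset({"toxic epidermal necrolysis", "bullous drug eruption"}),
        frozenset({"full-thickness epidermal necrosis"}),
    )
    record = make_record(
        "svd",
        ("H", "toxic epidermal necrolysis"),
        ("D", "toxic epidermal necrolysis"),
        ("CLOSE",),
    )
    ec = evaluate_case(record, kb, case)
    det = detect_satisficing(ec)
    assert det is not None
    assert brute_satisficing(record, case)


def test_satisficing_blocked_by_add_after_diagnosis(kb):
    record = make_record(
        "bp",
        ("H", "pemphigoid gestationis"),
        ("D", "pemphigoid gestationis"),
        ("LINK", "blister", "pemphigoid gestationis", "support"),
        ("CLOSE",),
    )
    ec = evaluate_case(record, kb, BP_CASE)
    assert detect_satisficing(ec) is None


# -- representativeness --------------------------------------------------


def _taught_pair_record(case_id, dx="sarcoidosis"):
    return make_record(
        case_id,
        ("F", "sarcoidal naked granulomas"),
        ("D", dx),
        ("H", dx),
        ("CLOSE",),
    )


def test_representativeness_needs_repetition(kb):
    case = CaseDefinition("n1", "NDD", frozenset({"sarcoidosis"}), frozenset())
    ecs = [evaluate_case(_taught_pair_record("n1"), kb, case)]
    assert detect_representativeness(ecs, kb) == {}


def test_representativeness_labels_each_occurrence_by_own_case(kb):
    correct = CaseDefinition("n1", "NDD", frozenset({"sarcoidosis"}), frozenset())
    wrong = CaseDefinition("n2", "NDD", frozenset({"lupus vulgaris"}), frozenset())
    ecs = [
        evaluate_case(_taught_pair_record("n1"), kb, correct),
        evaluate_case(_taught_pair_record("n2"), kb, wrong),
    ]
    out = detect_representativeness(ecs, kb)
    assert _labels(out["n1"]) == {Label.REPR_HEURISTIC}
    assert _labels(out["n2"]) == {Label.REPR_BIAS}
    brute = brute_representativeness(
        [(ecs[0].record, correct), (ecs[1].record, wrong)], kb
    )
    assert {cid: _labels(d) for cid, d in out.items()} == brute


def test_untaught_pair_never_labels(kb):
    # caseating granulomas -> lupus vulgaris is supported but not taught
    case = CaseDefinition("n1", "NDD", frozenset({"lupus vulgaris"}), frozenset())
    rec = make_record(
        "n1", ("F", "caseating granulomas"), ("D", "lupus vulgaris"), ("H", "lupus vulgaris"), ("CLOSE",)
    )
    rec2 = make_record(
        "n2", ("F", "caseating granulomas"), ("D", "lupus vulgaris"), ("H", "lupus vulgaris"), ("CLOSE",)
    )
    ecs = [evaluate_case(rec, kb, case), evaluate_case(rec2, kb, CaseDefinition("n2", "NDD", frozenset({"lupus vulgaris"}), frozenset()))]
    assert detect_representativeness(ecs, kb) == {}


# -- availability / gambler's fallacy ------------------------------------

_SEQ_CASES = {
    "c1": CaseDefinition("c1", "X", frozenset({"A"}), frozenset()),
    "c2": CaseDefinition("c2", "X", frozenset({"A"}), frozenset()),
    "c3": CaseDefinition("c3", "X", frozenset({"B"}), frozenset()),
    "c4": CaseDefinition("c4", "X", frozenset({"A"}), frozenset()),
}
_AVAIL_PLAN = SequencePlan(sequences={"X": ("c1", "c2", "c3")})
_GAMB_PLAN = SequencePlan(sequences={"X": ("c1", "c2", "c4")})


def _answer_record(case_id, dx):
    return make_record(case_id, ("H", dx), ("D", dx), ("CLOSE",))


def _evaluated(records, kb_micro):
    session = make_session("p", records)
    return evaluate_session(session, kb_micro, _SEQ_CASES)


def test_availability_flags_preceding_diagnosis(micro_kb):
    ecs = _evaluated(
        [_answer_record("c1", "A"), _answer_record("c2", "A"), _answer_record("c3", "A")],
        micro_kb,
    )
    out = detect_availability(ecs, _AVAIL_PLAN, _SEQ_CASES)
    assert set(out) == {"c3"}
    assert out["c3"].evidence == ("c1", "c2", "c3")


def test_availability_ignores_other_wrong_answers(micro_kb):
    ecs = _evaluated(
        [_answer_record("c1", "A"), _answer_record("c2", "A"), _answer_record("c3", "C")],
        micro_kb,
    )
    assert detect_availability(ecs, _AVAIL_PLAN, _SEQ_CASES) == {}


def test_availability_not_flagged_when_correct(micro_kb):
    ecs = _evaluated(
        [_answer_record("c1", "A"), _answer_record("c2", "A"), _answer_record("c3", "B")],
        micro_kb,
    )
    assert detect_availability(ecs, _AVAIL_PLAN, _SEQ_CASES) == {}


def test_availability_requires_completed_predecessors(micro_kb):
    incomplete = make_record("c1", ("H", "A"), ("D", "A"))  # never closed
    ecs = _evaluated(
        [incomplete, _answer_record("c2", "A"), _answer_record("c3", "A")], micro_kb
    )
    assert detect_availability(ecs, _AVAIL_PLAN, _SEQ_CASES) == {}


def test_gamblers_flags_deviation(micro_kb):
    ecs = _evaluated(
        [_answer_record("c1", "A"), _answer_record("c2", "A"), _answer_record("c4", "C")],
        micro_kb,
    )
    assert set(detect_gamblers(ecs, _GAMB_PLAN, _SEQ_CASES)) == {"c4"}


def test_gamblers_no_flag_without_deviation(micro_kb):
    ecs = _evaluated(
        [_answer_record("c1", "A"), _answer_record("c2", "A"), _answer_record("c4", "A")],
        micro_kb,
    )
    assert detect_gamblers(ecs, _GAMB_PLAN, _SEQ_CASES) == {}


def test_gamblers_previous_answers_may_be_wrong(micro_kb):
    ecs = _evaluated(
        [_answer_record("c1", "B"), _answer_record("c2", "B"), _answer_record("c4", "C")],
        micro_kb,
    )
    assert set(detect_gamblers(ecs, _GAMB_PLAN, _SEQ_CASES)) == {"c4"}


# -- whole-session composition ------------------------------------------


def test_detect_all_equals_merge_of_individual_detectors(micro_kb):
    rng = np.random.default_rng(42)
    plan = random_plan(rng)
    sessions = [random_session(rng, f"p{i}", plan) for i in range(5)]
    report = detect_all(sessions, micro_kb, plan, MICRO_CASES)
    for session in sessions:
        ecs = evaluate_session(session, micro_kb, MICRO_CASES)
        merged = {}
        for ec in ecs:
            labels = _labels(detect_anchoring(ec, micro_kb))
            conf = detect_confirmation(ec, micro_kb)
            if conf:
                labels.add(conf.label)
            sat = detect_satisficing(ec)
            if sat:
                labels.add(sat.label)
            if labels:
                merged[ec.case_id] = labels
        for cid, dets in detect_representativeness(ecs, micro_kb).items():
            merged.setdefault(cid, set()).update(_labels(dets))
        for cid, det in detect_availability(ecs, plan, MICRO_CASES).items():
            merged.setdefault(cid, set()).add(det.label)
        for cid, det in detect_gamblers(ecs, plan, MICRO_CASES).items():
            merged.setdefault(cid, set()).add(det.label)
        pid = session.participant_id
        got = {
            cid: set(labels)
            for (p, cid), labels in report.labels.items()
            if p == pid
        }
        assert got == merged


def test_detect_all_deterministic(micro_kb):
    rng = np.random.default_rng(7)
    plan = random_plan(rng)
    sessions = [random_session(rng, f"p{i}", plan) for i in range(3)]
    a = detect_all(sessions, micro_kb, plan, MICRO_CASES)
    b = detect_all(sessions, micro_kb, plan, MICRO_CASES)
    assert a.labels == b.labels
    assert a.to_frame().equals(b.to_frame())


def test_empty_session_empty_report(micro_kb):
    plan = SequencePlan(sequences={"X": ()})
    session = make_session("p", [])
    report = detect_all([session], micro_kb, plan, MICRO_CASES)
    assert report.labels == {}


def test_detectors_match_bruteforce_on_random_sessions(micro_kb):
    """Randomized cross-check against the naive enumerators (small scale;
    the acceptance suite runs the full-size version)."""
    rng = np.random.default_rng(1234)
    for i in range(60):
        plan = random_plan(rng)
        session = random_session(rng, f"p{i}", plan)
        ecs = evaluate_session(session, micro_kb, MICRO_CASES)
        for ec in ecs:
            assert _labels(detect_anchoring(ec, micro_kb)) == brute_anchoring(
                ec.record, micro_kb
            )
            got = detect_confirmation(ec, micro_kb) is not None
            assert got == brute_confirmation(ec.record, ec.case, micro_kb)
            assert (detect_satisficing(ec) is not None) == brute_satisficing(
                ec.record, ec.case
            )
        repr_got = {
            cid: _labels(dets)
            for cid, dets in detect_representativeness(ecs, micro_kb).items()
        }
        assert repr_got == brute_representativeness(
            [(ec.record, ec.case) for ec in ecs], micro_kb
        )
        seq_got = {}
        for cid, det in detect_availability(ecs, plan, MICRO_CASES).items():
            seq_got.setdefault(cid, set()).add(det.label)
        for cid, det in detect_gamblers(ecs, plan, MICRO_CASES).items():
            seq_got.setdefault(cid, set()).add(det.label)
        assert seq_got == brute_sequence_biases(session, plan, MICRO_CASES)
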