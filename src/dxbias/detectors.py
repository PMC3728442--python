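"""Deterministic rule-based detectors for eight heuristics and biases.

Each detector is a pure function of evaluated session data. The single-case
rules (anchoring, confirmation, search satisficing) look at one case's add
events; representativeness scans the whole session; availability and
gambler's fallacy fire only at designed opportunity positions of the case
sequence. A case is labelled at most once per label regardless of how many
episodes matched, and a case may carry several labels at once.

Deletions and confidence marks are transparent to every sequential rule:
the rules fire on actions as performed, so an anchored hypothesis that is
later deleted still anchored.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

import pandas as pd

from .calibration import ConfidenceScore, case_bias_score
from .case_sequence import SequencePlan, enumerate_opportunities
from .errors import UndefinedScoreError
from .knowledge_base import CaseDefinition, DxVerdict, KnowledgeBase
from .session_log import EvaluatedCase, EventKind, Session, evaluate_session


class Label(str, Enum):
    ANCHOR_HEURISTIC = "ANCHOR_HEURISTIC"
    ANCHOR_BIAS = "ANCHOR_BIAS"
    AVAILABILITY_BIAS = "AVAILABILITY_BIAS"
    CONFIRMATION_BIAS = "CONFIRMATION_BIAS"
    GAMBLERS_BIAS = "GAMBLERS_BIAS"
    REPR_HEURISTIC = "REPR_HEURISTIC"
    REPR_BIAS = "REPR_BIAS"
    SATISFICING_BIAS = "SATISFICING_BIAS"


BIAS_LABELS = frozenset(
    {
        Label.ANCHOR_BIAS,
        Label.AVAILABILITY_BIAS,
        Label.CONFIRMATION_BIAS,
        Label.GAMBLERS_BIAS,
        Label.REPR_BIAS,
        Label.SATISFICING_BIAS,
    }
)
HEURISTIC_LABELS = frozenset({Label.ANCHOR_HEURISTIC, Label.REPR_HEURISTIC})

#: Labels confined to opportunity cases of the sequence plan.
SEQUENCE_LABELS = frozenset({Label.AVAILABILITY_BIAS, Label.GAMBLERS_BIAS})


@dataclass(frozen=True)
class Detection:
    label: Label
    #: seq numbers (single-case rules) or case-id triple (sequence rules)
    #: that triggered the label.
    evidence: tuple


def _incorrect(ec: EvaluatedCase) -> bool:
    return ec.dx_verdict is DxVerdict.INCORRECT


# -- anchoring -----------------------------------------------------------


def detect_anchoring(ec: EvaluatedCase, kb: KnowledgeBase) -> list[Detection]:
    """Anchoring heuristic and/or bias for one completed case.

    An episode is a hypothesis followed by at least one finding and then a
    diagnosis. The episode's finding set is every finding added after the
    anchoring hypothesis (the remainder of the case). The episode is the
    *heuristic* when the diagnosis is supported by every episode finding —
    whether it equals the hypothesis (sufficient non-adjustment) or not
    (sufficient adjustment). It is the *bias* when the diagnosis is not so
    supported and no subsequent hypothesis or diagnosis in the case is
    supported by all episode findings (insufficient adjustment). The case
    carries the union over episodes, so distinct episodes can make a case
    both heuristic and bias.
    """
    if not ec.completed:
        return []
    adds = ec.record.add_events()
    findings = [e for e in adds if e.kind is EventKind.ADD_FINDING]
    out: dict[Label, tuple] = {}
    for h in adds:
        if h.kind is not EventKind.ADD_HYPOTHESIS:
            continue
        episode_findings = [f for f in findings if f.seq > h.seq]
        if not episode_findings:
            continue
        first_f_seq = episode_findings[0].seq
        flabels = {f.label for f in episode_findings}
        for d in adds:
            if d.kind is not EventKind.ADD_DIAGNOSIS or d.seq <= first_f_seq:
                continue
            supported = all(kb.is_supporting(f, d.label) for f in flabels)
            if supported:
                out.setdefault(Label.ANCHOR_HEURISTIC, (h.seq, d.seq))
            else:
                adjusted = any(
                    e.kind in (EventKind.ADD_HYPOTHESIS, EventKind.ADD_DIAGNOSIS)
                    and e.seq > d.seq
                    and all(kb.is_supporting(f, e.label) for f in flabels)
                    for e in adds
                )
                if not adjusted:
                    out.setdefault(Label.ANCHOR_BIAS, (h.seq, d.seq))
    return [Detection(label, ev) for label, ev in out.items()]


# -- confirmation --------------------------------------------------------


def detect_confirmation(
    ec: EvaluatedCase, kb: KnowledgeBase, *, window: str = "next"
) -> Optional[Detection]:
    """Confirmation bias: an incorrect diagnosis followed by a finding that
    supports it.

    With ``window='next'`` (default) the supporting finding must be the very
    next add-type action after the incorrect diagnosis; ``window='any_later'``
    accepts any later finding in the case (sensitivity variant).
    """
    if window not in ("next", "any_later"):
        raise ValueError(f"window must be 'next' or 'any_later', got {window!r}")
    if not ec.completed:
        return None
    adds = ec.record.add_events()
    for i, d in enumerate(adds):
        if d.kind is not EventKind.ADD_DIAGNOSIS or ec.verdicts[d.seq]:
            continue
        if window == "next":
            later = adds[i + 1 : i + 2]
        else:
            later = adds[i + 1 :]
        for f in later:
            if f.kind is EventKind.ADD_FINDING and kb.is_supporting(f.label, d.label):
                return Detection(Label.CONFIRMATION_BIAS, (d.seq, f.seq))
    return None


# -- search satisficing --------------------------------------------------


def detect_satisficing(ec: EvaluatedCase) -> Optional[Detection]:
    """Search-satisficing bias: hypothesis straight to diagnosis, then close.

    Requires, on a completed case: (a) any findings precede the first
    hypothesis, (b) a hypothesis is followed by a diagnosis with no finding
    between them, (c) the final differential is incorrect or correct but
    incomplete, and (d) the case is closed immediately after the diagnosis —
    no add-type action between the final diagnosis and CLOSE_CASE.
    """
    if not ec.completed:
        return None
    if ec.dx_verdict not in (DxVerdict.INCORRECT, DxVerdict.CORRECT_INCOMPLETE):
        return None
    adds = ec.record.add_events()
    hyp_seqs = [e.seq for e in adds if e.kind is EventKind.ADD_HYPOTHESIS]
    if not hyp_seqs:
        return None
    first_hyp = hyp_seqs[0]
    if any(e.kind is EventKind.ADD_FINDING and e.seq > first_hyp for e in adds):
        return None  # (a)
    if not adds or adds[-1].kind is not EventKind.ADD_DIAGNOSIS:
        return None  # (d)
    final_d = adds[-1]
    if not any(s < final_d.seq for s in hyp_seqs):
        return None  # (b); with (a) holding, no finding can intervene
    return Detection(Label.SATISFICING_BIAS, (first_hyp, final_d.seq))


# -- representativeness --------------------------------------------------


def detect_representativeness(
    evaluated: Iterable[EvaluatedCase], kb: KnowledgeBase
) -> dict[str, list[Detection]]:
    """Representativeness (Type 2) heuristic/bias across a whole session.

    An occurrence is a finding immediately followed (next add-type action)
    by a diagnosis where the pair was taught in the study material. Pairs
    occurring more than once across the session qualify; each qualifying
    occurrence labels its own case — heuristic when that diagnosis is
    correct for that case, bias when incorrect.
    """
    occurrences: dict[tuple[str, str], list[tuple[str, bool, tuple[int, int]]]] = {}
    for ec in evaluated:
        if not ec.completed:
            continue
        adds = ec.record.add_events()
        for f, d in zip(adds, adds[1:]):
            if f.kind is EventKind.ADD_FINDING and d.kind is EventKind.ADD_DIAGNOSIS:
                pair = (f.label, d.label)
                if pair in kb.taught_pairs:
                    occurrences.setdefault(pair, []).append(
                        (ec.case_id, ec.verdicts[d.seq], (f.seq, d.seq))
                    )
    out: dict[str, dict[Label, tuple]] = {}
    for pair, occs in occurrences.items():
        if len(occs) < 2:
            continue
        for case_id, dx_correct, evid in occs:
            label = Label.REPR_HEURISTIC if dx_correct else Label.REPR_BIAS
            out.setdefault(case_id, {}).setdefault(label, evid)
    return {
        cid: [Detection(label, ev) for label, ev in labels.items()]
        for cid, labels in out.items()
    }


# -- availability and gambler's fallacy ----------------------------------


def _by_case(evaluated: Iterable[EvaluatedCase]) -> dict[str, EvaluatedCase]:
    return {ec.case_id: ec for ec in evaluated}


def detect_availability(
    evaluated: Iterable[EvaluatedCase],
    plan: SequencePlan,
    cases: Mapping[str, CaseDefinition],
) -> dict[str, Detection]:
    """Availability bias on the plan's availability-opportunity cases.

    An opportunity case is flagged when the participant's final differential
    is incorrect and contains a member of the shared acceptable set of the
    two immediately preceding cases (whose summaries exposed that diagnosis).
    Both predecessors must have been completed by the participant.
    """
    ec_by_case = _by_case(evaluated)
    out: dict[str, Detection] = {}
    for cid in enumerate_opportunities(plan, cases, "availability"):
        ec = ec_by_case.get(cid)
        if ec is None or not ec.completed:
            continue
        p1, p2 = plan.predecessors(cid)
        pred1, pred2 = ec_by_case.get(p1), ec_by_case.get(p2)
        if pred1 is None or pred2 is None or not (pred1.completed and pred2.completed):
            continue
        shared = cases[p2].acceptable_dx  # == cases[p1].acceptable_dx by construction
        if _incorrect(ec) and ec.final_dx & shared:
            out[cid] = Detection(Label.AVAILABILITY_BIAS, (p1, p2, cid))
    return out


def detect_gamblers(
    evaluated: Iterable[EvaluatedCase],
    plan: SequencePlan,
    cases: Mapping[str, CaseDefinition],
) -> dict[str, Detection]:
    """Gambler's-fallacy bias on the plan's gambler's-opportunity cases.

    On a triple of same-diagnosis cases, the participant gave the same
    differential (correct or not) on the first two, then a different and
    incorrect differential on the third.
    """
    ec_by_case = _by_case(evaluated)
    out: dict[str, Detection] = {}
    for cid in enumerate_opportunities(plan, cases, "gamblers"):
        ec = ec_by_case.get(cid)
        if ec is None or not ec.completed:
            continue
        p1, p2 = plan.predecessors(cid)
        pred1, pred2 = ec_by_case.get(p1), ec_by_case.get(p2)
        if pred1 is None or pred2 is None or not (pred1.completed and pred2.completed):
            continue
        prev = pred1.final_dx
        if not prev or pred2.final_dx != prev:
            continue
        if _incorrect(ec) and ec.final_dx != prev:
            out[cid] = Detection(Label.GAMBLERS_BIAS, (p1, p2, cid))
    return out


# -- aggregation ---------------------------------------------------------


@dataclass
class DetectionReport:
    """Per (participant, case) label sets with triggering evidence, plus
    per-case confidence scores."""

    labels: dict[tuple[str, str], dict[Label, tuple]] = field(default_factory=dict)
    confidence: dict[tuple[str, str], ConfidenceScore] = field(default_factory=dict)

    def add(self, participant: str, case_id: str, detection: Detection) -> None:
        self.labels.setdefault((participant, case_id), {}).setdefault(
            detection.label, detection.evidence
        )

    def labels_for(self, participant: str, case_id: str) -> frozenset[Label]:
        return frozenset(self.labels.get((participant, case_id), {}))

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "participant": pid,
                "case": cid,
                "label": label.value,
                "evidence": ";".join(str(x) for x in evidence),
            }
            for (pid, cid), labels in sorted(self.labels.items())
            for label, evidence in sorted(labels.items(), key=lambda kv: kv[0].value)
        ]
        return pd.DataFrame(rows, columns=["participant", "case", "label", "evidence"])

    def confidence_frame(self) -> pd.DataFrame:
        rows = [
            {
                "participant": pid,
                "case": cid,
                "total_sure": s.total_sure,
                "total_correct": s.total_correct,
                "total_items": s.total_items,
                "bias_score": s.score,
            }
            for (pid, cid), s in sorted(self.confidence.items())
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "participant", "case", "total_sure", "total_correct",
                "total_items", "bias_score",
            ],
        )


def detect_case(
    ec: EvaluatedCase, kb: KnowledgeBase, *, confirmation_window: str = "next"
) -> list[Detection]:
    """Run the three single-case detectors on one evaluated case."""
    detections = list(detect_anchoring(ec, kb))
    conf = detect_confirmation(ec, kb, window=confirmation_window)
    if conf:
        detections.append(conf)
    sat = detect_satisficing(ec)
    if sat:
        detections.append(sat)
    return detections


def detect_all(
    sessions: Iterable[Session],
    kb: KnowledgeBase,
    plan: SequencePlan,
    cases: Mapping[str, CaseDefinition],
    *,
    confirmation_window: str = "next",
    warn_unmarked: bool = False,
) -> DetectionReport:
    """Evaluate and label every session; deterministic for identical inputs."""
    report = DetectionReport()
    for session in sessions:
        pid = session.participant_id
        evaluated = evaluate_session(session, kb, cases)
        for ec in evaluated:
            for det in detect_case(ec, kb, confirmation_window=confirmation_window):
                report.add(pid, ec.case_id, det)
            if ec.completed:
                try:
                    report.confidence[(pid, ec.case_id)] = case_bias_score(
                        ec, warn_unmarked=warn_unmarked
                    )
                except UndefinedScoreError:
                    pass
        for cid, dets in detect_representativeness(evaluated, kb).items():
            for det in dets:
                report.add(pid, cid, det)
        for cid, det in detect_availability(evaluated, plan, cases).items():
            report.add(pid, cid, det)
        for cid, det in detect_gamblers(evaluated, plan, cases).items():
            report.add(pid, cid, det)
    return report
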