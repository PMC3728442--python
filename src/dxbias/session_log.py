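"""Participant sessions: ordered per-case event streams and their evaluation.

A session is the full event trace of one participant working through the case
sequence. Events are the atomic user actions the reasoning interface records:
identifying a finding, proposing a hypothesis, committing a diagnosis, linking
a finding to a hypothesis, deleting an item, marking confidence ('sure' /
'unsure') after the case is closed, and closing the case.

Evaluation replays each case against the knowledge base and case truth,
grading every add action (correct/incorrect), reconstructing the final
differential live at close, and classifying it. Evaluation is a pure
function: identical inputs always produce identical output.
"""

from __future__ import annotations

import csv
import io
import json
from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Any, Optional, Union

from .errors import CaseLookupError, LogIntegrityError, LogParseError, VocabularyError
from .knowledge_base import (
    CaseDefinition,
    DxVerdict,
    KnowledgeBase,
    classify_diagnosis,
)


class EventKind(str, Enum):
    ADD_FINDING = "ADD_FINDING"
    ADD_HYPOTHESIS = "ADD_HYPOTHESIS"
    ADD_DIAGNOSIS = "ADD_DIAGNOSIS"
    ADD_LINK = "ADD_LINK"
    DELETE_ITEM = "DELETE_ITEM"
    MARK_CONFIDENCE = "MARK_CONFIDENCE"
    CLOSE_CASE = "CLOSE_CASE"


#: Event kinds that create a reasoning entity. Deletions and confidence marks
#: are transparent to all sequential detection rules.
ADD_KINDS = frozenset(
    {EventKind.ADD_FINDING, EventKind.ADD_HYPOTHESIS, EventKind.ADD_DIAGNOSIS, EventKind.ADD_LINK}
)

#: Kinds whose payload is a bare entity label.
LABEL_KINDS = frozenset(
    {EventKind.ADD_FINDING, EventKind.ADD_HYPOTHESIS, EventKind.ADD_DIAGNOSIS}
)


@dataclass(frozen=True)
class ActionEvent:
    """One atomic user action.

    ``payload`` is a bare label for ADD_FINDING/ADD_HYPOTHESIS/ADD_DIAGNOSIS;
    ``{"finding", "hypothesis", "polarity"}`` for ADD_LINK;
    ``{"item", "label"}`` for DELETE_ITEM (``item`` in finding/hypothesis/
    diagnosis, optional); ``{"label", "rating"[, "item"]}`` for
    MARK_CONFIDENCE with rating 'sure' or 'unsure'; None for CLOSE_CASE.
    """

    seq: int
    kind: EventKind
    payload: Any = None
    t: Optional[str] = None

    @property
    def label(self) -> Optional[str]:
        if self.kind in LABEL_KINDS:
            return str(self.payload).strip()
        if isinstance(self.payload, Mapping):
            lab = self.payload.get("label")
            return None if lab is None else str(lab).strip()
        return None


@dataclass(frozen=True)
class CaseRecord:
    """Ordered event stream of one participant on one case."""

    case_id: str
    events: tuple[ActionEvent, ...]

    def __post_init__(self) -> None:
        seqs = [e.seq for e in self.events]
        if any(b <= a for a, b in zip(seqs, seqs[1:])):
            raise LogIntegrityError(
                f"case {self.case_id!r}: event seq numbers must be strictly increasing"
            )
        closes = [i for i, e in enumerate(self.events) if e.kind is EventKind.CLOSE_CASE]
        if len(closes) > 1:
            raise LogIntegrityError(f"case {self.case_id!r}: CLOSE_CASE appears more than once")
        close_at = closes[0] if closes else None
        for i, e in enumerate(self.events):
            if e.kind is EventKind.MARK_CONFIDENCE and (close_at is None or i < close_at):
                raise LogIntegrityError(
                    f"case {self.case_id!r}: MARK_CONFIDENCE before CLOSE_CASE (seq {e.seq})"
                )
            if close_at is not None and i > close_at and e.kind is not EventKind.MARK_CONFIDENCE:
                raise LogIntegrityError(
                    f"case {self.case_id!r}: only MARK_CONFIDENCE may follow CLOSE_CASE"
                )
        if close_at is not None:
            before = {e.kind for e in self.events[:close_at]}
            if EventKind.ADD_HYPOTHESIS not in before or EventKind.ADD_DIAGNOSIS not in before:
                raise LogIntegrityError(
                    f"case {self.case_id!r}: a completed case requires at least one "
                    "hypothesis and one diagnosis before CLOSE_CASE"
                )

    @property
    def completed(self) -> bool:
        return any(e.kind is EventKind.CLOSE_CASE for e in self.events)

    def pre_close_events(self) -> tuple[ActionEvent, ...]:
        """Events up to (excluding) CLOSE_CASE; all events if never closed."""
        out = []
        for e in self.events:
            if e.kind is EventKind.CLOSE_CASE:
                break
            out.append(e)
        return tuple(out)

    def add_events(self) -> tuple[ActionEvent, ...]:
        """Pre-close events of an add kind, in order (the detector view)."""
        return tuple(e for e in self.pre_close_events() if e.kind in ADD_KINDS)


@dataclass(frozen=True)
class Session:
    """One participant's ordered case records.

    ``level`` groups participants by training: 1 = Y1-2 residents,
    2 = Y3-4 residents, 3 = fellows and junior attendings.
    """

    participant_id: str
    level: int
    case_records: tuple[CaseRecord, ...]

    def __post_init__(self) -> None:
        if self.level not in (1, 2, 3):
            raise LogIntegrityError(
                f"participant {self.participant_id!r}: level must be 1, 2 or 3, got {self.level!r}"
            )
        seen = set()
        for rec in self.case_records:
            if rec.case_id in seen:
                raise LogIntegrityError(
                    f"participant {self.participant_id!r}: duplicate case {rec.case_id!r}"
                )
            seen.add(rec.case_id)

    def record(self, case_id: str) -> Optional[CaseRecord]:
        for rec in self.case_records:
            if rec.case_id == case_id:
                return rec
        return None


@dataclass(frozen=True)
class EvaluatedCase:
    """A CaseRecord joined with its grading against case truth.

    ``verdicts`` maps the seq of every ADD_FINDING/ADD_HYPOTHESIS/
    ADD_DIAGNOSIS event to a correctness boolean. ``final_dx`` is the set of
    diagnoses live (added, not deleted) at CLOSE_CASE; ``dx_verdict`` is None
    for cases never completed or closed with an empty differential.
    """

    record: CaseRecord
    case: CaseDefinition
    verdicts: Mapping[int, bool]
    final_dx: frozenset[str]
    live_findings: frozenset[str]
    dx_verdict: Optional[DxVerdict]
    marks: Mapping[tuple[str, str], str]  # (item_kind, label) -> 'sure' | 'unsure'

    @property
    def case_id(self) -> str:
        return self.record.case_id

    @property
    def completed(self) -> bool:
        return self.record.completed

    def correct(self, seq: int) -> bool:
        return self.verdicts[seq]


# -- parsing -------------------------------------------------------------

_REQUIRED_FIELDS = ("participant", "level", "case", "seq", "kind")


def _coerce_payload(raw: Any) -> Any:
    if isinstance(raw, str):
        raw = raw.strip()
        if raw.startswith("{"):
            return json.loads(raw)
        return raw or None
    return raw


def _iter_lines(stream) -> Iterable[str]:
    is_path = isinstance(stream, Path) or (
        isinstance(stream, str) and "\n" not in stream and Path(stream).exists()
    )
    if is_path:
        with open(stream) as fh:
            yield from fh
    elif isinstance(stream, str):
        yield from io.StringIO(stream)
    else:
        yield from stream


def parse_session_log(stream: Union[str, Path, Iterable[str]]) -> list["Session"]:
    """Parse a line-delimited event log into Sessions.

    Accepts a path, a multi-line string, or an iterable of lines. Two
    dialects are supported: JSONL (one object per line with keys
    ``participant, level, case, seq, kind, payload[, t]``) and CSV with the
    same columns (structured payloads JSON-encoded in the cell). Sessions are
    returned sorted by participant id; case order follows first appearance in
    the log; events are ordered by seq.
    """
    rows: list[dict] = []
    reader = None
    for lineno, line in enumerate(_iter_lines(stream), start=1):
        line = line.rstrip("\n")
        if not line.strip():
            continue
        if reader is None and not line.lstrip().startswith("{"):
            # CSV dialect: first line is the header.
            reader = csv.DictReader([line])
            continue
        if reader is not None:
            parsed = next(csv.DictReader([line], fieldnames=reader.fieldnames))
        else:
            try:
                parsed = json.loads(line)
            except json.JSONDecodeError as exc:
                raise LogParseError(f"line {lineno}: invalid JSON: {exc}") from None
        missing = [k for k in _REQUIRED_FIELDS if parsed.get(k) in (None, "")]
        if missing:
            raise LogParseError(f"line {lineno}: missing field(s) {missing}")
        try:
            kind = EventKind(str(parsed["kind"]).strip())
        except ValueError:
            raise LogParseError(f"line {lineno}: unknown event kind {parsed['kind']!r}") from None
        try:
            rows.append(
                {
                    "participant": str(parsed["participant"]).strip(),
                    "level": int(parsed["level"]),
                    "case": str(parsed["case"]).strip(),
                    "seq": int(parsed["seq"]),
                    "kind": kind,
                    "payload": _coerce_payload(parsed.get("payload")),
                    "t": parsed.get("t") or None,
                    "lineno": lineno,
                }
            )
        except (TypeError, ValueError) as exc:
            raise LogParseError(f"line {lineno}: {exc}") from None

    by_participant: dict[str, dict] = {}
    seen_keys: dict[tuple[str, str, int], int] = {}
    for row in rows:
        key = (row["participant"], row["case"], row["seq"])
        if key in seen_keys:
            raise LogIntegrityError(
                f"line {row['lineno']}: duplicate (participant, case, seq) {key}; "
                f"first seen at line {seen_keys[key]}"
            )
        seen_keys[key] = row["lineno"]
        part = by_participant.setdefault(
            row["participant"], {"level": row["level"], "cases": {}}
        )
        if part["level"] != row["level"]:
            raise LogIntegrityError(
                f"participant {row['participant']!r}: inconsistent training level"
            )
        part["cases"].setdefault(row["case"], []).append(row)

    sessions = []
    for pid in sorted(by_participant):
        part = by_participant[pid]
        records = []
        for case_id, case_rows in part["cases"].items():
            case_rows.sort(key=lambda r: r["seq"])
            events = tuple(
                ActionEvent(seq=r["seq"], kind=r["kind"], payload=r["payload"], t=r["t"])
                for r in case_rows
            )
            records.append(CaseRecord(case_id=case_id, events=events))
        sessions.append(Session(participant_id=pid, level=part["level"], case_records=tuple(records)))
    return sessions


def write_session_log(sessions: Iterable[Session], path: Union[str, Path]) -> None:
    """Serialize sessions to a JSONL event log (inverse of parse_session_log)."""
    with open(path, "w") as fh:
        for s in sessions:
            for rec in s.case_records:
                for e in rec.events:
                    obj = {
                        "participant": s.participant_id,
                        "level": s.level,
                        "case": rec.case_id,
                        "seq": e.seq,
                        "kind": e.kind.value,
                        "payload": e.payload,
                    }
                    if e.t is not None:
                        obj["t"] = e.t
                    fh.write(json.dumps(obj, sort_keys=True) + "\n")


# -- evaluation ----------------------------------------------------------

_ITEM_KINDS = ("finding", "hypothesis", "diagnosis")
_KIND_TO_ITEM = {
    EventKind.ADD_FINDING: "finding",
    EventKind.ADD_HYPOTHESIS: "hypothesis",
    EventKind.ADD_DIAGNOSIS: "diagnosis",
}


def evaluate_case(record: CaseRecord, kb: KnowledgeBase, case: CaseDefinition) -> EvaluatedCase:
    """Replay one case record against case truth.

    Add actions are graded as performed (a later deletion does not retract
    the verdict); the live state drives ``final_dx`` and the confidence
    denominators only.
    """
    live: dict[str, set[str]] = {k: set() for k in _ITEM_KINDS}
    verdicts: dict[int, bool] = {}
    final_dx: frozenset[str] = frozenset()
    live_findings: frozenset[str] = frozenset()
    marks: dict[tuple[str, str], str] = {}
    closed = False
    for e in record.events:
        if e.kind in LABEL_KINDS:
            label = e.label
            item = _KIND_TO_ITEM[e.kind]
            vocab = kb.findings if item == "finding" else kb.diagnoses
            if label not in vocab:
                raise VocabularyError(
                    f"case {record.case_id!r} seq {e.seq}: unknown {item} label {label!r}"
                )
            truth = case.true_findings if item == "finding" else case.acceptable_dx
            verdicts[e.seq] = label in truth
            live[item].add(label)
        elif e.kind is EventKind.DELETE_ITEM:
            label = e.label
            which = None
            if isinstance(e.payload, Mapping):
                which = e.payload.get("item")
            targets = [which] if which else list(_ITEM_KINDS)
            for item in targets:
                live[item].discard(label)
        elif e.kind is EventKind.CLOSE_CASE:
            closed = True
            final_dx = frozenset(live["diagnosis"])
            live_findings = frozenset(live["finding"])
        elif e.kind is EventKind.MARK_CONFIDENCE:
            payload = e.payload if isinstance(e.payload, Mapping) else {}
            label = str(payload.get("label", "")).strip()
            rating = str(payload.get("rating", "")).strip()
            if rating not in ("sure", "unsure"):
                raise LogParseError(
                    f"case {record.case_id!r} seq {e.seq}: confidence rating must be "
                    f"'sure' or 'unsure', got {rating!r}"
                )
            which = payload.get("item")
            targets = [which] if which else _ITEM_KINDS
            for item in targets:
                marks[(item, label)] = rating
    dx_verdict = None
    if closed and final_dx:
        dx_verdict = classify_diagnosis(case, final_dx)
    return EvaluatedCase(
        record=record,
        case=case,
        verdicts=verdicts,
        final_dx=final_dx,
        live_findings=live_findings,
        dx_verdict=dx_verdict,
        marks=marks,
    )


def evaluate_session(
    session: Session,
    kb: KnowledgeBase,
    cases: Mapping[str, CaseDefinition],
) -> list[EvaluatedCase]:
    """Evaluate every case record of a session, in session order."""
    out = []
    for rec in session.case_records:
        if rec.case_id not in cases:
            raise CaseLookupError(
                f"participant {session.participant_id!r}: no case definition for "
                f"{rec.case_id!r}"
            )
        out.append(evaluate_case(rec, kb, cases[rec.case_id]))
    return out
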