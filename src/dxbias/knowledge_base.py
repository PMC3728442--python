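"""Domain model: finding/diagnosis vocabularies, support relations, case truth.

The knowledge base mirrors the structure a tutoring system uses to grade
diagnostic reasoning: a controlled vocabulary of histopathologic findings and
diagnoses, directed finding->diagnosis relations with a polarity (a finding
either *supports* or *refutes* a diagnosis), and the subset of supporting
finding-diagnosis pairs that were explicitly taught in the study material
(these drive the representativeness rule).

Each case carries its expert ground truth: the set of *acceptable* diagnoses
(any member counts as correct) and the findings actually present.
"""

from __future__ import annotations

import csv
import json
from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Optional, Union

import yaml

from .errors import KBValidationError, VocabularyError


class Polarity(str, Enum):
    SUPPORT = "support"
    REFUTE = "refute"


class DxVerdict(str, Enum):
    """Verdict on a final differential relative to the acceptable set."""

    CORRECT_COMPLETE = "correct_complete"
    CORRECT_INCOMPLETE = "correct_incomplete"
    INCORRECT = "incorrect"


def _clean(label: str) -> str:
    return str(label).strip()


@dataclass(frozen=True)
class KnowledgeBase:
    """Validated domain model.

    Parameters
    ----------
    findings, diagnoses
        Label vocabularies (case-sensitive exact strings, whitespace-trimmed).
    relations
        Mapping ``(finding, diagnosis) -> Polarity``. At most one polarity per
        pair (conflicting duplicates are rejected at load time).
    taught_pairs
        Supporting pairs included in the study material; must be a subset of
        the support relations.
    """

    findings: frozenset[str]
    diagnoses: frozenset[str]
    relations: Mapping[tuple[str, str], Polarity]
    taught_pairs: frozenset[tuple[str, str]]

    def __post_init__(self) -> None:
        for (f, d), pol in self.relations.items():
            if f not in self.findings:
                raise KBValidationError(
                    f"relation ({f!r}, {d!r}, {pol.value}) references undeclared finding {f!r}"
                )
            if d not in self.diagnoses:
                raise KBValidationError(
                    f"relation ({f!r}, {d!r}, {pol.value}) references undeclared diagnosis {d!r}"
                )
        for f, d in self.taught_pairs:
            if self.relations.get((f, d)) is not Polarity.SUPPORT:
                raise KBValidationError(
                    f"taught pair ({f!r}, {d!r}) has no support relation in the knowledge base"
                )

    # -- queries ---------------------------------------------------------

    def supports(self, finding: str, dx: str) -> Optional[Polarity]:
        """Polarity of the (finding, diagnosis) relation, or None if unrelated."""
        finding, dx = _clean(finding), _clean(dx)
        if finding not in self.findings:
            raise VocabularyError(f"unknown finding label {finding!r}")
        if dx not in self.diagnoses:
            raise VocabularyError(f"unknown diagnosis label {dx!r}")
        return self.relations.get((finding, dx))

    def is_supporting(self, finding: str, dx: str) -> bool:
        return self.supports(finding, dx) is Polarity.SUPPORT

    def supporting_findings(self, dx: str) -> frozenset[str]:
        """All findings with a support relation to ``dx``."""
        if dx not in self.diagnoses:
            raise VocabularyError(f"unknown diagnosis label {dx!r}")
        return frozenset(
            f for (f, d), pol in self.relations.items()
            if d == dx and pol is Polarity.SUPPORT
        )


@dataclass(frozen=True)
class CaseDefinition:
    """Expert ground truth for a single case."""

    case_id: str
    subdomain: str
    acceptable_dx: frozenset[str]
    true_findings: frozenset[str]

    def __post_init__(self) -> None:
        if not self.acceptable_dx:
            raise KBValidationError(f"case {self.case_id!r}: acceptable_dx must be non-empty")

    def validate_against(self, kb: KnowledgeBase) -> None:
        bad_dx = self.acceptable_dx - kb.diagnoses
        if bad_dx:
            raise KBValidationError(
                f"case {self.case_id!r}: acceptable diagnoses not in vocabulary: {sorted(bad_dx)}"
            )
        bad_f = self.true_findings - kb.findings
        if bad_f:
            raise KBValidationError(
                f"case {self.case_id!r}: true findings not in vocabulary: {sorted(bad_f)}"
            )


def classify_diagnosis(case: CaseDefinition, final_dx: Iterable[str]) -> DxVerdict:
    """Grade a final differential against the case's acceptable set.

    ``incorrect`` if the differential shares no member with the acceptable
    set; ``correct_complete`` if it contains every acceptable diagnosis (extra
    wrong diagnoses alongside a full acceptable set do not demote the
    verdict — correctness is membership-based); otherwise
    ``correct_incomplete`` (equally plausible diagnoses were omitted from the
    differential).
    """
    final = frozenset(_clean(d) for d in final_dx)
    if not final:
        raise ValueError(f"case {case.case_id!r}: no recorded diagnosis (empty final_dx)")
    if not final & case.acceptable_dx:
        return DxVerdict.INCORRECT
    if final >= case.acceptable_dx:
        return DxVerdict.CORRECT_COMPLETE
    return DxVerdict.CORRECT_INCOMPLETE


# -- file loading --------------------------------------------------------


def _read_structured(path: Union[str, Path]) -> dict:
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() in {".yaml", ".yml"}:
        return yaml.safe_load(text)
    return json.loads(text)


def build_kb(
    findings: Iterable[str],
    diagnoses: Iterable[str],
    relations: Iterable[tuple[str, str, str]],
    taught_pairs: Iterable[tuple[str, str]] = (),
) -> KnowledgeBase:
    """Assemble and validate a KnowledgeBase from plain records."""
    rel: dict[tuple[str, str], Polarity] = {}
    for f, d, pol in relations:
        f, d = _clean(f), _clean(d)
        try:
            polarity = Polarity(_clean(pol))
        except ValueError as exc:
            raise KBValidationError(
                f"relation ({f!r}, {d!r}): polarity must be 'support' or 'refute', got {pol!r}"
            ) from exc
        key = (f, d)
        if key in rel and rel[key] is not polarity:
            raise KBValidationError(
                f"conflicting polarity for relation ({f!r}, {d!r})"
            )
        rel[key] = polarity
    return KnowledgeBase(
        findings=frozenset(_clean(f) for f in findings),
        diagnoses=frozenset(_clean(d) for d in diagnoses),
        relations=rel,
        taught_pairs=frozenset((_clean(f), _clean(d)) for f, d in taught_pairs),
    )


def load_kb(path: Union[str, Path]) -> KnowledgeBase:
    """Load a knowledge base from a JSON or YAML file.

    Schema: ``{"findings": [...], "diagnoses": [...],
    "relations": [{"finding":, "diagnosis":, "polarity":}, ...],
    "taught_pairs": [[finding, diagnosis], ...]}``.
    """
    raw = _read_structured(path)
    try:
        relations = [
            (r["finding"], r["diagnosis"], r.get("polarity", "support"))
            for r in raw.get("relations", [])
        ]
        return build_kb(
            findings=raw["findings"],
            diagnoses=raw["diagnoses"],
            relations=relations,
            taught_pairs=[tuple(p) for p in raw.get("taught_pairs", [])],
        )
    except (KeyError, TypeError) as exc:
        raise KBValidationError(f"malformed knowledge-base file {path}: {exc!r}") from exc


def _parse_list_field(value) -> list[str]:
    # CSV cells hold either a JSON list or a ';'-separated string.
    if isinstance(value, (list, tuple)):
        return [str(v) for v in value]
    value = str(value).strip()
    if value.startswith("["):
        return [str(v) for v in json.loads(value)]
    return [v for v in (part.strip() for part in value.split(";")) if v]


def load_cases(
    path: Union[str, Path], kb: Optional[KnowledgeBase] = None
) -> dict[str, CaseDefinition]:
    """Load case definitions from JSON/YAML (list of records) or CSV.

    Columns/keys: ``case_id, subdomain, acceptable_dx, true_findings``. When a
    ``kb`` is given every case is validated against its vocabularies.
    """
    path = Path(path)
    if path.suffix.lower() == ".csv":
        with path.open(newline="") as fh:
            records = list(csv.DictReader(fh))
    else:
        raw = _read_structured(path)
        records = raw["cases"] if isinstance(raw, dict) else raw
    cases: dict[str, CaseDefinition] = {}
    for rec in records:
        try:
            case = CaseDefinition(
                case_id=_clean(rec["case_id"]),
                subdomain=_clean(rec["subdomain"]),
                acceptable_dx=frozenset(_clean(d) for d in _parse_list_field(rec["acceptable_dx"])),
                true_findings=frozenset(_clean(f) for f in _parse_list_field(rec["true_findings"])),
            )
        except KeyError as exc:
            raise KBValidationError(f"case record missing field {exc} in {path}") from exc
        if case.case_id in cases:
            raise KBValidationError(f"duplicate case_id {case.case_id!r} in {path}")
        if kb is not None:
            case.validate_against(kb)
        cases[case.case_id] = case
    return cases


# -- bundled fixtures ----------------------------------------------------


def _data_path(name: str) -> Path:
    return Path(resources.files("dxbias.data") / name)


def toy_kb() -> KnowledgeBase:
    """Small eczematous-dermatitis toy knowledge base (6 findings, 4 diagnoses)."""
    return load_kb(_data_path("toy_kb.json"))


def study_kb() -> KnowledgeBase:
    """Bundled dermatopathology knowledge base spanning both study sub-domains."""
    return load_kb(_data_path("study_kb.json"))


def study_case_library(kb: Optional[KnowledgeBase] = None) -> dict[str, CaseDefinition]:
    """Bundled 40-case library: 20 SVD + 20 NDD cases with designed diagnosis multiplicities."""
    return load_cases(_data_path("study_cases.json"), kb=kb or study_kb())
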