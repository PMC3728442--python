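"""Synthetic clinician cohorts with injectable, ground-truth-labelled biases.

Agents are pattern emitters, not cognitive models: each simulated
participant works through the sequence plan case by case, usually emitting a
diligent default stream (identified findings in canonical order, a
hypothesis, then the final differential), and — with per-bias propensities
theta — occasionally emitting an event pattern constructed to satisfy one
detection rule exactly. Every injected pattern is recorded in the cohort's
truth table, so detector recall and false-positive behaviour can be measured
against known ground truth, which no real participant log provides.

Injection channels are kept mutually exclusive within a case: the
sequence-dependent biases fire only on their opportunity cases, and the four
single-case biases fire only on non-opportunity cases (an incorrect final
diagnosis on a gambler's-fallacy opportunity would otherwise always co-fire
the gambler's rule and muddy the truth labels). ``allow_overlap=True`` lifts
that restriction for stress testing.

Determinism: each participant draws from an independent generator seeded as
``seed + participant index``, so cohorts are reproducible and stable under
profile reordering.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
import yaml

from .case_sequence import SequencePlan, enumerate_opportunities
from .detectors import Label
from .errors import PlanConstructionError
from .knowledge_base import CaseDefinition, KnowledgeBase, Polarity
from .session_log import ActionEvent, CaseRecord, EventKind, Session

#: Injection priority (first match wins within a case).
BIAS_KEYS = (
    "satisficing",
    "availability",
    "gamblers",
    "confirmation",
    "anchor_bias",
    "representativeness_bias",
)

BIAS_TO_LABEL: Mapping[str, Label] = {
    "satisficing": Label.SATISFICING_BIAS,
    "availability": Label.AVAILABILITY_BIAS,
    "gamblers": Label.GAMBLERS_BIAS,
    "confirmation": Label.CONFIRMATION_BIAS,
    "anchor_bias": Label.ANCHOR_BIAS,
    "representativeness_bias": Label.REPR_BIAS,
}

_SINGLE_CASE_KEYS = ("satisficing", "confirmation", "anchor_bias", "representativeness_bias")


@dataclass(frozen=True)
class AgentProfile:
    """Propensity parameters of one simulated participant.

    p_find
        Probability each true finding of a case is identified (default from
        the observed ~65% finding accuracy of the study cohort).
    p_dx
        Probability of a correct final differential absent any injected bias
        (default from the observed ~37% diagnostic accuracy).
    theta
        Per-bias injection probabilities, keyed by :data:`BIAS_KEYS`;
        applied only when the bias's preconditions hold on the case.
    p_sure_given_correct, p_sure_given_incorrect
        Confidence model; the defaults reproduce mild overconfidence (mean
        case bias score around +0.1 at the default accuracies).
    """

    participant_id: str
    level: int = 1
    p_find: float = 0.65
    p_dx: float = 0.37
    theta: Mapping[str, float] = field(default_factory=dict)
    p_sure_given_correct: float = 0.85
    p_sure_given_incorrect: float = 0.50

    def __post_init__(self) -> None:
        probs = [self.p_find, self.p_dx, self.p_sure_given_correct, self.p_sure_given_incorrect]
        probs += list(self.theta.values())
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise ValueError(f"profile {self.participant_id!r}: probabilities must lie in [0, 1]")
        unknown = set(self.theta) - set(BIAS_KEYS)
        if unknown:
            raise ValueError(f"profile {self.participant_id!r}: unknown bias keys {sorted(unknown)}")


#: Level-dependent default satisficing propensities echo the finding that
#: more-trained participants satisficed more often.
_LEVEL_THETA_SATISFICING = {1: 0.14, 2: 0.27, 3: 0.30}


def default_profiles(n_per_level: Mapping[int, int] = {1: 22, 2: 26, 3: 23}) -> list[AgentProfile]:
    """A cohort of profiles mirroring the study's three training levels."""
    profiles = []
    for level in sorted(n_per_level):
        for i in range(n_per_level[level]):
            profiles.append(
                AgentProfile(
                    participant_id=f"L{level}-{i + 1:02d}",
                    level=level,
                    theta={
                        "satisficing": _LEVEL_THETA_SATISFICING[level],
                        "availability": 0.20,
                        "gamblers": 0.08,
                        "confirmation": 0.01,
                        "anchor_bias": 0.06,
                        "representativeness_bias": 0.03,
                    },
                )
            )
    return profiles


def load_profiles(path: Union[str, Path]) -> list[AgentProfile]:
    """Load agent profiles from a YAML/JSON list of mappings."""
    raw = yaml.safe_load(Path(path).read_text())
    return [AgentProfile(**rec) for rec in raw]


@dataclass
class SimulatedCohort:
    """Sessions plus injection ground truth and per-bias eligibility sets."""

    sessions: list[Session]
    truth: dict[tuple[str, str], frozenset[Label]]
    eligible: dict[str, set[tuple[str, str]]]

    def truth_frame(self) -> pd.DataFrame:
        rows = [
            {"participant": pid, "case": cid, "label": label.value}
            for (pid, cid), labels in sorted(self.truth.items())
            for label in sorted(labels, key=lambda l: l.value)
        ]
        return pd.DataFrame(rows, columns=["participant", "case", "label"])

    def injected_count(self, bias: str) -> int:
        label = BIAS_TO_LABEL[bias]
        return sum(label in labels for labels in self.truth.values())


class _CaseStream:
    """Accumulates the events of one case with consecutive seq numbers."""

    def __init__(self) -> None:
        self.events: list[ActionEvent] = []

    def emit(self, kind: EventKind, payload=None) -> None:
        self.events.append(ActionEvent(seq=len(self.events) + 1, kind=kind, payload=payload))


def _identified_findings(
    case: CaseDefinition, profile: AgentProfile, rng: np.random.Generator
) -> list[str]:
    return [f for f in sorted(case.true_findings) if rng.random() < profile.p_find]


def _pick(rng: np.random.Generator, items: Sequence[str]) -> str:
    if not items:
        raise PlanConstructionError("empty choice pool during simulation")
    return items[int(rng.integers(len(items)))]


def _subdomain_dx_pools(
    plan: SequencePlan, cases: Mapping[str, CaseDefinition]
) -> dict[str, list[str]]:
    pools: dict[str, set[str]] = {}
    for sub, seq in plan.sequences.items():
        pools[sub] = set()
        for cid in seq:
            pools[sub] |= cases[cid].acceptable_dx
    return {sub: sorted(dxs) for sub, dxs in pools.items()}


def simulate_cohort(
    profiles: Iterable[AgentProfile],
    plan: SequencePlan,
    cases: Mapping[str, CaseDefinition],
    kb: KnowledgeBase,
    seed: int,
    *,
    allow_overlap: bool = False,
) -> SimulatedCohort:
    """Generate one session per profile over the plan's case order."""
    avail_opps = enumerate_opportunities(plan, cases, "availability")
    gamb_opps = enumerate_opportunities(plan, cases, "gamblers")
    opp_cases = avail_opps | gamb_opps
    dx_pools = _subdomain_dx_pools(plan, cases)

    sessions: list[Session] = []
    truth: dict[tuple[str, str], frozenset[Label]] = {}
    eligible: dict[str, set[tuple[str, str]]] = {b: set() for b in BIAS_KEYS}

    for idx, profile in enumerate(profiles):
        rng = np.random.default_rng((seed + idx) % 2**31)
        pid = profile.participant_id
        answers: dict[str, frozenset[str]] = {}
        records: list[CaseRecord] = []
        for sub, seq in plan.sequences.items():
            for k, cid in enumerate(seq):
                case = cases[cid]
                wrong_pool = [d for d in dx_pools[sub] if d not in case.acceptable_dx]

                elig: dict[str, bool] = {}
                prev_answer: Optional[frozenset[str]] = None
                if cid in avail_opps:
                    elig["availability"] = True
                if cid in gamb_opps:
                    a1, a2 = answers.get(seq[k - 2]), answers.get(seq[k - 1])
                    if a1 and a1 == a2:
                        elig["gamblers"] = True
                        prev_answer = a1
                for b in _SINGLE_CASE_KEYS:
                    if allow_overlap or cid not in opp_cases:
                        elig[b] = True

                injected: Optional[str] = None
                for b in BIAS_KEYS:
                    if not elig.get(b, False):
                        continue
                    eligible[b].add((pid, cid))
                    if injected is None and rng.random() < profile.theta.get(b, 0.0):
                        injected = b

                stream = _CaseStream()
                if injected == "satisficing":
                    final = _emit_satisficing(stream, case, profile, rng, wrong_pool)
                elif injected == "availability":
                    shared = cases[seq[k - 1]].acceptable_dx
                    final = _emit_sequence_bias(stream, case, profile, rng, sorted(shared))
                elif injected == "gamblers":
                    pool = [d for d in wrong_pool if d not in (prev_answer or frozenset())]
                    final = _emit_sequence_bias(stream, case, profile, rng, pool)
                elif injected == "confirmation":
                    final = _emit_confirmation(stream, case, profile, rng, kb, wrong_pool)
                elif injected == "anchor_bias":
                    final = _emit_anchor_bias(
                        stream, case, profile, rng, kb, wrong_pool, dx_pools[sub]
                    )
                elif injected == "representativeness_bias":
                    final = _emit_repr_bias(stream, case, profile, rng, kb, wrong_pool)
                    if final is None:  # no feasible taught pair for this case
                        injected = None
                        final = _emit_default(stream, case, profile, rng, wrong_pool)
                else:
                    final = _emit_default(stream, case, profile, rng, wrong_pool)

                stream.emit(EventKind.CLOSE_CASE)
                _emit_confidence_marks(stream, case, profile, rng)
                answers[cid] = final
                records.append(CaseRecord(case_id=cid, events=tuple(stream.events)))
                if injected is not None:
                    truth[(pid, cid)] = frozenset({BIAS_TO_LABEL[injected]})
        sessions.append(
            Session(participant_id=pid, level=profile.level, case_records=tuple(records))
        )
    return SimulatedCohort(sessions=sessions, truth=truth, eligible=eligible)


# -- stream builders -----------------------------------------------------


def _emit_default(stream, case, profile, rng, wrong_pool) -> frozenset[str]:
    """Findings in canonical order, hypothesis, differential per p_dx."""
    findings = _identified_findings(case, profile, rng)
    for f in findings:
        stream.emit(EventKind.ADD_FINDING, f)
    if rng.random() < profile.p_dx or not wrong_pool:
        dxs = sorted(case.acceptable_dx)
    else:
        dxs = [_pick(rng, wrong_pool)]
    stream.emit(EventKind.ADD_HYPOTHESIS, dxs[0])
    for d in dxs:
        stream.emit(EventKind.ADD_DIAGNOSIS, d)
    return frozenset(dxs)


def _emit_satisficing(stream, case, profile, rng, wrong_pool) -> frozenset[str]:
    """Optional findings, hypothesis, incorrect diagnosis, immediate close."""
    for f in _identified_findings(case, profile, rng):
        stream.emit(EventKind.ADD_FINDING, f)
    w = _pick(rng, wrong_pool)
    stream.emit(EventKind.ADD_HYPOTHESIS, w)
    stream.emit(EventKind.ADD_DIAGNOSIS, w)
    return frozenset({w})


def _emit_sequence_bias(stream, case, profile, rng, dx_pool) -> frozenset[str]:
    """Availability/gambler's stream: wrong diagnosis drawn from ``dx_pool``.

    The re-affirmed hypothesis after the diagnosis keeps the (incorrect,
    immediately closed) stream from additionally matching the satisficing
    rule, so the truth label stays unambiguous.
    """
    for f in _identified_findings(case, profile, rng):
        stream.emit(EventKind.ADD_FINDING, f)
    w = _pick(rng, sorted(dx_pool))
    stream.emit(EventKind.ADD_HYPOTHESIS, w)
    stream.emit(EventKind.ADD_DIAGNOSIS, w)
    stream.emit(EventKind.ADD_HYPOTHESIS, w)
    return frozenset({w})


def _emit_confirmation(stream, case, profile, rng, kb, wrong_pool) -> frozenset[str]:
    """Incorrect diagnosis immediately followed by a finding supporting it."""
    pool = [w for w in wrong_pool if kb.supporting_findings(w)]
    w = _pick(rng, pool)
    f_supp = _pick(rng, sorted(kb.supporting_findings(w)))
    for f in _identified_findings(case, profile, rng):
        if f != f_supp:
            stream.emit(EventKind.ADD_FINDING, f)
    stream.emit(EventKind.ADD_HYPOTHESIS, w)
    stream.emit(EventKind.ADD_DIAGNOSIS, w)
    stream.emit(EventKind.ADD_FINDING, f_supp)
    return frozenset({w})


def _emit_anchor_bias(stream, case, profile, rng, kb, wrong_pool, dx_pool) -> frozenset[str]:
    """Hypothesis first, findings after, then a diagnosis none of them support."""
    findings = _identified_findings(case, profile, rng) or [sorted(case.true_findings)[0]]
    pool = [
        w for w in wrong_pool
        if all(kb.supports(f, w) is not Polarity.SUPPORT for f in findings)
    ]
    if not pool:  # fall back to one finding, which always leaves unsupported diagnoses
        findings = findings[:1]
        pool = [
            w for w in wrong_pool
            if kb.supports(findings[0], w) is not Polarity.SUPPORT
        ]
    w = _pick(rng, pool)
    anchor = _pick(rng, dx_pool)
    stream.emit(EventKind.ADD_HYPOTHESIS, anchor)
    for f in findings:
        stream.emit(EventKind.ADD_FINDING, f)
    stream.emit(EventKind.ADD_DIAGNOSIS, w)
    return frozenset({w})


def _emit_repr_bias(stream, case, profile, rng, kb, wrong_pool) -> Optional[frozenset[str]]:
    """Taught finding->diagnosis pair, diagnosis wrong for the case, emitted
    twice in the case so the pair qualifies session-wide. Returns None when
    no taught pair with a wrong diagnosis exists (caller falls back)."""
    pairs = sorted((f, d) for f, d in kb.taught_pairs if d in wrong_pool)
    if not pairs:
        return None
    f, w = pairs[int(rng.integers(len(pairs)))]
    spacers = sorted(
        g for g in kb.findings if g != f and kb.supports(g, w) is not Polarity.SUPPORT
    )
    g = _pick(rng, spacers)
    for base in _identified_findings(case, profile, rng):
        if base not in (f, g):
            stream.emit(EventKind.ADD_FINDING, base)
    stream.emit(EventKind.ADD_FINDING, f)
    stream.emit(EventKind.ADD_DIAGNOSIS, w)
    stream.emit(EventKind.ADD_FINDING, g)
    stream.emit(EventKind.ADD_FINDING, f)
    stream.emit(EventKind.ADD_DIAGNOSIS, w)
    stream.emit(EventKind.ADD_HYPOTHESIS, w)
    return frozenset({w})


def _emit_confidence_marks(stream, case, profile, rng) -> None:
    """Post-close sure/unsure marks for every live finding and diagnosis."""
    live_findings: set[str] = set()
    live_dx: set[str] = set()
    for e in stream.events:
        if e.kind is EventKind.ADD_FINDING:
            live_findings.add(e.payload)
        elif e.kind is EventKind.ADD_DIAGNOSIS:
            live_dx.add(e.payload)
    for item_kind, labels, truth in (
        ("finding", sorted(live_findings), case.true_findings),
        ("diagnosis", sorted(live_dx), case.acceptable_dx),
    ):
        for label in labels:
            p_sure = (
                profile.p_sure_given_correct
                if label in truth
                else profile.p_sure_given_incorrect
            )
            rating = "sure" if rng.random() < p_sure else "unsure"
            stream.emit(
                EventKind.MARK_CONFIDENCE,
                {"item": item_kind, "label": label, "rating": rating},
            )
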