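"""Case-sequence plans and opportunity enumeration.

Two of the biases are sequence-dependent and can only occur at designed
positions in the case order:

* an **availability** opportunity is the third case of a consecutive triple
  whose first two cases share the same acceptable-diagnosis set while the
  third case's set is disjoint from it (the recently seen diagnosis is
  tempting but wrong);
* a **gambler's-fallacy** opportunity is the third case of a triple in which
  all three cases share the same acceptable set (the same diagnosis "again"
  feels unlikely).

"Same diagnosis" between cases means equal acceptable sets and "different"
means disjoint sets; triples with partial overlap are neither kind of
opportunity. Sub-domain sequences are scanned independently and windows
slide by one, so opportunities may overlap in principle; the default builder
produces non-overlapping blocks for interpretability.
"""

from __future__ import annotations

import json
from collections.abc import Mapping, Sequence
from dataclasses import dataclass
from pathlib import Path
from typing import Union

import numpy as np

from .errors import CaseLookupError, PlanConstructionError
from .knowledge_base import CaseDefinition


@dataclass(frozen=True)
class SequencePlan:
    """Ordered case ids per sub-domain. Opportunity sets are always derived."""

    sequences: Mapping[str, tuple[str, ...]]

    def __post_init__(self) -> None:
        for sub, seq in self.sequences.items():
            if len(set(seq)) != len(seq):
                raise PlanConstructionError(f"sub-domain {sub!r}: repeated case_id in sequence")
        all_ids = [c for seq in self.sequences.values() for c in seq]
        if len(set(all_ids)) != len(all_ids):
            raise PlanConstructionError("a case_id appears in more than one sub-domain sequence")

    def case_ids(self) -> list[str]:
        return [c for sub in self.sequences for c in self.sequences[sub]]

    def position(self, case_id: str) -> tuple[str, int]:
        """(sub-domain, 0-based index) of a case id."""
        for sub, seq in self.sequences.items():
            if case_id in seq:
                return sub, seq.index(case_id)
        raise CaseLookupError(f"case {case_id!r} not in plan")

    def predecessors(self, case_id: str) -> tuple[str, str]:
        """The two cases immediately preceding ``case_id`` in its sequence."""
        sub, k = self.position(case_id)
        if k < 2:
            raise CaseLookupError(f"case {case_id!r} has fewer than two predecessors")
        seq = self.sequences[sub]
        return seq[k - 2], seq[k - 1]


def enumerate_opportunities(
    plan: SequencePlan,
    cases: Mapping[str, CaseDefinition],
    kind: str,
) -> set[str]:
    """Case ids at which ``kind`` ('availability' | 'gamblers') can occur.

    The first two positions of each sub-domain sequence are never flagged;
    sequences shorter than 3 yield no opportunities.
    """
    if kind not in ("availability", "gamblers"):
        raise ValueError(f"kind must be 'availability' or 'gamblers', got {kind!r}")
    flagged: set[str] = set()
    for sub, seq in plan.sequences.items():
        for cid in seq:
            if cid not in cases:
                raise CaseLookupError(f"case {cid!r} in plan but not in case library")
        accs = [cases[cid].acceptable_dx for cid in seq]
        for k in range(2, len(seq)):
            a, b, c = accs[k - 2], accs[k - 1], accs[k]
            if a != b:
                continue
            if kind == "gamblers" and c == a:
                flagged.add(seq[k])
            elif kind == "availability" and not (c & a):
                flagged.add(seq[k])
    return flagged


def _pick(rng: np.random.Generator, items: Sequence):
    return items[int(rng.integers(len(items)))]


def build_default_plan(
    cases: Mapping[str, CaseDefinition],
    seed: int,
    run_lengths: tuple[int, ...] = (5, 4, 2),
    sequence_length: int = 20,
) -> SequencePlan:
    """Build the default two-sequence study plan.

    Per sub-domain the layout is three same-diagnosis runs (default lengths
    5, 4 and 2), each immediately followed by a disjoint-diagnosis trigger
    case, with the remaining cases appended as fillers whose consecutive
    acceptable sets never repeat. Runs of length L contribute L-2
    gambler's-fallacy opportunities; each trigger is one availability
    opportunity. The defaults give 3 availability and 5 gambler's
    opportunities per sub-domain — 6 and 10 over the two 20-case sequences.
    The seed permutes block order, within-run case order and filler order
    without changing the opportunity counts.
    """
    subdomains = sorted({c.subdomain for c in cases.values()})
    expected_avail = len(run_lengths)
    expected_gamb = sum(max(length - 2, 0) for length in run_lengths)
    sequences: dict[str, tuple[str, ...]] = {}
    root = np.random.default_rng(seed)
    for sub in subdomains:
        rng = np.random.default_rng(root.integers(2**31))
        sub_cases = sorted(
            (c for c in cases.values() if c.subdomain == sub), key=lambda c: c.case_id
        )
        if len(sub_cases) < sequence_length:
            raise PlanConstructionError(
                f"sub-domain {sub!r}: {len(sub_cases)} cases available, "
                f"{sequence_length} required"
            )
        groups: dict[frozenset[str], list[str]] = {}
        for c in sub_cases:
            groups.setdefault(c.acceptable_dx, []).append(c.case_id)

        # Assign a distinct diagnosis group to each run, longest runs first.
        run_assignment: dict[int, frozenset[str]] = {}
        used: set[frozenset[str]] = set()
        for i in sorted(range(len(run_lengths)), key=lambda i: -run_lengths[i]):
            candidates = sorted(
                (g for g, ids in groups.items() if g not in used and len(ids) >= run_lengths[i]),
                key=sorted,
            )
            if not candidates:
                raise PlanConstructionError(
                    f"sub-domain {sub!r}: no unused diagnosis with at least "
                    f"{run_lengths[i]} cases for a run of length {run_lengths[i]}"
                )
            run_assignment[i] = _pick(rng, candidates)
            used.add(run_assignment[i])

        remaining = {
            g: list(ids) for g, ids in groups.items() if g not in used
        }
        for i, g in run_assignment.items():
            leftover = groups[g][run_lengths[i]:]
            if leftover:
                remaining.setdefault(g, []).extend(leftover)

        blocks: list[list[str]] = []
        singles = [
            (g, cid) for g, ids in sorted(remaining.items(), key=lambda kv: sorted(kv[0]))
            for cid in ids
        ]
        rng.shuffle(singles)
        taken = [False] * len(singles)
        for i, g in run_assignment.items():
            run_ids = list(groups[g][: run_lengths[i]])
            rng.shuffle(run_ids)
            trigger = None
            for j, (sg, cid) in enumerate(singles):
                if not taken[j] and not (sg & g):
                    trigger, taken[j] = cid, True
                    break
            if trigger is None:
                raise PlanConstructionError(
                    f"sub-domain {sub!r}: no remaining case with a diagnosis set "
                    f"disjoint from {sorted(g)} to trigger an availability opportunity"
                )
            blocks.append(run_ids + [trigger])
        rng.shuffle(blocks)

        fillers = [(g, cid) for j, (g, cid) in enumerate(singles) if not taken[j]]
        # Arrange fillers so no two consecutive share an acceptable set
        # (prevents accidental opportunity pairs). Greedy with backoff.
        filler_ids: list[str] = []
        prev_set = None
        pool = list(fillers)
        while pool:
            idx = next(
                (j for j, (g, _) in enumerate(pool) if g != prev_set), None
            )
            if idx is None:
                raise PlanConstructionError(
                    f"sub-domain {sub!r}: cannot order filler cases without "
                    "creating an unintended same-diagnosis pair"
                )
            g, cid = pool.pop(idx)
            filler_ids.append(cid)
            prev_set = g

        order = [cid for block in blocks for cid in block] + filler_ids
        order = order[:sequence_length]
        sequences[sub] = tuple(order)

    plan = SequencePlan(sequences=sequences)
    n_avail = len(enumerate_opportunities(plan, cases, "availability"))
    n_gamb = len(enumerate_opportunities(plan, cases, "gamblers"))
    if n_avail != expected_avail * len(subdomains) or n_gamb != expected_gamb * len(subdomains):
        raise PlanConstructionError(
            f"constructed plan yields {n_avail} availability / {n_gamb} gambler's "
            f"opportunities; expected {expected_avail * len(subdomains)} / "
            f"{expected_gamb * len(subdomains)} (case library too entangled)"
        )
    return plan


def load_plan(path: Union[str, Path]) -> SequencePlan:
    """Load a plan from JSON ``{"subdomain": [case_id, ...], ...}``."""
    raw = json.loads(Path(path).read_text())
    return SequencePlan(sequences={sub: tuple(ids) for sub, ids in raw.items()})


def save_plan(plan: SequencePlan, path: Union[str, Path]) -> None:
    Path(path).write_text(
        json.dumps({sub: list(ids) for sub, ids in plan.sequences.items()}, indent=2) + "\n"
    )
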