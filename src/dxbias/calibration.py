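"""Feeling-of-knowing calibration: the over/underconfidence bias score.

After closing a case the participant marks each identified item 'sure' or
'unsure'. The case bias score compares those marks to graded performance:

    score = (total_sure - total_correct) / total_items

over the scoreable items of the case — the findings identified (live at
close) and the diagnoses in the final differential, weighted equally.
Hypotheses and relationship links, although markable in the interface, do
not enter the totals. The score lies in [-1, +1]: +1 is complete
overconfidence (sure of everything, all of it wrong), -1 complete
underconfidence, and 0 matched totals. Because the formula is totals-based,
0 does not imply per-item matching: a sure-wrong item can offset an
unsure-right one.

A participant's score is the unweighted mean over their scoreable completed
cases (a case-size-weighted variant is available via ``weighted=True``).
"""

from __future__ import annotations

import warnings
from collections.abc import Iterable, Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import UndefinedScoreError
from .session_log import EvaluatedCase


@dataclass(frozen=True)
class ConfidenceScore:
    case_id: str
    total_sure: int
    total_correct: int
    total_items: int

    @property
    def score(self) -> float:
        return (self.total_sure - self.total_correct) / self.total_items


def _lookup_mark(ec: EvaluatedCase, item_kind: str, label: str) -> str:
    mark = ec.marks.get((item_kind, label))
    if mark is None:
        warnings.warn(
            f"case {ec.case_id!r}: {item_kind} {label!r} carries no confidence "
            "mark; treated as 'unsure'",
            stacklevel=3,
        )
        mark = "unsure"
    return mark


def case_bias_score(ec: EvaluatedCase, *, warn_unmarked: bool = True) -> ConfidenceScore:
    """Compute the confidence bias score for one completed case.

    Raises UndefinedScoreError when the case was not completed or has no
    scoreable items. Unmarked items count as 'unsure' (with a warning unless
    ``warn_unmarked=False``).
    """
    if not ec.completed:
        raise UndefinedScoreError(f"case {ec.case_id!r}: not completed, score undefined")
    items = [("finding", f) for f in sorted(ec.live_findings)]
    items += [("diagnosis", d) for d in sorted(ec.final_dx)]
    if not items:
        raise UndefinedScoreError(f"case {ec.case_id!r}: no scoreable items")
    total_sure = 0
    total_correct = 0
    for item_kind, label in items:
        if warn_unmarked:
            mark = _lookup_mark(ec, item_kind, label)
        else:
            mark = ec.marks.get((item_kind, label), "unsure")
        if mark == "sure":
            total_sure += 1
        truth = ec.case.true_findings if item_kind == "finding" else ec.case.acceptable_dx
        if label in truth:
            total_correct += 1
    return ConfidenceScore(
        case_id=ec.case_id,
        total_sure=total_sure,
        total_correct=total_correct,
        total_items=len(items),
    )


def participant_bias_score(
    evaluated: Iterable[EvaluatedCase], *, weighted: bool = False, warn_unmarked: bool = True
) -> float:
    """Mean bias score across a participant's scoreable completed cases."""
    scores: list[ConfidenceScore] = []
    for ec in evaluated:
        if not ec.completed:
            continue
        try:
            scores.append(case_bias_score(ec, warn_unmarked=warn_unmarked))
        except UndefinedScoreError:
            continue
    if not scores:
        raise UndefinedScoreError("no scoreable completed cases")
    if weighted:
        total = sum(s.total_items for s in scores)
        return sum(s.total_sure - s.total_correct for s in scores) / total
    return float(np.mean([s.score for s in scores]))


def score_distribution(scores: Sequence[float], width: float = 0.1) -> pd.Series:
    """Bin participant bias scores at fixed intervals centred on multiples of ``width``.

    Returns counts indexed by interval centre, spanning [-1, 1]; the
    convention mirrors histogram summaries of calibration scores.
    """
    centres = np.round(np.arange(-1.0, 1.0 + width / 2, width), 10)
    edges = np.concatenate([centres - width / 2, [centres[-1] + width / 2]])
    counts, _ = np.histogram(np.asarray(scores, dtype=float), bins=edges)
    return pd.Series(counts, index=pd.Index(centres, name="score_interval_centre"), name="n")
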