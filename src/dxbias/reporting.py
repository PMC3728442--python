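"""Aggregate detections into frequency tables and association summaries.

Frequencies follow the "% of possible cases" convention: for each
participant and label the denominator is the number of completed cases in
which that label could occur — every completed case for the single-case
labels, and only completed opportunity cases whose two predecessors were
also completed for availability and gambler's fallacy. Denominators
therefore differ across participants.

Distributions of these frequencies are not normal, so group summaries use
the median with a dispersion computed as the root-mean-square deviation
about the median, and group comparisons use Kruskal-Wallis with pairwise
Mann-Whitney U follow-ups (two-sided, unadjusted).
"""

from __future__ import annotations

import math
from collections.abc import Iterable, Mapping
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .case_sequence import SequencePlan, enumerate_opportunities
from .detectors import BIAS_LABELS, HEURISTIC_LABELS, SEQUENCE_LABELS, DetectionReport, Label
from .knowledge_base import CaseDefinition, DxVerdict
from .session_log import EvaluatedCase


def _completed_ids(evaluated: Iterable[EvaluatedCase]) -> set[str]:
    return {ec.case_id for ec in evaluated if ec.completed}


def _denominator(
    label: Label,
    completed: set[str],
    plan: SequencePlan,
    cases: Mapping[str, CaseDefinition],
) -> int:
    if label not in SEQUENCE_LABELS:
        return len(completed)
    kind = "availability" if label is Label.AVAILABILITY_BIAS else "gamblers"
    n = 0
    for cid in enumerate_opportunities(plan, cases, kind):
        if cid in completed and all(p in completed for p in plan.predecessors(cid)):
            n += 1
    return n


def frequency_table(
    report: DetectionReport,
    evaluated_by_participant: Mapping[str, list[EvaluatedCase]],
    plan: SequencePlan,
    cases: Mapping[str, CaseDefinition],
) -> pd.DataFrame:
    """Per participant x label counts, denominators and percentages.

    Columns: participant, label, n_cases, n_possible, percent (one decimal
    place; NaN when the denominator is zero).
    """
    rows = []
    for pid in sorted(evaluated_by_participant):
        completed = _completed_ids(evaluated_by_participant[pid])
        for label in Label:
            n_possible = _denominator(label, completed, plan, cases)
            n_cases = sum(
                1
                for (p, cid), labels in report.labels.items()
                if p == pid and label in labels
            )
            percent = round(100.0 * n_cases / n_possible, 1) if n_possible else np.nan
            rows.append(
                {
                    "participant": pid,
                    "label": label.value,
                    "n_cases": n_cases,
                    "n_possible": n_possible,
                    "percent": percent,
                }
            )
    return pd.DataFrame(rows, columns=["participant", "label", "n_cases", "n_possible", "percent"])


def sd_from_median(values: Iterable[float]) -> float:
    """Root-mean-square deviation about the median (dispersion for
    non-normal measures)."""
    arr = np.asarray([v for v in values if not (isinstance(v, float) and math.isnan(v))], float)
    if arr.size == 0:
        return float("nan")
    return float(np.sqrt(np.mean((arr - np.median(arr)) ** 2)))


def level_summary(
    freqs: pd.DataFrame, levels: Mapping[str, int], value: str = "percent"
) -> pd.DataFrame:
    """Median and SD-from-median of a frequency column, overall and by level."""
    df = freqs.copy()
    df["level"] = df["participant"].map(levels)
    rows = []
    for label, sub in df.groupby("label", sort=True):
        groups = [("all", sub)] + [
            (f"level {lv}", g) for lv, g in sub.groupby("level", sort=True)
        ]
        for name, g in groups:
            vals = g[value].dropna()
            rows.append(
                {
                    "label": label,
                    "group": name,
                    "n": len(vals),
                    "median": float(vals.median()) if len(vals) else float("nan"),
                    "sd_from_median": sd_from_median(vals),
                }
            )
    return pd.DataFrame(rows, columns=["label", "group", "n", "median", "sd_from_median"])


def error_bias_association(
    report: DetectionReport,
    evaluated_by_participant: Mapping[str, list[EvaluatedCase]],
    plan: Optional[SequencePlan] = None,
    cases: Optional[Mapping[str, CaseDefinition]] = None,
    *,
    opportunity_denominator: str = "error_opportunities",
) -> dict:
    """Error-bias and correct-heuristic association summary.

    Among completed cases with an incorrect final diagnosis: the percentage
    carrying at least one bias label, plus per-bias percentages normalized
    for opportunity (for the sequence biases the denominator is either the
    error cases that were opportunity cases, the default, or all opportunity
    cases with ``opportunity_denominator='all_opportunities'``). Among
    correctly diagnosed completed cases: the percentage carrying at least
    one heuristic label.
    """
    if opportunity_denominator not in ("error_opportunities", "all_opportunities"):
        raise ValueError(f"unknown opportunity_denominator {opportunity_denominator!r}")
    opp_ids: dict[Label, set[str]] = {}
    if plan is not None and cases is not None:
        opp_ids[Label.AVAILABILITY_BIAS] = enumerate_opportunities(plan, cases, "availability")
        opp_ids[Label.GAMBLERS_BIAS] = enumerate_opportunities(plan, cases, "gamblers")

    error_keys: list[tuple[str, str]] = []
    correct_keys: list[tuple[str, str]] = []
    for pid, evaluated in evaluated_by_participant.items():
        for ec in evaluated:
            if not ec.completed or ec.dx_verdict is None:
                continue
            key = (pid, ec.case_id)
            if ec.dx_verdict is DxVerdict.INCORRECT:
                error_keys.append(key)
            else:
                correct_keys.append(key)

    def pct(num: int, den: int) -> float:
        return round(100.0 * num / den, 1) if den else float("nan")

    n_error_with_bias = sum(
        1 for key in error_keys if report.labels_for(*key) & BIAS_LABELS
    )
    n_correct_with_heuristic = sum(
        1 for key in correct_keys if report.labels_for(*key) & HEURISTIC_LABELS
    )
    per_label = {}
    for label in sorted(BIAS_LABELS, key=lambda l: l.value):
        if label in opp_ids:
            if opportunity_denominator == "error_opportunities":
                denom_keys = [k for k in error_keys if k[1] in opp_ids[label]]
            else:
                denom_keys = [
                    (pid, cid)
                    for pid in evaluated_by_participant
                    for cid in opp_ids[label]
                ]
        else:
            denom_keys = error_keys
        n_flagged = sum(1 for k in denom_keys if label in report.labels_for(*k))
        per_label[label.value] = pct(n_flagged, len(denom_keys))

    return {
        "n_error_cases": len(error_keys),
        "n_correct_cases": len(correct_keys),
        "pct_error_with_bias": pct(n_error_with_bias, len(error_keys)),
        "pct_correct_with_heuristic": pct(n_correct_with_heuristic, len(correct_keys)),
        "per_bias_pct_of_error_cases": per_label,
    }


def _mannwhitney_z(x: np.ndarray, y: np.ndarray, u: float) -> float:
    """Normal-approximation z for the Mann-Whitney U statistic, tie-corrected."""
    n1, n2 = len(x), len(y)
    n = n1 + n2
    pooled = np.concatenate([x, y])
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = (counts**3 - counts).sum() / (n * (n - 1)) if n > 1 else 0.0
    sigma2 = n1 * n2 / 12.0 * (n + 1 - tie_term)
    if sigma2 <= 0:
        return 0.0
    return (u - n1 * n2 / 2.0) / math.sqrt(sigma2)


def compare_groups(
    freqs: pd.DataFrame, levels: Mapping[str, int], value: str = "percent"
) -> pd.DataFrame:
    """Kruskal-Wallis across training levels plus pairwise Mann-Whitney U.

    One row per label for the omnibus test (test='kruskal': H, p) and one
    per level pair (test='mannwhitney': U, z, p, effect size r = |z|/sqrt(n)).
    Alpha 0.05 is the reporting convention; nothing is enforced and no
    multiplicity adjustment is applied.
    """
    df = freqs.copy()
    df["level"] = df["participant"].map(levels)
    if df["level"].nunique() < 2:
        raise ValueError("compare_groups requires at least two training levels")
    rows = []
    for label, sub in df.groupby("label", sort=True):
        samples = {
            lv: g[value].dropna().to_numpy(float) for lv, g in sub.groupby("level", sort=True)
        }
        samples = {lv: arr for lv, arr in samples.items() if arr.size > 0}
        if len(samples) < 2:
            continue
        groups = [samples[lv] for lv in sorted(samples)]
        if np.ptp(np.concatenate(groups)) == 0:
            h_stat, h_p = 0.0, 1.0  # kruskal is undefined when every value ties
        else:
            h_stat, h_p = stats.kruskal(*groups)
        rows.append(
            {
                "label": label, "test": "kruskal", "groups": "all",
                "statistic": float(h_stat), "z": float("nan"),
                "p": float(h_p), "effect_size": float("nan"),
            }
        )
        lvls = sorted(samples)
        for i in range(len(lvls)):
            for j in range(i + 1, len(lvls)):
                x, y = samples[lvls[i]], samples[lvls[j]]
                u_res = stats.mannwhitneyu(x, y, alternative="two-sided")
                z = _mannwhitney_z(x, y, float(u_res.statistic))
                r = abs(z) / math.sqrt(len(x) + len(y))
                rows.append(
                    {
                        "label": label, "test": "mannwhitney",
                        "groups": f"{lvls[i]} vs {lvls[j]}",
                        "statistic": float(u_res.statistic), "z": z,
                        "p": float(u_res.pvalue), "effect_size": r,
                    }
                )
    return pd.DataFrame(
        rows, columns=["label", "test", "groups", "statistic", "z", "p", "effect_size"]
    )
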