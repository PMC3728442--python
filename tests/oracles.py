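"""Naive brute-force re-implementations of every detection rule.

Deliberately independent of the package's detector code paths: each oracle
enumerates all qualifying index combinations directly from the raw event
streams and recomputes correctness and final differentials from first
principles. Used to cross-check the detectors on hand examples and large
randomized session sets.
"""

from dxbias.detectors import Label
from dxbias.knowledge_base import Polarity
from dxbias.session_log import EventKind

F, H, D = EventKind.ADD_FINDING, EventKind.ADD_HYPOTHESIS, EventKind.ADD_DIAGNOSIS
ADD = (F, H, D, EventKind.ADD_LINK)


def _pre_close(record):
    out = []
    for e in record.events:
        if e.kind is EventKind.CLOSE_CASE:
            break
        out.append(e)
    return out


def _is_completed(record):
    return any(e.kind is EventKind.CLOSE_CASE for e in record.events)


def _supports(kb, finding, dx):
    return kb.relations.get((finding, dx)) is Polarity.SUPPORT


def replay_final_dx(record):
    """Forward replay of add/delete events; diagnoses live at close."""
    live = set()
    for e in record.events:
        if e.kind is D:
            live.add(str(e.payload).strip())
        elif e.kind is EventKind.DELETE_ITEM:
            item = e.payload.get("item") if isinstance(e.payload, dict) else None
            if item in (None, "diagnosis"):
                live.discard(str(e.payload.get("label")).strip())
        elif e.kind is EventKind.CLOSE_CASE:
            return frozenset(live)
    return frozenset()


def verdict_of(case, final):
    if not final:
        return None
    if not (final & case.acceptable_dx):
        return "incorrect"
    if final >= case.acceptable_dx:
        return "correct_complete"
    return "correct_incomplete"


def brute_anchoring(record, kb):
    """Label set from exhaustive (hypothesis, diagnosis) episode enumeration."""
    if not _is_completed(record):
        return set()
    evs = [e for e in _pre_close(record) if e.kind in (F, H, D)]
    labels = set()
    for h in evs:
        if h.kind is not H:
            continue
        post_findings = [e for e in evs if e.kind is F and e.seq > h.seq]
        if not post_findings:
            continue
        flabels = sorted({e.label for e in post_findings})
        for d in evs:
            if d.kind is not D:
                continue
            if not any(h.seq < f.seq < d.seq for f in (e for e in post_findings)):
                continue
            if all(_supports(kb, f, d.label) for f in flabels):
                labels.add(Label.ANCHOR_HEURISTIC)
            else:
                adjusted = any(
                    e.kind in (H, D)
                    and e.seq > d.seq
                    and all(_supports(kb, f, e.label) for f in flabels)
                    for e in evs
                )
                if not adjusted:
                    labels.add(Label.ANCHOR_BIAS)
    return labels


def brute_confirmation(record, case, kb, window="next"):
    if not _is_completed(record):
        return False
    adds = [e for e in _pre_close(record) if e.kind in ADD]
    for i, d in enumerate(adds):
        if d.kind is not D or str(d.payload).strip() in case.acceptable_dx:
            continue
        candidates = adds[i + 1 : i + 2] if window == "next" else adds[i + 1 :]
        for f in candidates:
            if f.kind is F and _supports(kb, f.label, str(d.payload).strip()):
                return True
    return False


def brute_satisficing(record, case):
    if not _is_completed(record):
        return False
    if verdict_of(case, replay_final_dx(record)) not in ("incorrect", "correct_incomplete"):
        return False
    adds = [e for e in _pre_close(record) if e.kind in ADD]
    hyp_seqs = [e.seq for e in adds if e.kind is H]
    if not hyp_seqs:
        return False
    if any(e.kind is F and e.seq > min(hyp_seqs) for e in adds):
        return False
    pairs = [
        (h, d)
        for h in adds
        for d in adds
        if h.kind is H
        and d.kind is D
        and h.seq < d.seq
        and not any(e.kind is F and h.seq < e.seq < d.seq for e in adds)
    ]
    if not pairs:
        return False
    return adds[-1].kind is D


def brute_representativeness(records_with_cases, kb):
    """{case_id: label set} over a whole session.

    ``records_with_cases``: iterable of (CaseRecord, CaseDefinition).
    """
    occurrences = {}
    for record, case in records_with_cases:
        if not _is_completed(record):
            continue
        adds = [e for e in _pre_close(record) if e.kind in ADD]
        for a, b in zip(adds, adds[1:]):
            if a.kind is F and b.kind is D:
                pair = (a.label, b.label)
                if pair in kb.taught_pairs:
                    correct = b.label in case.acceptable_dx
                    occurrences.setdefault(pair, []).append((record.case_id, correct))
    out = {}
    for pair, occs in occurrences.items():
        if len(occs) <= 1:
            continue
        for case_id, correct in occs:
            out.setdefault(case_id, set()).add(
                Label.REPR_HEURISTIC if correct else Label.REPR_BIAS
            )
    return out


def brute_sequence_biases(session, plan, cases):
    """{case_id: label set} for availability and gambler's fallacy.

    Scans every consecutive triple of each sub-domain sequence directly.
    """
    by_case = {rec.case_id: rec for rec in session.case_records}
    out = {}
    for sub, seq in plan.sequences.items():
        for k in range(2, len(seq)):
            trio = [seq[k - 2], seq[k - 1], seq[k]]
            recs = [by_case.get(cid) for cid in trio]
            if any(r is None or not _is_completed(r) for r in recs):
                continue
            accs = [cases[cid].acceptable_dx for cid in trio]
            finals = [replay_final_dx(r) for r in recs]
            target_verdict = verdict_of(cases[trio[2]], finals[2])
            if accs[0] == accs[1] and not (accs[2] & accs[0]):
                if target_verdict == "incorrect" and finals[2] & accs[1]:
                    out.setdefault(trio[2], set()).add(Label.AVAILABILITY_BIAS)
            if accs[0] == accs[1] == accs[2]:
                if (
                    finals[0]
                    and finals[0] == finals[1]
                    and finals[2] != finals[0]
                    and target_verdict == "incorrect"
                ):
                    out.setdefault(trio[2], set()).add(Label.GAMBLERS_BIAS)
    return out
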