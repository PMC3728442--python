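# dxbias

Rule-based detection of cognitive heuristics and biases in
diagnostic-reasoning event logs.

When clinicians diagnose cases in a computer-based system that records every
reasoning step — identifying findings, proposing hypotheses, committing a
final diagnosis, marking confidence — those event streams can be searched
automatically for the signatures of well-known cognitive shortcuts:
anchoring, availability, confirmation bias, gambler's fallacy,
representativeness, search satisficing, and over/underconfidence. A shortcut
that ends in a correct diagnosis is a *heuristic*; the same pattern ending
in an incorrect one is a *bias*. `dxbias` implements these eight detection
rules as deterministic classifiers for researchers in medical education and
diagnostic-safety informatics, together with everything needed to run and
validate them end to end:

* a **knowledge base / case truth** layer (findings, diagnoses,
  support/refute relations, taught finding-diagnosis pairs, acceptable
  diagnosis sets) that grades every logged action;
* a **case-sequence designer** that embeds availability and
  gambler's-fallacy opportunity sub-sequences (two 20-case sub-domain
  sequences with 6 and 10 opportunity cases by default) and enumerates
  opportunities in any plan;
* the **eight detectors**, emitting per-case labels with the triggering
  event indices as evidence;
* a **confidence calibration** score per case,
  `(total_sure − total_correct) / total_items` over the identified findings
  and diagnoses, ranging from +1 (completely overconfident) through 0
  (matched) to −1 (completely underconfident);
* a **synthetic clinician simulator** whose agents inject bias patterns
  with known propensities, giving labelled ground truth no real log can
  provide;
* **reporting**: per-participant "% of possible cases" frequency tables
  with opportunity-aware denominators, error-bias association summaries,
  and nonparametric group comparisons (Kruskal-Wallis, Mann-Whitney U).

See `docs/methods.md` for the precise rule definitions and design choices.

## Worked example: validating a detector against injected ground truth

Simulate 20 diagnostically accurate agents who commit the availability bias
on 30% of their opportunity cases, then measure what the detector recovers:

```python
from dxbias import (
    study_kb, study_case_library, build_default_plan, AgentProfile,
    simulate_cohort, detect_all, Label,
)

kb = study_kb()
cases = study_case_library(kb)
plan = build_default_plan(cases, seed=0)   # 6 availability + 10 gambler's opportunities

profiles = [
    AgentProfile(participant_id=f"a{i:02d}", level=1, p_find=0.8, p_dx=1.0,
                 theta={"availability": 0.3})
    for i in range(20)
]
cohort = simulate_cohort(profiles, plan, cases, kb, seed=11)
report = detect_all(cohort.sessions, kb, plan, cases)

flagged = {k for k, labs in report.labels.items() if Label.AVAILABILITY_BIAS in labs}
injected = set(cohort.truth)
eligible = cohort.eligible["availability"]
print(f"eligible opportunity cases : {len(eligible)}")
print(f"injected bias patterns     : {len(injected)}")
print(f"detector-flagged cases     : {len(flagged)}")
print(f"recall on injections       : {len(flagged & injected) / len(injected):.2f}")
print(f"estimated propensity       : {len(flagged) / len(eligible):.3f}  (true 0.3)")
```

Output:

```
eligible opportunity cases : 120
injected bias patterns     : 36
detector-flagged cases     : 36
recall on injections       : 1.00
estimated propensity       : 0.300  (true 0.3)
```

Each of the 20 agents faces 6 designed availability opportunities (a case
whose two predecessors shared a different diagnosis); 36 of the 120 drew an
injection, the detector recovered all 36 with no false positives, and the
estimated propensity equals the injected rate. The same harness validates
every detector channel.

The same pipeline is available from the shell:

```sh
dxbias plan --seed 0 --out plan.json
dxbias simulate --plan plan.json --seed 11 --out log.jsonl --truth truth.csv
dxbias detect --plan plan.json --log log.jsonl --out detections.csv
dxbias report --plan plan.json --log log.jsonl --out summary.csv --by-level
```

## Layout

```
src/dxbias/
  knowledge_base.py   vocabularies, relations, case truth, verdict grading
  session_log.py      event model, JSONL/CSV parsing, session evaluation
  case_sequence.py    sequence plans, opportunity enumeration, default design
  detectors.py        the eight rules and whole-cohort detection reports
  calibration.py      confidence bias score and distributions
  simulator.py        synthetic cohorts with injectable bias patterns
  reporting.py        frequency tables, associations, group comparisons
  cli.py              `dxbias` command-line interface
  data/               bundled synthetic knowledge base and 40-case library
tests/                pytest suite incl. brute-force oracle cross-checks
```
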