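# Methods

## Setting and unit of analysis

`dxbias` re-creates, as a self-contained library, the off-line analysis
pipeline of a virtual-slide diagnostic training system in which participants
articulate their reasoning through discrete interface actions: identifying
histopathologic findings, proposing diagnostic hypotheses, drawing
supporting/refuting links, committing a final diagnosis (single disease or a
differential), closing the case, and then marking each identified item
'sure' or 'unsure'. Eight deterministic production rules label each
completed case with the cognitive shortcuts it exhibits. A shortcut that led
to a correct diagnosis is a *heuristic*; the same pattern ending in an
incorrect diagnosis is a *bias*. A case is labelled at most once per label
no matter how many episodes matched, and one case may carry several labels.

Correctness is graded against expert case truth: a finding is correct when
it is among the case's annotated findings; a hypothesis or diagnosis is
correct when it belongs to the case's *acceptable set* (one or more diseases
matching the histopathologic pattern, any of which counts). A final
differential is `incorrect` when it shares no member with the acceptable
set, `correct_complete` when it contains the whole set, and
`correct_incomplete` otherwise. Completeness is superset containment: extra
wrong diagnoses alongside a full acceptable set do not demote the verdict,
because correctness is membership-based. Labels are case-sensitive exact
strings after whitespace trimming; the original interface forced a
controlled vocabulary, so no fuzzy matching is attempted.

## Detection rules

All sequential rules operate on the *add-type* events of a case
(ADD_FINDING, ADD_HYPOTHESIS, ADD_DIAGNOSIS, ADD_LINK) in seq order.
Deletions and confidence marks are transparent: rules fire on actions as
performed, so an anchored hypothesis later deleted still anchored. Events
after CLOSE_CASE (confidence marks only) are invisible to the rules. Cases
never closed contribute to no rule and no denominator.

**Anchoring** (single case, heuristic or bias). An episode is a hypothesis
followed by at least one finding and then a diagnosis. The episode's finding
set is every finding added after the anchoring hypothesis — the remainder of
the case, one window used consistently both to judge the episode diagnosis
and the adjustment clause (the between-hypothesis-and-diagnosis reading was
the design alternative; the remainder window was chosen so that "consistent
with all new findings" means the same finding set everywhere in the rule).
The episode is the heuristic when the diagnosis is supported (a knowledge-
base support edge) by every episode finding, whether it equals the
hypothesis (sufficient non-adjustment) or not (sufficient adjustment). It is
the bias when the diagnosis is not so supported and no subsequent hypothesis
or diagnosis in the case is supported by all episode findings (insufficient
adjustment). Every hypothesis-episode is evaluated and the case carries the
union, so distinct episodes can make a case both heuristic and bias.

**Confirmation bias** (single case). An incorrect diagnosis immediately
followed — next add-type action — by a finding that supports it. The
immediate reading is the default because it is the stricter of the two
natural readings; `window="any_later"` accepts any later finding in the case
as a sensitivity variant.

**Search satisficing** (single case). On a completed case: (a) any findings
precede the first hypothesis, (b) a hypothesis is followed by a diagnosis
with no finding between them, (c) the final differential is incorrect or
correct-but-incomplete, and (d) no add-type action separates the final
diagnosis from CLOSE_CASE (premature closure).

**Representativeness, Type 2** (whole session, heuristic or bias). An
occurrence is a finding immediately followed by a diagnosis where that
finding-diagnosis pair was explicitly taught in the study material
(`taught_pairs` in the knowledge base, necessarily a subset of the support
relations). Occurrences are pooled across the participant's whole session —
both sub-domains — and a pair qualifies only when it occurs more than once
(a rigidly applied learned model, not a one-off). Each qualifying occurrence
labels its own case: heuristic when that diagnosis is correct there, bias
when incorrect.

**Availability bias** (case sequence). Opportunity positions are designed
into the sequence: the third case of a consecutive triple whose first two
cases share an acceptable set while the third's is disjoint from it. Because
a case-summary screen reveals the correct diagnosis after every case, the
participant is exposed to the predecessors' diagnosis regardless of their
own answers, so only case truth matters on the predecessors. The opportunity
case is flagged when the participant's final differential is incorrect and
contains a member of the predecessors' shared set. Both predecessors must
have been completed by that participant (exposure requirement).

**Gambler's fallacy** (case sequence). Opportunities are the third case of
a triple in which all three acceptable sets are equal. Here the
participant's own answers matter: the case is flagged when their final
differentials on the two predecessors were equal as sets (correct or not),
and on the opportunity case the differential deviates from that set and is
incorrect.

**Over/underconfidence** (calibration). Per completed case,

    score = (total_sure − total_correct) / total_items

over the scoreable items — the findings live at close and the diagnoses of
the final differential, weighted equally. Hypotheses and links, although
markable in the interface, are excluded: the metric is defined over findings
and diagnoses. Unmarked items count as 'unsure' with a warning. The score
lies in [−1, +1]; +1 is complete overconfidence, −1 complete
underconfidence, 0 matched totals (which, being totals-based, does not imply
per-item matching). A participant's score is the unweighted mean over their
scoreable completed cases; a case-size-weighted variant exists behind a
flag. `score_distribution` bins participant means at 0.1-wide intervals
centred on multiples of 0.1.

Edge conventions: "same diagnosis" between cases means equal acceptable
sets and "different" means disjoint sets — partial overlap makes a triple
neither kind of opportunity. A completed case whose every diagnosis was
deleted before close has an empty differential; its verdict is undefined and
it is excluded from verdict-dependent rules and denominators rather than
failing the whole session. Refuting links are stored for log fidelity but no
detection rule consumes them.

## Sequence design

`build_default_plan` lays out, per sub-domain, three same-diagnosis runs
(default lengths 5, 4 and 2), each immediately followed by a
disjoint-diagnosis trigger case, then fillers whose consecutive acceptable
sets never repeat. A run of length L yields L−2 gambler's opportunities
(windows slide by one); each trigger is one availability opportunity. The
defaults give 3 availability + 5 gambler's opportunities per 20-case
sub-domain sequence — 6 and 10 across the two sequences, split evenly
because the source design states only the totals. The seed permutes block
order, within-run order and filler order without changing opportunity
counts; an infeasible library raises an error naming the missing diagnosis
multiplicity. Availability and gambler's opportunity sets are disjoint by
construction of the definitions (a triple cannot have its third set both
equal and disjoint to the first two). Opportunity sets are always recomputed
from a plan, never trusted from file.

The bundled 40-case dermatopathology library (synthetic, as is the bundled
knowledge base) provides per sub-domain one diagnosis with five cases, one
with four, one with two, and nine singletons — the minimal multiplicities
for this layout.

## Synthetic cohorts

The simulator exists to validate the detectors, which real logs cannot do:
it produces sessions with known injected bias patterns. Agents are pattern
emitters, not cognitive models.

Parameters (all probabilities): `p_find = 0.65` — chance each true finding
is identified, matching the ~65% finding accuracy observed in cohorts doing
this task; `p_dx = 0.37` — chance of a correct differential absent
injection, matching ~37% diagnostic accuracy; per-bias propensities `theta`
(defaults: availability 0.20; satisficing 0.14/0.27/0.30 for training
levels 1/2/3, echoing the observed increase with training; gambler's 0.08;
anchoring bias 0.06; representativeness bias 0.03; confirmation 0.01 —
chosen once from the typical per-participant medians of this task family);
and a confidence model `p_sure_given_correct = 0.85`,
`p_sure_given_incorrect = 0.50`, which at the default accuracies yields a
mean case bias score near +0.1 (mild overconfidence).

The default (non-injected) stream is findings in canonical order, a
hypothesis, then the differential (full acceptable set when correct, a
wrong singleton otherwise), close, confidence marks. Injected streams are
constructed to satisfy exactly one rule: the satisficing stream closes
immediately on a wrong diagnosis; the confirmation stream appends a
supporting finding right after the wrong diagnosis; the anchoring-bias
stream opens with a hypothesis and diagnoses a disease unsupported by any
emitted finding; the representativeness stream emits a taught pair twice
(with a non-supporting spacer finding so the confirmation rule cannot
co-fire); availability/gambler's streams give the designed wrong answer on
an opportunity case and re-affirm the hypothesis before closing so the
satisficing rule cannot co-fire.

Two deliberate couplings remain and are properties of the rules, not
detector errors. First, a default stream that happens to end in a wrong
diagnosis *is* premature closure by rule (a)-(d), so realistic cohorts with
`p_dx` well below 1 show substantial satisficing beyond the injected rate,
and nearly every error case carries at least one bias. Per-bias validation
therefore uses `p_dx = 1` single-bias cohorts, where injections are the only
bias patterns in the data: recall on injections is 1, channel false
positives are 0, and the detector-estimated rate recovers theta within
binomial sampling error (checked for theta in {0.1, 0.3, 0.5} with at least
150 eligible cases per configuration). Second, injections are mutually
exclusive within a case, and the four single-case channels fire only on
non-opportunity cases: any incorrect differential on a gambler's opportunity
(after equal predecessor answers) necessarily also fires the gambler's rule,
so unrestricted placement would make truth labels ambiguous.
`allow_overlap=True` lifts the restriction for stress testing.

Reproducibility: participant i draws from `default_rng(seed + i)`, so
cohorts are byte-identical under the same seed and stable under profile
reordering. Gambler's eligibility is dynamic (it depends on the agent's own
preceding answers); the cohort records realized eligibility per bias so
rates use the right denominators.

What the simulator does not emulate: visual search, timing, learning within
the session, deletions, partial differentials, or any dependence of errors
on case difficulty. Passing validation therefore shows the detectors
implement the rules exactly; it does not show the rules capture real
cognition.

## Reporting

Frequencies use the "% of possible cases" convention: per participant and
label, the denominator is the completed cases in which the label could occur
— all completed cases for the single-case labels; for availability and
gambler's fallacy, completed opportunity cases whose two predecessors were
also completed. Percentages are reported to one decimal; a zero denominator
yields a missing value. Group summaries use the median and, since the usual
"standard deviation from the median" is not precisely defined anywhere we
could follow, the root-mean-square deviation about the median. Group
comparisons use Kruskal-Wallis across the three training levels and
two-sided pairwise Mann-Whitney U with a tie-corrected normal-approximation
z and effect size r = |z|/sqrt(n); alpha = 0.05 is the reporting convention,
nothing is enforced, and no multiplicity adjustment is applied (matching the
source analyses). When every observation ties, H is reported as 0 with p = 1
rather than erroring.

The error-bias association reports, among completed incorrect-diagnosis
cases, the fraction carrying at least one bias label, and among correctly
diagnosed cases the fraction carrying at least one heuristic label
(anchoring and representativeness heuristics — the only heuristic-side
labels the rules define). Per-bias breakdowns are normalized for
opportunity: for the sequence biases the denominator is the error cases
that were opportunity cases (the alternative all-opportunities denominator
is available by flag, since the convention is ambiguous).

## Numerical and interface choices

Event ordering is by `seq` alone; timestamps are informational. Sessions
parse from JSONL (one event per line) or an equivalent CSV dialect;
malformed lines are rejected with their line number, duplicate
(participant, case, seq) keys and double closes are integrity errors, and a
completed case must contain at least one hypothesis and one diagnosis
before close (the interface's only required actions). Knowledge bases load
from JSON or YAML with full invariant validation (no dangling relation
endpoints, no conflicting polarities, taught pairs must be supported
relations). The CLI (`dxbias plan | simulate | detect | report`) is a thin
wrapper over these functions.

Problem sizes in the shipped test suite — 1000 randomized sessions for the
brute-force cross-check and 8-30 participants per recovery configuration —
were chosen as the smallest sizes at which the binomial checks have the
prescribed >=150 eligible cases per configuration; the whole suite runs in a
few seconds.

## Known limitations

* The rules are order-based pattern matchers; they cannot see intentions a
  participant did not articulate (a searched-for but never-identified
  finding cannot reveal confirmation bias).
* "Availability heuristic" (the correct-diagnosis counterpart of the
  availability bias) has no rule definition and no label; heuristic-side
  association rates cover anchoring and representativeness only.
* The bundled knowledge base and case library are synthetic stand-ins
  shaped like the study materials (vocabulary sizes, diagnosis
  multiplicities, taught pairs), not clinical ground truth.
* Cohort-level frequencies from real participants are not reproducible from
  this package; all validation is against designed constants, closed forms,
  brute-force enumeration and simulated ground truth.
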