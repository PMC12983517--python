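# Methods

## Scope

`vpdx` implements an automated assessment pipeline for staged
virtual-patient (VP) diagnostic encounters: rubric-driven scoring of
learner traces, rule-based detection of five diagnostic cognitive
errors, a synthetic multi-school learner-cohort generator, and the
clustered longitudinal statistics used to relate clinical-reasoning (CR)
components to misdiagnosis and to practice effects. History-taking and
physical-exam *information gathering* is deliberately not assessed —
cases present findings; the assessed skills are interpretation
(diagnostic justification), differential construction, test selection,
and committing to a diagnosis.

## Case and trace model

A case has four stages — one-sentence introduction, history, physical
exam, investigations. Per stage the learner maintains a differential
diagnosis (Ddx) of up to five free-text conditions and flags a
most-probable diagnosis at each stage transition; clinical data are
assigned to diagnoses as *increasing* or *decreasing* their likelihood
(diagnostic justification, DxJ); investigations are ordered free-text in
rounds, and results are revealed only for ordered tests; the case ends
with a final diagnosis and a 1–5 certainty rating (recorded, not
scored).

Free-text diagnoses and test names resolve against curated synonym
lexicons after normalization (case-folding, punctuation stripping,
whitespace collapsing). Exact normalized matching is the default —
scoring stays reproducible; a bounded Levenshtein fallback (distance
≤ 2, via edlib) is available behind a flag for typo tolerance.
Unmatched entries are logged and contribute zero, never an error.

Serialization: JSON documents for cases and scorecards (JSON Schemas
shipped), JSON-Lines for trace streams (one trace per line), CSV for the
long cohort score table. Timestamps are ISO-8601; durations are
reported in minutes.

## Scoring rules

Against an expert scorecard that labels (datum, diagnosis) pairs
`required_increase` / `required_decrease` / `neutral` / `wrong` and
tests `required` / `neutral` / `inappropriate`:

* **Ddx** — percent of the rubric's appropriate diagnoses appearing in
  the union of the learner's Ddx across stages (generation ability;
  extraneous entries are not penalized here).
* **DxJ** — +1 per required pair assigned with the correct direction;
  −0.5 (configurable `wrong_assignment_deduction`) per assignment to a
  wrong-labeled pair or contradicting a required direction; clamped at
  0, normalized by the required-entry count. Unlabeled pairs are
  treated as neutral. Duplicate assignments count once.
* **Test ordering** — (required ordered − inappropriate ordered),
  clamped at 0, over the required count; neutral tests contribute 0.
* **Final diagnosis** — 1.0 for the correct diagnosis as the flagged
  leader, 0.5 (`second_choice_credit`) when it is the second-listed
  entry of the final Ddx, else 0. `correct` means full credit.
* **Penalties** (reported separately from component percents; a config
  flag folds them into the test score) — exceeding the test-count or
  round-count threshold ("auto" = twice the cohort mean, rounded up;
  ties not penalized), results ordered but never used in any DxJ
  assignment, and inappropriate orders, combined with configurable
  weights.
* **Navigation** — per-stage total minutes and view counts.

All component percents are clamped to [0, 100]; scoring is a pure
function of (trace, scorecard, cohort stats).

## Cognitive-error detectors

Five rule-based detectors over DxJ assignments, Ddx snapshots and test
orders; each clause threshold is exposed in `ErrorThresholds`
(defaults in parentheses), and every raised flag carries an evidence
list naming the triggering data. Flags are binary per case; the error
count is their sum (0–5).

* **Premature closure** — the final diagnosis has < 50% of its
  supporting (required_increase) data assigned *and* < 50% of its
  confirmatory tests ordered.
* **Failure to rule out** — some appropriate competitor the learner
  listed has < 50% of its required_decrease data assigned and none of
  its discriminating tests ordered. Unlisted competitors are the Ddx
  score's business, not this detector's.
* **Confirmation bias** — ≥ 1 assignment marking a datum as
  *increasing* the stage's flagged leader when the rubric labels that
  pair required_decrease or wrong.
* **Anchoring** — the same incorrect diagnosis is the flagged leader
  for ≥ 2 consecutive transitions through to the final diagnosis while
  ≥ 2 contradicting (required_decrease) data for it were available
  (stage visited; test results seen only if ordered).
* **Search satisficing** — Ddx size after history < 3 and under half
  the appropriate diagnoses ever listed.

Degenerate denominators count as complete (no flag): a diagnosis with
no supporting data cannot be "unconfirmed", one with no rule-out data
cannot be "not ruled out". Premature closure, failure to rule out and
confirmation bias are driven by DxJ assignments plus rubric labels (the
first two also consult the ordered-test set); they are invariant to
navigation events and certainty.

## Synthetic cohort generator

The generator exists because no learner-level dataset ships with the
pipeline; it emulates the design of a five-school cohort of ~1,000
pre-clerkship students completing up to 20 sequenced cases.

Each learner carries latent logit-scale skills (Ddx building, DxJ, test
ordering, error propensity) drawn from school-shifted normal
populations, with log-time learning: skill at case *t* is
`a + beta*log(t) + r(t)`, where `r` is a shared within-student AR(1)
residual (stationary, rho = 0.4, sd = 0.3) — a per-case "good day"
effect, inverted for error propensity. Behavior is hypothesis-driven:
appropriate diagnoses are listed with probability logistic(s_ddx);
required DxJ pairs are assigned with probability logistic(s_dxj) plus an
engagement bonus for the learner's leading diagnosis; required tests are
ordered with probability logistic(s_inv), boosted for tests confirming
the leader or discriminating listed competitors; inappropriate orders
and spurious wrong assignments scale with error propensity and shrink
with skill (so saturated skill yields perfect play). With probability
logistic(s_err) a case is played *anchored*: an early wrong leader is
held, contradicting data are reinterpreted as supporting (tripping the
anchoring and confirmation-bias detectors), and unless released at
investigations the final diagnosis stays wrong. Otherwise correctness
is Bernoulli in a logistic link on realized component performance
(0–10 point scale), the count of wrong assignments, and a small
practice offset in log(t) capturing case familiarity not mediated by
scored components. Navigation times are log-normal and view counts
Poisson, both tied mildly to skill so time-on-history separates correct
from misdiagnosed cases.

Every trace's RNG is keyed by (seed, school, student, case): adding
students or cases never perturbs existing traces, and reruns are
byte-identical.

**Calibration.** The link slopes default to the reference multivariate
estimates (+0.29 DxJ, +0.18 test ordering, +0.12 Ddx, −0.42 per error,
on the 0–10 / per-error scale). The skill intercepts and slopes, the
link intercept, and the practice offset are root-found by
`vpdx.calibration.calibrate` — bisection against the trace-level
simulator itself with common random numbers — so that first-case and
last-case cohort means hit the reference endpoints (Ddx 79→90.7%, DxJ
27→46.5%, test ordering 46→64.5%, errors 0.87→0.43 per case,
misdiagnosis 27→9%). Behavioral constants (engagement bonuses,
hypothesis-driven ordering boosts, flip rates) are realism choices fixed
before calibration; the frozen results live in `vpdx.defaults` and are
regenerated by rerunning the routine. The natural (uninjected) detector
rate sets a floor on the error-count endpoint; the anchored-play
injection channel supplies the rest.

At the calibrated optimum the anchored-injection propensity is
essentially zero: the detectors' natural firing rates under the
calibrated behavior already account for the error-count trajectory
(first-case mean ~0.92 against the 0.87 target — the one endpoint with
a visible residual, inside its Monte-Carlo tolerance — and 0.44 against
0.43 at case 20). Error flags in the synthetic study therefore emerge
from behavior, not from labeled injections.

A reduced-form generator (`simulate_scores`) draws score tables
directly from the same latent-skill and link structure (binomial
components on the rubric denominators, binomial error counts) for
statistical experiments where exactly known coefficients matter more
than trace mechanics; parameter-recovery and permutation-null suites use
it at scale. Its error counts are parameterized on the *observable*
flag-rate scale (logit endpoints of 0.87/5 and 0.43/5), since the
trace-level error counts are emergent rather than drawn.

**What the generator does not emulate:** real clinical content and
inter-case difficulty variation, group work and faculty review effects,
curricular timing (cases are equally spaced by construction), dropout
and variable completion counts (a fixed case count per cohort), and any
cognitive architecture behind the behaviors. Passing calibration and
recovery tests therefore demonstrates that the pipeline measures what
the generator encodes — not that the generator reproduces real
students.

**M2 emulation.** Second-year cohorts share the M1 skill population
except a lower baseline error rate (−0.15 logit) and complete 10 cases;
this reproduces the intended pattern — similar baselines with fewer
baseline errors, M1 ahead at end of pre-clerkship after twice the
practice. One margin is structurally thin: the expected error-count
difference between 20 and 10 completed cases barely exceeds the M2
baseline advantage, so the end-of-curriculum error contrast holds in
expectation but not reliably in a single 500-per-arm draw (the other
three metrics separate clearly).

## Statistical stage

* **Univariate contrasts** (correct vs misdiagnosed): Welch t-test when
  Shapiro–Wilk (on a 500-capped subsample, alpha = 0.05) accepts
  normality in both groups, Wilcoxon rank-sum otherwise; constant
  variables are skipped with a logged reason. Percent difference is
  (mean_correct − mean_incorrect)/mean_incorrect × 100.
* **GEE**: marginal logistic regression of correctness on the component
  point scores (pct/10) and error count; clusters = students, school a
  fixed (dummy) covariate, AR(1) working correlation over the case
  sequence, robust standard errors. Time variables are log(1+x)
  transformed; counts with |skew| > 2 are dichotomized at zero. A
  cluster-at-school alternative and exchangeable/independence working
  structures are config-selectable; estimates are insensitive to the
  working structure (a marginal-model sanity property the tests
  assert). Collinear designs fail with the offending columns named.
  No multiple-testing correction by default (raw p-values), Holm
  available.
* **Learning curves**: per metric, a generalized mixed model with
  random student intercept and fixed log-sequence trend — linear mixed
  model for percents, variational Bayes binomial / Poisson mixed GLMs
  for correctness / error counts. Fitted trends are reported on the
  response scale over sequence 1..20 with Wald bands, next to empirical
  per-sequence means.
* **Cohort contrast**: M1 vs M2 at sequence 1 and at each cohort's own
  final case; two-proportion z-test for misdiagnosis, rank-sum
  otherwise. A single-case cohort degenerates to start == end and is
  flagged in the output.

Open choices made here: one joint GEE (not per-predictor models);
percents are the primary scale with the 0–10 point scale derived for
regression; the "no plateau" claim is not formally tested.

## Problem sizes

Default desk-scale runs use 5 schools × 60–200 students × 20 cases;
the calibration round-trip suite uses 1,000 students (the emulated
cohort size), parameter recovery 50 replicates of 200 × 20, and
permutation nulls 200 replicates of 100 × 10 — sizes at which every
check's Monte-Carlo error is small relative to its tolerance.

## Known limitations

* The five detector rules are this artifact's operationalizations of
  the named error behaviors; thresholds are declared defaults, not
  estimates, and alternative renderings can be swapped in via config.
* DxJ deduction magnitude (0.5) and penalty point values are
  conventions exposed per scorecard.
* The error-count calibration target is achievable only while the
  natural detector rate stays below it; changing detector thresholds or
  case structure requires re-running calibration.
* GEE estimates are population-averaged; they are compared to reference
  values for sign and rough magnitude, not identity, since marginal
  coefficients attenuate under cluster heterogeneity.
* On fully trace-level data the GEE's conditional estimates shift
  weight onto the error flags and Ddx: the detectors are constructed
  from the justification and test-ordering patterns and so mediate
  those components' association with correctness. The reduced-form
  cohort, whose link is the configured coefficients, is the right
  instrument for coefficient-recovery claims.
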