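"""Rule-based detectors for five diagnostic cognitive errors.

Each detector renders a named cognitive-error behavior as an explicit,
threshold-parameterized rule over the trace's diagnostic-justification
(DxJ) assignments, Ddx snapshots and test orders, judged against the
expert scorecard.  Every raised flag carries an evidence list naming the
data that triggered it, so feedback can cite the behavior.

The five classes:

* premature closure — committing to a final diagnosis without confirming
  it: too few of its supporting (required_increase) data assigned and too
  few of its confirmatory tests ordered.
* failure to rule out — a plausible competitor the learner themselves
  listed is never ruled out: too few of its required_decrease data
  assigned and none of its discriminating tests ordered.
* confirmation bias — reading contradicting data as supporting the
  leading diagnosis: assignments marked "increases" on pairs the rubric
  labels required_decrease or wrong, for the stage's flagged leader.
* anchoring — holding the same incorrect leading diagnosis across stage
  transitions despite accumulated contradicting data, through to the
  final diagnosis.
* search satisficing — stopping differential generation early: a short
  Ddx after the history stage and under half of the appropriate
  diagnoses ever listed.

All clauses and thresholds are config-exposed via
:class:`ErrorThresholds` so alternative renderings can be swapped in.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from pydantic import BaseModel, Field

from .matching import LexiconMatcher
from .model import ClinicalCase, Scorecard, StudentTrace

__all__ = [
    "ErrorThresholds",
    "ErrorFlags",
    "detect_premature_closure",
    "detect_failure_to_rule_out",
    "detect_confirmation_bias",
    "detect_anchoring",
    "detect_search_satisficing",
    "detect_all",
]

ERROR_NAMES = (
    "premature_closure",
    "failure_to_rule_out",
    "confirmation_bias",
    "anchoring",
    "search_satisficing",
)


class ErrorThresholds(BaseModel):
    """Tunable clause thresholds for the five detectors."""

    confirm_fraction: float = Field(default=0.5, gt=0, le=1)
    ruleout_fraction: float = Field(default=0.5, gt=0, le=1)
    bias_min_count: int = Field(default=1, ge=1)
    anchor_min_contradictions: int = Field(default=2, ge=1)
    anchor_min_stages: int = Field(default=2, ge=1)
    satisfice_min_ddx: int = Field(default=3, ge=1)
    coverage_fraction: float = Field(default=0.5, gt=0, le=1)


@dataclass
class Evidence:
    flag: bool
    items: list[str] = field(default_factory=list)


@dataclass
class ErrorFlags:
    premature_closure: bool = False
    failure_to_rule_out: bool = False
    confirmation_bias: bool = False
    anchoring: bool = False
    search_satisficing: bool = False
    evidence: dict[str, list[str]] = field(default_factory=dict)

    @property
    def error_count(self) -> int:
        return sum(getattr(self, name) for name in ERROR_NAMES)

    def as_dict(self) -> dict[str, bool]:
        return {name: getattr(self, name) for name in ERROR_NAMES}


class _TraceView:
    """Canonicalized view of a trace shared by the detectors."""

    def __init__(self, trace: StudentTrace, case: ClinicalCase, scorecard: Scorecard):
        self.trace = trace
        self.case = case
        self.scorecard = scorecard
        self.dx_matcher = LexiconMatcher(case.diagnosis_lexicon)
        test_lex = case.test_lexicon()
        self.test_matcher = LexiconMatcher(test_lex) if test_lex else None
        self.datum_stage = case.finding_stage()
        for t in case.tests:
            self.datum_stage[t.test_id] = "investigations"

        self.final_dx = (
            self.dx_matcher.match(trace.final_diagnosis)
            if trace.final_diagnosis
            else None
        )
        self.listed: set[str] = {
            d
            for d in (self.dx_matcher.match(x) for x in trace.ddx_union())
            if d is not None
        }
        # distinct canonical assignments (unknown data ignored here; the
        # scoring engine is the place that rejects them)
        self.assignments: set[tuple[str, str, str]] = set()
        for a in trace.dxj_assignments:
            dx = self.dx_matcher.match(a.diagnosis)
            if dx is not None:
                self.assignments.add((a.datum_id, dx, a.direction))
        self.ordered: set[str] = set()
        if self.test_matcher is not None:
            for o in trace.test_orders:
                tid = self.test_matcher.match(o.test_text)
                if tid is not None:
                    self.ordered.add(tid)
        # stage -> canonical flagged leader, in stage order
        self.leaders: list[tuple[str, str | None]] = []
        for snap in trace.ddx_snapshots:
            leader = (
                self.dx_matcher.match(snap.most_probable)
                if snap.most_probable
                else None
            )
            self.leaders.append((snap.stage, leader))
        self.visited_stages = {s for s, _ in self.leaders} | {
            e.stage for e in trace.navigation_events
        }

    def assigned(self, datum: str, dx: str, direction: str) -> bool:
        return (datum, dx, direction) in self.assignments

    def leader_at(self, stage: str) -> str | None:
        for s, leader in self.leaders:
            if s == stage:
                return leader
        return None


def _fraction(hits: int, total: int) -> float:
    """Fraction with an empty denominator counting as complete (1.0)."""
    return hits / total if total else 1.0


def _pc(view: _TraceView, th: ErrorThresholds) -> Evidence:
    F = view.final_dx
    if F is None:
        return Evidence(False)
    sc = view.scorecard
    support = sorted(sc.supporting_data(F))
    conf_tests = sorted(sc.confirmatory_tests(F))
    if not support:
        return Evidence(False)
    missing_data = [d for d in support if not view.assigned(d, F, "increases")]
    frac_data = _fraction(len(support) - len(missing_data), len(support))
    missing_tests = [t for t in conf_tests if t not in view.ordered]
    # no confirmatory test exists -> nothing could have been ordered to
    # confirm, so the test clause is satisfied and the data clause decides
    frac_tests = (
        (len(conf_tests) - len(missing_tests)) / len(conf_tests) if conf_tests else 0.0
    )
    if frac_data < th.confirm_fraction and frac_tests < th.confirm_fraction:
        items = [f"unassigned supporting datum {d} for {F}" for d in missing_data]
        items += [f"confirmatory test {t} for {F} not ordered" for t in missing_tests]
        return Evidence(True, items)
    return Evidence(False)


def _ftro(view: _TraceView, th: ErrorThresholds) -> Evidence:
    sc = view.scorecard
    items: list[str] = []
    for comp in sc.appropriate_diagnoses:
        if comp == view.final_dx or comp not in view.listed:
            continue
        rule = sorted(sc.ruleout_data(comp))
        if not rule:
            continue
        missing = [d for d in rule if not view.assigned(d, comp, "decreases")]
        frac = _fraction(len(rule) - len(missing), len(rule))
        disc = sc.discriminating_tests(comp)
        none_ordered = not (disc & view.ordered)
        if frac < th.ruleout_fraction and none_ordered:
            items += [f"competitor {comp}: rule-out datum {d} unassigned" for d in missing]
    return Evidence(bool(items), items)


def _bias(view: _TraceView, th: ErrorThresholds) -> Evidence:
    labels = view.scorecard.label_map()
    items: list[str] = []
    for datum, dx, direction in sorted(view.assignments):
        if direction != "increases":
            continue
        if labels.get((datum, dx)) not in ("required_decrease", "wrong"):
            continue
        stage = view.datum_stage.get(datum)
        if stage is not None and view.leader_at(stage) == dx:
            items.append(f"datum {datum} marked as supporting leading dx {dx}")
    if len(items) >= th.bias_min_count:
        return Evidence(True, items)
    return Evidence(False)


def _anchor(view: _TraceView, th: ErrorThresholds) -> Evidence:
    F = view.final_dx
    if F is None or F == view.scorecard.correct_diagnosis:
        return Evidence(False)
    leaders = [leader for _, leader in view.leaders]
    run = 0
    for leader in reversed(leaders):
        if leader == F:
            run += 1
        else:
            break
    if run < th.anchor_min_stages:
        return Evidence(False)
    contradictions = [
        d
        for d in sorted(view.scorecard.ruleout_data(F))
        if (
            view.datum_stage.get(d) in view.visited_stages
            and (view.datum_stage.get(d) != "investigations" or d in view.ordered)
        )
    ]
    if len(contradictions) >= th.anchor_min_contradictions:
        items = [f"held incorrect leading dx {F} across {run} stage transitions"]
        items += [f"contradicting datum {d} available for {F}" for d in contradictions]
        return Evidence(True, items)
    return Evidence(False)


def _satisfice(view: _TraceView, th: ErrorThresholds) -> Evidence:
    hist = view.trace.snapshot_for("history")
    hist_size = len(hist.diagnoses) if hist is not None else 0
    appropriate = view.scorecard.appropriate_diagnoses
    covered = [d for d in appropriate if d in view.listed]
    coverage = _fraction(len(covered), len(appropriate))
    if hist_size < th.satisfice_min_ddx and coverage < th.coverage_fraction:
        missed = [d for d in appropriate if d not in view.listed]
        items = [f"Ddx of {hist_size} after history"] + [
            f"appropriate dx {d} never listed" for d in missed
        ]
        return Evidence(True, items)
    return Evidence(False)


_DETECTORS = {
    "premature_closure": _pc,
    "failure_to_rule_out": _ftro,
    "confirmation_bias": _bias,
    "anchoring": _anchor,
    "search_satisficing": _satisfice,
}


def detect_all(
    trace: StudentTrace,
    case: ClinicalCase,
    scorecard: Scorecard,
    thresholds: ErrorThresholds | None = None,
) -> ErrorFlags:
    """Run all five detectors; order-independent and deterministic."""
    th = thresholds or ErrorThresholds()
    view = _TraceView(trace, case, scorecard)
    flags = ErrorFlags()
    for name, fn in _DETECTORS.items():
        ev = fn(view, th)
        setattr(flags, name, ev.flag)
        if ev.flag:
            flags.evidence[name] = ev.items
    return flags


def _single(name: str):
    def run(
        trace: StudentTrace,
        case: ClinicalCase,
        scorecard: Scorecard,
        thresholds: ErrorThresholds | None = None,
    ) -> Evidence:
        th = thresholds or ErrorThresholds()
        return _DETECTORS[name](_TraceView(trace, case, scorecard), th)

    run.__name__ = f"detect_{name}"
    run.__doc__ = f"Run only the {name.replace('_', ' ')} detector."
    return run


detect_premature_closure = _single("premature_closure")
detect_failure_to_rule_out = _single("failure_to_rule_out")
detect_confirmation_bias = _single("confirmation_bias")
detect_anchoring = _single("anchoring")
detect_search_satisficing = _single("search_satisficing")
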