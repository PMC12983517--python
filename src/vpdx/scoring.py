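"""Algorithmic scorecard: component scores, penalties, navigation metrics.

Scoring a trace against its expert rubric yields four component scores —
differential-diagnosis coverage (ddx), diagnostic justification (dxj),
test ordering (inv), and final diagnosis — plus penalty and navigation
records.  Component scores are percents clamped to [0, 100]; penalties
are reported separately (a config flag can fold them into inv_pct).

Rules, in brief:

* ddx: fraction of the rubric's appropriate diagnoses that ever appear in
  the learner's Ddx (union across stages).
* dxj: +1 per required (datum, diagnosis) assignment made with the correct
  direction; minus ``wrong_assignment_deduction`` per assignment to a
  wrong-labeled pair or with a direction contradicting a required label;
  clamped at 0 and normalized by the number of required entries.
* inv: (# required tests ordered - # inappropriate tests ordered),
  clamped at 0, over the number of required tests. Neutral tests are 0.
* final dx: full credit for the correct diagnosis as the flagged leader,
  ``second_choice_credit`` if it is the second-listed entry of the final
  Ddx, else 0.
* penalties: exceeding the test / round thresholds ("auto" = twice the
  cohort mean, rounded up; ties not penalized), results ordered but never
  used in any DxJ assignment, and inappropriate orders.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

from .errors import ErrorThresholds, detect_all
from .matching import LexiconMatcher
from .model import CaseScore, ClinicalCase, Scorecard, StudentTrace

__all__ = [
    "CohortStats",
    "PenaltyRecord",
    "CaseScorer",
    "score_ddx",
    "score_dxj",
    "score_investigations",
    "score_final_dx",
    "compute_penalties",
    "compute_navigation_metrics",
    "score_case",
]


@dataclass(frozen=True)
class CohortStats:
    """Cohort means backing the "auto" penalty thresholds."""

    mean_tests: float
    mean_rounds: float

    @classmethod
    def from_traces(cls, traces: Iterable[StudentTrace]) -> "CohortStats":
        n = t = r = 0
        for tr in traces:
            n += 1
            t += len(tr.test_orders)
            r += len({o.round_index for o in tr.test_orders})
        if n == 0:
            raise ValueError("cannot compute cohort stats from zero traces")
        return cls(mean_tests=t / n, mean_rounds=r / n)


@dataclass
class PenaltyRecord:
    excess_tests: bool = False
    excess_rounds: bool = False
    unused_results_count: int = 0
    inappropriate_tests_count: int = 0
    total_penalty_points: float = 0.0


def _clamp_pct(raw: float, denom: int) -> float:
    if denom <= 0:
        raise ValueError("rubric denominator must be positive")
    return min(100.0, 100.0 * max(raw, 0.0) / denom)


class CaseScorer:
    """Bundles a case + scorecard with the matchers needed to score traces.

    Building the matchers once makes scoring a cohort of traces against
    the same case cheap.
    """

    def __init__(
        self,
        case: ClinicalCase,
        scorecard: Scorecard,
        *,
        max_edit_distance: int = 0,
        fold_penalties: bool = False,
        thresholds: ErrorThresholds | None = None,
    ) -> None:
        if case.case_id != scorecard.case_id:
            raise ValueError("case and scorecard case_id mismatch")
        self.case = case
        self.scorecard = scorecard
        self.fold_penalties = fold_penalties
        self.thresholds = thresholds or ErrorThresholds()
        self.dx_matcher = LexiconMatcher(case.diagnosis_lexicon, max_edit_distance)
        test_lex = case.test_lexicon()
        self.test_matcher = (
            LexiconMatcher(test_lex, max_edit_distance) if test_lex else None
        )
        self._label_map = scorecard.label_map()
        self._required = scorecard.required_entries()
        self._valid_data = {f.finding_id for f in case.findings} | {
            t.test_id for t in case.tests
        }

    # -- matching helpers ----------------------------------------------

    def match_dx(self, text: str) -> str | None:
        return self.dx_matcher.match(text)

    def ordered_test_ids(self, trace: StudentTrace) -> list[str]:
        """Matched test ids for the trace's orders (dedup, order kept)."""
        if self.test_matcher is None:
            return []
        seen: dict[str, None] = {}
        for order in trace.test_orders:
            tid = self.test_matcher.match(order.test_text)
            if tid is not None:
                seen.setdefault(tid, None)
        return list(seen)

    def canonical_assignments(
        self, trace: StudentTrace, *, strict: bool = True
    ) -> set[tuple[str, str, str]]:
        """Distinct (datum_id, canonical diagnosis, direction) triples."""
        out: set[tuple[str, str, str]] = set()
        for a in trace.dxj_assignments:
            if a.datum_id not in self._valid_data:
                if strict:
                    raise ValueError(
                        f"assignment references unknown datum_id {a.datum_id!r}"
                    )
                continue
            dx = self.match_dx(a.diagnosis)
            if dx is not None:
                out.add((a.datum_id, dx, a.direction))
        return out

    # -- component scores ----------------------------------------------

    def score_ddx(self, trace: StudentTrace) -> float:
        appropriate = self.scorecard.appropriate_diagnoses
        listed = {self.match_dx(d) for d in trace.ddx_union()}
        hits = sum(1 for d in appropriate if d in listed)
        return _clamp_pct(hits, len(appropriate))

    def score_dxj(self, trace: StudentTrace) -> float:
        required = self._required
        if not required:
            raise ValueError("scorecard has no required dxj entries")
        assigned = self.canonical_assignments(trace)
        required_set = set(required)
        raw = sum(1.0 for entry in required_set if entry in assigned)
        ded = self.scorecard.wrong_assignment_deduction
        for datum, dx, direction in assigned:
            label = self._label_map.get((datum, dx))
            if label == "wrong":
                raw -= ded
            elif label == "required_increase" and direction == "decreases":
                raw -= ded
            elif label == "required_decrease" and direction == "increases":
                raw -= ded
        return _clamp_pct(raw, len(required_set))

    def score_investigations(self, trace: StudentTrace) -> float:
        req = self.scorecard.required_tests()
        if not req:
            raise ValueError("scorecard defines no required tests")
        ordered = set(self.ordered_test_ids(trace))
        raw = len(req & ordered) - len(self.scorecard.inappropriate_tests() & ordered)
        return _clamp_pct(raw, len(req))

    def score_final_dx(self, trace: StudentTrace) -> float:
        correct = self.scorecard.correct_diagnosis
        if trace.final_diagnosis and self.match_dx(trace.final_diagnosis) == correct:
            return 1.0
        snap = trace.final_snapshot()
        if snap is not None and len(snap.diagnoses) >= 2:
            if self.match_dx(snap.diagnoses[1]) == correct:
                return self.scorecard.second_choice_credit
        return 0.0

    # -- penalties & navigation ----------------------------------------

    def resolve_thresholds(
        self, cohort_stats: CohortStats | None
    ) -> tuple[int, int]:
        out = []
        for name, mean_attr in (
            ("max_tests_threshold", "mean_tests"),
            ("max_rounds_threshold", "mean_rounds"),
        ):
            v = getattr(self.scorecard, name)
            if v == "auto":
                if cohort_stats is None:
                    raise ValueError(
                        f"{name} is 'auto' but no cohort_stats were supplied"
                    )
                v = math.ceil(2.0 * getattr(cohort_stats, mean_attr))
            out.append(int(v))
        return out[0], out[1]

    def compute_penalties(
        self, trace: StudentTrace, cohort_stats: CohortStats | None = None
    ) -> PenaltyRecord:
        thr_tests, thr_rounds = self.resolve_thresholds(cohort_stats)
        n_tests = len(trace.test_orders)
        n_rounds = len({o.round_index for o in trace.test_orders})
        ordered = set(self.ordered_test_ids(trace))
        used = {a.datum_id for a in trace.dxj_assignments}
        rec = PenaltyRecord(
            excess_tests=n_tests > thr_tests,
            excess_rounds=n_rounds > thr_rounds,
            unused_results_count=len(ordered - used),
            inappropriate_tests_count=len(
                ordered & self.scorecard.inappropriate_tests()
            ),
        )
        w = self.scorecard.penalty_weights
        rec.total_penalty_points = (
            w.excess_tests * rec.excess_tests
            + w.excess_rounds * rec.excess_rounds
            + w.unused_result * rec.unused_results_count
            + w.inappropriate_test * rec.inappropriate_tests_count
        )
        return rec

    # -- assembly -------------------------------------------------------

    def score(
        self, trace: StudentTrace, cohort_stats: CohortStats | None = None
    ) -> CaseScore:
        nav = compute_navigation_metrics(trace)
        pen = self.compute_penalties(trace, cohort_stats)
        flags = detect_all(trace, self.case, self.scorecard, self.thresholds)
        final_points = self.score_final_dx(trace)
        inv = self.score_investigations(trace)
        if self.fold_penalties:
            inv = max(0.0, inv - pen.total_penalty_points)
        return CaseScore(
            student_id=trace.student_id,
            school_id=trace.school_id,
            cohort=trace.cohort,
            case_id=trace.case_id,
            sequence_index=trace.sequence_index,
            ddx_pct=self.score_ddx(trace),
            dxj_pct=self.score_dxj(trace),
            inv_pct=inv,
            final_dx_points=final_points,
            correct=final_points == 1.0,
            excess_tests=pen.excess_tests,
            excess_rounds=pen.excess_rounds,
            unused_results_count=pen.unused_results_count,
            inappropriate_tests_count=pen.inappropriate_tests_count,
            total_penalty_points=pen.total_penalty_points,
            premature_closure=flags.premature_closure,
            failure_to_rule_out=flags.failure_to_rule_out,
            confirmation_bias=flags.confirmation_bias,
            anchoring=flags.anchoring,
            search_satisficing=flags.search_satisficing,
            error_count=flags.error_count,
            n_tests=len(trace.test_orders),
            n_rounds=len({o.round_index for o in trace.test_orders}),
            time_history=nav["time_history"],
            time_physical=nav["time_physical"],
            time_investigations=nav["time_investigations"],
            views_history=nav["views_history"],
            views_physical=nav["views_physical"],
            views_investigations=nav["views_investigations"],
            certainty=trace.certainty,
        )


def compute_navigation_metrics(trace: StudentTrace) -> dict[str, float]:
    """Per-stage total minutes and view counts from the navigation log."""
    out: dict[str, float] = {}
    for stage in ("history", "physical", "investigations"):
        events = [e for e in trace.navigation_events if e.stage == stage]
        out[f"time_{stage}"] = sum(e.minutes() for e in events)
        out[f"views_{stage}"] = len(events)
    return out


# -- free-function views of the operations (single-trace convenience) ----


def _scorer(case: ClinicalCase, scorecard: Scorecard, **kw) -> CaseScorer:
    return CaseScorer(case, scorecard, **kw)


def score_ddx(trace: StudentTrace, case: ClinicalCase, scorecard: Scorecard) -> float:
    return _scorer(case, scorecard).score_ddx(trace)


def score_dxj(trace: StudentTrace, case: ClinicalCase, scorecard: Scorecard) -> float:
    return _scorer(case, scorecard).score_dxj(trace)


def score_investigations(
    trace: StudentTrace, case: ClinicalCase, scorecard: Scorecard
) -> float:
    return _scorer(case, scorecard).score_investigations(trace)


def score_final_dx(
    trace: StudentTrace, case: ClinicalCase, scorecard: Scorecard
) -> float:
    return _scorer(case, scorecard).score_final_dx(trace)


def compute_penalties(
    trace: StudentTrace,
    case: ClinicalCase,
    scorecard: Scorecard,
    cohort_stats: CohortStats | None = None,
) -> PenaltyRecord:
    return _scorer(case, scorecard).compute_penalties(trace, cohort_stats)


def score_case(
    trace: StudentTrace,
    case: ClinicalCase,
    scorecard: Scorecard,
    cohort_stats: CohortStats | None = None,
    **kw,
) -> CaseScore:
    return _scorer(case, scorecard, **kw).score(trace, cohort_stats)


def score_stream(
    traces: Sequence[StudentTrace],
    cases: dict[str, ClinicalCase],
    scorecards: dict[str, Scorecard],
    cohort_stats: CohortStats | None = None,
    **kw,
) -> list[CaseScore]:
    """Score a heterogeneous trace stream, reusing one scorer per case."""
    if cohort_stats is None and traces:
        # auto thresholds need cohort means per case
        cohort_stats = CohortStats.from_traces(traces)
    scorers: dict[str, CaseScorer] = {}
    out = []
    for tr in traces:
        sc = scorers.get(tr.case_id)
        if sc is None:
            sc = scorers[tr.case_id] = CaseScorer(
                cases[tr.case_id], scorecards[tr.case_id], **kw
            )
        out.append(sc.score(tr, cohort_stats))
    return out
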