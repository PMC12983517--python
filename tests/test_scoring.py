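import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from vpdx.cases import make_synthetic_case
from vpdx.model import (
    ClinicalCase,
    DdxSnapshot,
    DxjAssignment,
    DxjLabel,
    Finding,
    Scorecard,
    StudentTrace,
)
from vpdx.scoring import CaseScorer, CohortStats, compute_navigation_metrics
from trace_builders import (
    A1,
    ALL4,
    ALL_REQUIRED,
    CARD,
    CASE,
    F,
    T,
    TEST_NAME,
    TGT,
    baseline_trace,
    build_trace,
    empty_trace,
    make_nav,
    snapshots,
)

STATS = CohortStats(mean_tests=4.0, mean_rounds=2.0)


@pytest.fixture(scope="module")
def scorer():
    return CaseScorer(CASE, CARD)


def mini_rubric(n_data: int, n_dx: int, labels: dict) -> tuple[ClinicalCase, Scorecard]:
    """Tiny finding-only rubric; labels maps (datum idx, dx idx) -> label."""
    dxs = [f"d{j}" for j in range(1, n_dx + 1)]
    case = ClinicalCase(
        case_id="mini",
        findings=[Finding(finding_id=f"x{i}", stage="history") for i in range(1, n_data + 1)],
        correct_diagnosis="d1",
        diagnosis_lexicon={d: [] for d in dxs},
    )
    card = Scorecard(
        case_id="mini",
        correct_diagnosis="d1",
        appropriate_diagnoses=dxs,
        dxj_labels=[
            DxjLabel(datum_id=f"x{i}", diagnosis=f"d{j}", label=lab)
            for (i, j), lab in labels.items()
        ],
    )
    return case, card


def mini_trace(assignments) -> StudentTrace:
    return StudentTrace(
        student_id="s1",
        school_id="sch",
        case_id="mini",
        sequence_index=1,
        dxj_assignments=[
            DxjAssignment(datum_id=d, diagnosis=dx, direction=dirn)
            for d, dx, dirn in assignments
        ],
    )


class TestDdxScore:
    def test_partial_coverage(self, scorer):
        tr = build_trace(
            snapshots=snapshots([TGT, A1], [TGT, A1, "case01-alt2"], [TGT], (TGT, TGT, TGT)),
            final=TGT,
        )
        assert scorer.score_ddx(tr) == 75.0

    def test_extraneous_entries_do_not_reduce(self, scorer):
        tr = build_trace(
            snapshots=snapshots(
                ALL4[:4], ALL4[:4] + ["case01-red-herring"], ALL4[:3] + ["gibberish"],
                (TGT, TGT, TGT),
            ),
            final=TGT,
        )
        assert scorer.score_ddx(tr) == 100.0

    def test_union_across_stages_counts(self, scorer):
        # diagnoses only ever listed at history still earn credit
        tr = build_trace(
            snapshots=snapshots(ALL4, [TGT], [TGT], (TGT, TGT, TGT)), final=TGT
        )
        assert scorer.score_ddx(tr) == 100.0

    @given(st.lists(st.integers(0, 3), max_size=4, unique=True))
    @settings(max_examples=50, deadline=None)
    def test_matches_set_intersection_oracle(self, idx):
        scorer = CaseScorer(CASE, CARD)
        listed = [ALL4[i] for i in idx]
        tr = build_trace(
            snapshots=[DdxSnapshot(stage="history", diagnoses=listed[:5])], final=""
        )
        expected = 100.0 * len(set(listed) & set(ALL4)) / 4
        assert scorer.score_ddx(tr) == pytest.approx(expected)


class TestDxjScore:
    def test_partial_with_wrong_direction(self):
        labels = {(1, 1): "required_increase", (2, 1): "required_increase",
                  (3, 2): "required_decrease", (4, 2): "required_decrease"}
        case, card = mini_rubric(4, 2, labels)
        sc = CaseScorer(case, card)
        tr = mini_trace(
            [("x1", "d1", "increases"), ("x2", "d1", "increases"),
             ("x3", "d2", "decreases"), ("x4", "d2", "increases")]
        )
        # 3 correct of 4 required, one contradicting a required label
        assert sc.score_dxj(tr) == pytest.approx(100 * (3 - 0.5) / 4)

    def test_no_assignments_scores_zero(self, scorer):
        assert scorer.score_dxj(empty_trace()) == 0.0

    def test_all_required_correct_scores_full(self, scorer):
        assert scorer.score_dxj(baseline_trace()) == 100.0

    def test_unknown_datum_raises(self, scorer):
        tr = build_trace(assignments=[("no-such-datum", TGT, "increases")], final=TGT)
        with pytest.raises(ValueError, match="unknown datum_id"):
            scorer.score_dxj(tr)

    def test_duplicate_assignments_counted_once(self, scorer):
        tr = build_trace(
            assignments=[(F[1], TGT, "increases")] * 3, final=TGT
        )
        one = build_trace(assignments=[(F[1], TGT, "increases")], final=TGT)
        assert scorer.score_dxj(tr) == scorer.score_dxj(one)

    def test_monotone_in_correct_assignments(self, scorer):
        base = [a for a in ALL_REQUIRED if a[1] != TGT]
        prev = -1.0
        for k in range(len(ALL_REQUIRED) - len(base) + 1):
            tr = build_trace(
                assignments=base + [a for a in ALL_REQUIRED if a[1] == TGT][:k],
                final=TGT,
            )
            cur = scorer.score_dxj(tr)
            assert cur >= prev
            prev = cur

    @pytest.mark.parametrize("n_data,n_dx", [(2, 2), (3, 2)])
    def test_exhaustive_enumeration_oracle_small(self, n_data, n_dx):
        labels = {}
        cycle = ["required_increase", "required_decrease", "wrong", "neutral"]
        for idx, (i, j) in enumerate(itertools.product(range(1, n_data + 1), range(1, n_dx + 1))):
            labels[(i, j)] = cycle[idx % 4]
        labels[(1, 1)] = "required_increase"
        case, card = mini_rubric(n_data, n_dx, labels)
        sc = CaseScorer(case, card)
        check_dxj_against_enumeration_oracle(sc, case, card)


def check_dxj_against_enumeration_oracle(sc, case, card):
    """Enumerate every assignment set and compare with a brute-force score."""
    pairs = [(f.finding_id, d) for f in case.findings for d in card.appropriate_diagnoses]
    label_map = card.label_map()
    required = set(card.required_entries())
    ded = card.wrong_assignment_deduction
    for choice in itertools.product((None, "increases", "decreases"), repeat=len(pairs)):
        assignments = [
            (datum, dx, dirn) for (datum, dx), dirn in zip(pairs, choice) if dirn
        ]
        # oracle: direct formula over the assignment set
        raw = sum(1.0 for a in assignments if a in required)
        for datum, dx, dirn in assignments:
            lab = label_map.get((datum, dx))
            if lab == "wrong" or (lab == "required_increase" and dirn == "decreases") or (
                lab == "required_decrease" and dirn == "increases"
            ):
                raw -= ded
        expected = min(100.0, 100.0 * max(raw, 0.0) / len(required))
        got = sc.score_dxj(mini_trace(assignments))
        assert got == pytest.approx(expected), assignments


class TestInvestigationsScore:
    def test_required_plus_inappropriate(self, toy_case, toy_scorecard):
        sc = CaseScorer(toy_case, toy_scorecard)
        tr = build_trace(
            case_id="toy_mi",
            orders=[("ECG", 1), ("troponin", 1), ("d dimer", 1), ("CT head", 2)],
            final="MI",
        )
        assert sc.score_investigations(tr) == pytest.approx(100 * (3 - 1) / 3)

    def test_orders_nothing(self, scorer):
        assert scorer.score_investigations(empty_trace()) == 0.0

    def test_exactly_required_set(self, scorer):
        assert scorer.score_investigations(baseline_trace()) == 100.0

    def test_unmatched_test_text_contributes_zero(self, scorer):
        tr = build_trace(orders=[("totally unknown assay", 1)], final=TGT)
        assert scorer.score_investigations(tr) == 0.0
        assert scorer.test_matcher.unmatched == ["totally unknown assay"]

    def test_inappropriate_never_increases(self, scorer):
        base = build_trace(orders=[(TEST_NAME[1], 1), (TEST_NAME[2], 1)], final=TGT)
        worse = build_trace(
            orders=[(TEST_NAME[1], 1), (TEST_NAME[2], 1), (TEST_NAME[5], 2)], final=TGT
        )
        assert scorer.score_investigations(worse) <= scorer.score_investigations(base)


class TestFinalDx:
    def test_correct_leader_full_credit(self, scorer):
        assert scorer.score_final_dx(baseline_trace()) == 1.0

    def test_second_choice_partial_credit(self, scorer):
        tr = build_trace(
            snapshots=snapshots(ALL4, ALL4, [A1, TGT, "case01-alt2"], (TGT, TGT, A1)),
            final=A1,
        )
        assert scorer.score_final_dx(tr) == 0.5

    def test_absent_scores_zero(self, scorer):
        tr = build_trace(
            snapshots=snapshots([A1], [A1], [A1, "case01-alt2"], (A1, A1, A1)),
            final=A1,
        )
        assert scorer.score_final_dx(tr) == 0.0

    def test_synonym_final_text_matches(self, scorer):
        tr = baseline_trace()
        tr = tr.model_copy(update={"final_diagnosis": "case01 target disease"})
        assert scorer.score_final_dx(tr) == 1.0


class TestPenalties:
    def test_auto_threshold_from_cohort_mean(self, scorer):
        stats = CohortStats(mean_tests=5.0, mean_rounds=2.0)
        orders = [(TEST_NAME[1 + i % 6], 1) for i in range(11)]
        tr = build_trace(orders=orders, final=TGT)
        rec = scorer.compute_penalties(tr, stats)
        assert rec.excess_tests  # 11 > ceil(2*5) = 10
        ten = build_trace(orders=orders[:10], final=TGT)
        assert not scorer.compute_penalties(ten, stats).excess_tests  # tie not penalized

    def test_clean_play_zero_penalties(self, scorer):
        rec = scorer.compute_penalties(baseline_trace(), STATS)
        assert (
            rec.excess_tests,
            rec.excess_rounds,
            rec.unused_results_count,
            rec.inappropriate_tests_count,
            rec.total_penalty_points,
        ) == (False, False, 0, 0, 0.0)

    def test_unused_results_counted(self, scorer):
        tr = build_trace(
            orders=[(TEST_NAME[1], 1), (TEST_NAME[2], 1), (TEST_NAME[3], 1)],
            assignments=[(T[1], TGT, "increases")],
            final=TGT,
        )
        rec = scorer.compute_penalties(tr, STATS)
        assert rec.unused_results_count == 2

    def test_auto_without_stats_is_config_error(self, scorer):
        with pytest.raises(ValueError, match="cohort_stats"):
            scorer.compute_penalties(baseline_trace(), None)

    def test_weighted_total(self, scorer):
        tr = build_trace(orders=[(TEST_NAME[5], 1)], final=TGT)
        rec = scorer.compute_penalties(tr, STATS)
        w = CARD.penalty_weights
        assert rec.total_penalty_points == pytest.approx(
            w.unused_result * 1 + w.inappropriate_test * 1
        )


class TestNavigation:
    def test_two_history_visits(self):
        tr = build_trace(
            nav=[("history", 3.0), ("physical", 1.0), ("history", 4.0)], final=TGT
        )
        m = compute_navigation_metrics(tr)
        assert m["time_history"] == pytest.approx(7.0)
        assert m["views_history"] == 2

    def test_unvisited_stage_zero(self):
        tr = build_trace(nav=[("history", 2.0)], final=TGT)
        m = compute_navigation_metrics(tr)
        assert m["time_investigations"] == 0.0
        assert m["views_investigations"] == 0

    @given(
        st.lists(
            st.tuples(
                st.sampled_from(["history", "physical", "investigations"]),
                st.floats(0.1, 30.0),
            ),
            max_size=8,
        )
    )
    @settings(max_examples=60, deadline=None)
    def test_interval_sum_oracle(self, visits):
        tr = build_trace(nav=visits, final=TGT)
        m = compute_navigation_metrics(tr)
        for stage in ("history", "physical", "investigations"):
            # oracle: re-derive from the raw events
            expected = sum(
                e.minutes() for e in tr.navigation_events if e.stage == stage
            )
            assert m[f"time_{stage}"] == pytest.approx(expected)
            assert m[f"views_{stage}"] == sum(
                1 for s, _ in visits if s == stage
            )


class TestScoreCase:
    def test_perfect_play(self, scorer):
        sc = scorer.score(baseline_trace(), STATS)
        assert (sc.ddx_pct, sc.dxj_pct, sc.inv_pct) == (100.0, 100.0, 100.0)
        assert sc.correct and sc.final_dx_points == 1.0
        assert sc.error_count == 0 and sc.total_penalty_points == 0.0

    def test_empty_play(self, scorer):
        sc = scorer.score(empty_trace(), STATS)
        assert (sc.ddx_pct, sc.dxj_pct, sc.inv_pct) == (0.0, 0.0, 0.0)
        assert not sc.correct

    def test_flawed_trace_matches_hand_scoring(self, toy_case, toy_scorecard):
        sc = CaseScorer(toy_case, toy_scorecard)
        tr = build_trace(
            case_id="toy_mi",
            snapshots=[
                DdxSnapshot(stage="history", diagnoses=["heart attack", "UA"],
                            most_probable="heart attack"),
                DdxSnapshot(stage="physical", diagnoses=["heart attack", "UA", "PE"],
                            most_probable="heart attack"),
                DdxSnapshot(stage="investigations",
                            diagnoses=["unstable angina", "heart attack"],
                            most_probable="unstable angina"),
            ],
            assignments=[
                ("hx_pain", "MI", "increases"),
                ("hx_risk", "MI", "increases"),
                ("troponin", "UA", "increases"),      # contradicts required_decrease
                ("hx_pain", "GERD", "increases"),     # wrong-labeled pair
                ("ddimer", "PE", "decreases"),
            ],
            orders=[("ECG", 1), ("d dimer", 1), ("CT head", 2)],
            final="unstable angina",
            nav=[("introduction", 0.5), ("history", 3.0), ("history", 4.0),
                 ("physical", 4.0), ("investigations", 5.0)],
        )
        score = sc.score(tr, STATS)
        # hand-computed against the rubric: 12 required entries, 3 correct,
        # two deductions of 0.5 -> (3 - 1)/12
        assert score.dxj_pct == pytest.approx(100 * 2 / 12)
        assert score.inv_pct == pytest.approx(100 * (2 - 1) / 3)
        assert score.ddx_pct == pytest.approx(100 * 3 / 4)
        assert score.final_dx_points == 0.5 and not score.correct
        assert score.unused_results_count == 2
        assert score.inappropriate_tests_count == 1
        assert score.total_penalty_points == pytest.approx(0.5 * 2 + 0.5 * 1)
        assert score.time_history == pytest.approx(7.0)
        assert score.views_history == 2
        # bias: troponin marked as supporting the leading (wrong) final dx;
        # premature closure: that final dx has none of its supporting data
        # assigned and no confirmatory test to fall back on
        assert score.confirmation_bias and score.premature_closure
        assert score.error_count == 2

    def test_determinism(self, scorer):
        tr = baseline_trace()
        assert scorer.score(tr, STATS) == scorer.score(tr, STATS)


@st.composite
def adversarial_traces(draw):
    """Random messy-but-valid traces on case01."""
    dx_pool = ALL4 + ["case01-red-herring", "nonsense dx"]
    snaps = []
    for stage in ("history", "physical", "investigations"):
        if draw(st.booleans()):
            diagnoses = draw(
                st.lists(st.sampled_from(dx_pool), min_size=1, max_size=5, unique=True)
            )
            leader = draw(st.sampled_from(diagnoses + [None]))
            snaps.append(
                DdxSnapshot(stage=stage, diagnoses=diagnoses, most_probable=leader)
            )
    data = list(F.values()) + list(T.values())
    assigns = draw(
        st.lists(
            st.tuples(
                st.sampled_from(data),
                st.sampled_from(dx_pool),
                st.sampled_from(["increases", "decreases"]),
            ),
            max_size=20,
        )
    )
    n_ordered = draw(st.integers(0, 7))
    orders = [(TEST_NAME[1 + i % 7], 1 + i % max(n_ordered, 1)) for i in range(n_ordered)]
    rounds = sorted({r for _, r in orders})
    orders = [(t, rounds.index(r) + 1) for t, r in orders]
    final = draw(st.sampled_from(dx_pool + [""]))
    return build_trace(
        snapshots=snaps, assignments=assigns, orders=orders, final=final
    )


class TestClampingProperty:
    @given(adversarial_traces())
    @settings(max_examples=150, deadline=None)
    def test_components_stay_in_range(self, trace):
        scorer = CaseScorer(CASE, CARD)
        sc = scorer.score(trace, STATS)
        for v in (sc.ddx_pct, sc.dxj_pct, sc.inv_pct):
            assert 0.0 <= v <= 100.0
        assert sc.final_dx_points in (0.0, 0.5, 1.0)
        assert sc.error_count == sum(
            [sc.premature_closure, sc.failure_to_rule_out, sc.confirmation_bias,
             sc.anchoring, sc.search_satisficing]
        )
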