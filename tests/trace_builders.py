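"""Hand-constructed traces for scoring and detector tests.

The archetype builders construct, for each cognitive-error class, a trace
engineered to trip exactly that detector, plus a corrected twin (the
baseline competent play) that trips none.
"""

from __future__ import annotations

from datetime import datetime, timedelta

from vpdx.cases import make_synthetic_case
from vpdx.model import (
    DdxSnapshot,
    DxjAssignment,
    NavigationEvent,
    StudentTrace,
    TestOrder,
)

_T0 = datetime(2026, 1, 5, 9, 0, 0)


def make_nav(visits: list[tuple[str, float]], start: datetime = _T0) -> list[NavigationEvent]:
    """Sequential, non-overlapping navigation events from (stage, minutes)."""
    events = []
    clock = start
    for stage, minutes in visits:
        exit_ = clock + timedelta(minutes=minutes)
        events.append(
            NavigationEvent(
                stage=stage, enter_time=clock.isoformat(), exit_time=exit_.isoformat()
            )
        )
        clock = exit_ + timedelta(seconds=10)
    return events


DEFAULT_NAV = [
    ("introduction", 0.5),
    ("history", 4.0),
    ("physical", 3.0),
    ("investigations", 4.0),
]


def build_trace(
    case_id: str = "case01",
    snapshots: list[DdxSnapshot] | None = None,
    assignments: list[tuple[str, str, str]] = (),
    orders: list[tuple[str, int]] = (),
    final: str = "",
    nav: list[tuple[str, float]] | None = None,
    student_id: str = "school1-s0001",
    sequence_index: int = 1,
    certainty: int = 3,
    cohort: str = "M1",
) -> StudentTrace:
    return StudentTrace(
        student_id=student_id,
        school_id="school1",
        cohort=cohort,
        case_id=case_id,
        sequence_index=sequence_index,
        ddx_snapshots=snapshots or [],
        dxj_assignments=[
            DxjAssignment(datum_id=d, diagnosis=dx, direction=dirn)
            for d, dx, dirn in assignments
        ],
        test_orders=[TestOrder(test_text=t, round_index=r) for t, r in orders],
        navigation_events=make_nav(nav if nav is not None else DEFAULT_NAV),
        final_diagnosis=final,
        certainty=certainty,
    )


# --- synthetic case01 structural shorthand -----------------------------

CASE, CARD = make_synthetic_case(1)
TGT = "case01-target"
A1, A2, A3 = "case01-alt1", "case01-alt2", "case01-alt3"
F = {k: f"case01-f{k}" for k in range(1, 11)}
T = {k: f"case01-t{k}" for k in range(1, 8)}
TEST_NAME = {k: f"case01 test {k}" for k in range(1, 8)}

ALL_REQUIRED = [
    (F[1], TGT, "increases"),
    (F[2], TGT, "increases"),
    (F[9], TGT, "increases"),
    (F[5], TGT, "increases"),
    (F[10], TGT, "increases"),
    (T[1], TGT, "increases"),
    (F[3], A1, "increases"),
    (F[6], A1, "decreases"),
    (T[2], A1, "decreases"),
    (T[3], A1, "decreases"),
    (F[4], A2, "increases"),
    (F[7], A2, "decreases"),
    (T[3], A2, "decreases"),
    (T[7], A2, "decreases"),
    (F[8], A3, "increases"),
    (F[2], A3, "decreases"),
    (T[7], A3, "decreases"),
    (T[2], A3, "decreases"),
]

#: the four required test orders for competent play
REQUIRED_ORDERS = [(TEST_NAME[1], 1), (TEST_NAME[2], 1), (TEST_NAME[3], 1), (TEST_NAME[7], 1)]


def snapshots(hist: list[str], phys: list[str], inv: list[str], leaders: tuple[str, str, str]):
    return [
        DdxSnapshot(stage="history", diagnoses=hist, most_probable=leaders[0]),
        DdxSnapshot(stage="physical", diagnoses=phys, most_probable=leaders[1]),
        DdxSnapshot(stage="investigations", diagnoses=inv, most_probable=leaders[2]),
    ]


ALL4 = [TGT, A1, A2, A3]


def baseline_trace(**kw) -> StudentTrace:
    """Competent play on case01: full Ddx, full DxJ, required tests, correct."""
    return build_trace(
        snapshots=snapshots(ALL4, ALL4, ALL4, (TGT, TGT, TGT)),
        assignments=list(ALL_REQUIRED),
        orders=list(REQUIRED_ORDERS),
        final=TGT,
        **kw,
    )


def perfect_trace(**kw) -> StudentTrace:
    return baseline_trace(**kw)


def empty_trace(**kw) -> StudentTrace:
    """A walk-through with no diagnostic work at all."""
    return build_trace(
        snapshots=[],
        final="",
        nav=[("introduction", 0.2), ("investigations", 0.5)],
        **kw,
    )


def archetype(name: str) -> StudentTrace:
    """A trace engineered to trip exactly the named detector."""
    if name == "premature_closure":
        # commits to the (even correct) diagnosis without confirming it:
        # none of the target's supporting data assigned, its confirmatory
        # test not ordered; competitors still properly ruled out
        assigns = [a for a in ALL_REQUIRED if a[1] != TGT]
        return build_trace(
            snapshots=snapshots(ALL4, ALL4, ALL4, (TGT, TGT, TGT)),
            assignments=assigns,
            orders=[(TEST_NAME[2], 1), (TEST_NAME[3], 1), (TEST_NAME[7], 1)],
            final=TGT,
        )
    if name == "failure_to_rule_out":
        # competitor alt1 listed but never ruled out: none of its
        # rule-out data assigned, neither discriminating test ordered
        assigns = [a for a in ALL_REQUIRED if a[0] not in (F[6], T[2], T[3])]
        return build_trace(
            snapshots=snapshots(ALL4, ALL4, ALL4, (TGT, TGT, TGT)),
            assignments=assigns,
            orders=[(TEST_NAME[1], 1), (TEST_NAME[7], 1)],
            final=TGT,
        )
    if name == "confirmation_bias":
        # reads a contradicting datum as supporting the leading diagnosis
        assigns = list(ALL_REQUIRED) + [(F[6], TGT, "increases")]
        return build_trace(
            snapshots=snapshots(ALL4, ALL4, ALL4, (TGT, TGT, TGT)),
            assignments=assigns,
            orders=list(REQUIRED_ORDERS),
            final=TGT,
        )
    if name == "anchoring":
        # holds incorrect alt1 from history to final despite contradicting
        # data being available (f6 seen, t2 and t3 ordered); alt1 itself
        # is well justified so premature closure stays silent, and the
        # other competitors are fully ruled out
        assigns = [
            (F[3], A1, "increases"),
            (F[7], A2, "decreases"),
            (T[3], A2, "decreases"),
            (T[7], A2, "decreases"),
            (F[2], A3, "decreases"),
            (T[7], A3, "decreases"),
            (T[2], A3, "decreases"),
        ]
        return build_trace(
            snapshots=snapshots(ALL4, ALL4, ALL4, (A1, A1, A1)),
            assignments=assigns,
            orders=[(TEST_NAME[2], 1), (TEST_NAME[3], 1), (TEST_NAME[7], 1)],
            final=A1,
        )
    if name == "search_satisficing":
        # a single-condition differential, under half the appropriate
        # diagnoses ever considered; the one diagnosis is fully worked up
        assigns = [a for a in ALL_REQUIRED if a[1] == TGT]
        return build_trace(
            snapshots=snapshots([TGT], [TGT], [TGT], (TGT, TGT, TGT)),
            assignments=assigns,
            orders=[(TEST_NAME[1], 1), (TEST_NAME[2], 1), (TEST_NAME[3], 1)],
            final=TGT,
        )
    raise KeyError(name)


def corrected_twin(name: str) -> StudentTrace:
    """The archetype with its flaw repaired — competent baseline play."""
    return baseline_trace()
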