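"""Synthetic clinical case + scorecard factory.

The study conditions need a bank of staged diagnostic cases with expert
rubrics.  Real case content is clinical authorship and out of scope here;
this factory emits structurally realistic synthetic cases: four
appropriate diagnoses (one correct, three plausible competitors), a
red-herring diagnosis, ten findings split over history and physical
exam, and seven orderable tests (four required — one confirmatory for
the correct diagnosis, three discriminating tests each ruling out two
competitors — one neutral, two inappropriate).

The rubric shape per case:

* correct diagnosis: 6 required_increase data (5 findings + the
  confirmatory test);
* each competitor: 1 required_increase finding plus required_decrease
  data (a finding and two discriminating tests) — 4 entries each;
* 4 wrong-labeled (datum, diagnosis) pairs for deduction and
  confirmation-bias opportunities.

That yields 18 required DxJ entries per case, in line with rubrics that
generate on the order of a hundred derived datapoints per completed
case.  Every competitor can be excluded through more than one route
(its rule-out finding or either discriminating test), mirroring how
real scorecards credit alternative workups.
"""

from __future__ import annotations

from .model import ClinicalCase, DxjLabel, Finding, Scorecard, TestDefinition

__all__ = ["make_synthetic_case", "make_case_library", "N_REQUIRED_ENTRIES"]

#: required DxJ entries per synthetic case (structure above)
N_REQUIRED_ENTRIES = 18

_HISTORY = {1, 2, 3, 4, 9}


def make_synthetic_case(index: int) -> tuple[ClinicalCase, Scorecard]:
    """Deterministically build synthetic case number ``index`` (1-based)."""
    cid = f"case{index:02d}"
    target = f"{cid}-target"
    alts = [f"{cid}-alt{k}" for k in (1, 2, 3)]
    herring = f"{cid}-red-herring"

    lexicon = {
        target: [f"{cid} target disease", f"{cid} tgt"],
        alts[0]: [f"{cid} alternative one"],
        alts[1]: [f"{cid} alternative two"],
        alts[2]: [f"{cid} alternative three"],
        herring: [f"{cid} red herring"],
    }

    findings = [
        Finding(
            finding_id=f"{cid}-f{k}",
            stage="history" if k in _HISTORY else "physical",
            text=f"{cid} finding {k}",
        )
        for k in range(1, 11)
    ]
    f = {k: f"{cid}-f{k}" for k in range(1, 11)}

    tests = [
        TestDefinition(test_id=f"{cid}-t{k}", name=f"{cid} test {k}",
                       synonyms=[f"{cid} t{k}"], result=f"{cid} result {k}")
        for k in range(1, 8)
    ]
    t = {k: f"{cid}-t{k}" for k in range(1, 8)}

    case = ClinicalCase(
        case_id=cid,
        intro=f"A patient presents for evaluation ({cid}).",
        findings=findings,
        tests=tests,
        correct_diagnosis=target,
        diagnosis_lexicon=lexicon,
    )

    L = DxjLabel
    labels = [
        # correct diagnosis: supporting data + confirmatory test
        L(datum_id=f[1], diagnosis=target, label="required_increase"),
        L(datum_id=f[2], diagnosis=target, label="required_increase"),
        L(datum_id=f[9], diagnosis=target, label="required_increase"),
        L(datum_id=f[5], diagnosis=target, label="required_increase"),
        L(datum_id=f[10], diagnosis=target, label="required_increase"),
        L(datum_id=t[1], diagnosis=target, label="required_increase"),
        # competitor 1: why plausible, and how to rule out
        L(datum_id=f[3], diagnosis=alts[0], label="required_increase"),
        L(datum_id=f[6], diagnosis=alts[0], label="required_decrease"),
        L(datum_id=t[2], diagnosis=alts[0], label="required_decrease"),
        L(datum_id=t[3], diagnosis=alts[0], label="required_decrease"),
        # competitor 2
        L(datum_id=f[4], diagnosis=alts[1], label="required_increase"),
        L(datum_id=f[7], diagnosis=alts[1], label="required_decrease"),
        L(datum_id=t[3], diagnosis=alts[1], label="required_decrease"),
        L(datum_id=t[7], diagnosis=alts[1], label="required_decrease"),
        # competitor 3
        L(datum_id=f[8], diagnosis=alts[2], label="required_increase"),
        L(datum_id=f[2], diagnosis=alts[2], label="required_decrease"),
        L(datum_id=t[7], diagnosis=alts[2], label="required_decrease"),
        L(datum_id=t[2], diagnosis=alts[2], label="required_decrease"),
        # wrong-pair opportunities
        L(datum_id=f[6], diagnosis=target, label="wrong"),
        L(datum_id=f[7], diagnosis=target, label="wrong"),
        L(datum_id=f[1], diagnosis=alts[0], label="wrong"),
        L(datum_id=f[8], diagnosis=alts[1], label="wrong"),
        # explicit neutral labels (scoring treats unlabeled pairs as neutral)
        L(datum_id=f[3], diagnosis=target, label="neutral"),
        L(datum_id=f[4], diagnosis=alts[2], label="neutral"),
    ]

    scorecard = Scorecard(
        case_id=cid,
        correct_diagnosis=target,
        appropriate_diagnoses=[target, *alts],
        dxj_labels=labels,
        test_labels={
            t[1]: "required",
            t[2]: "required",
            t[3]: "required",
            t[7]: "required",
            t[4]: "neutral",
            t[5]: "inappropriate",
            t[6]: "inappropriate",
        },
    )
    return case, scorecard


def make_case_library(n_cases: int) -> tuple[dict[str, ClinicalCase], dict[str, Scorecard]]:
    """Build ``n_cases`` synthetic cases keyed by case_id."""
    cases: dict[str, ClinicalCase] = {}
    cards: dict[str, Scorecard] = {}
    for i in range(1, n_cases + 1):
        case, card = make_synthetic_case(i)
        cases[case.case_id] = case
        cards[card.case_id] = card
    return cases, cards
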