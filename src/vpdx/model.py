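"""Domain types and serialization for cases, scorecards, traces and scores.

A virtual-patient encounter has four stages — a one-sentence introduction,
history, physical exam, and investigations.  At each stage the learner
maintains a differential diagnosis (Ddx) of up to five conditions, flags a
most-probable diagnosis at each stage transition, assigns clinical data to
diagnoses as increasing or decreasing their likelihood (diagnostic
justification, DxJ), orders investigations in rounds, and commits to a
final diagnosis with a certainty rating.

Serialization: JSON for single documents (case, scorecard), JSON-Lines for
trace streams (one trace per line), CSV for the long-format score table.
"""

from __future__ import annotations

import json
from datetime import datetime
from dataclasses import dataclass, asdict, fields as dc_fields
from pathlib import Path
from typing import Iterable, Iterator, Literal, Union

import pandas as pd
from pydantic import BaseModel, Field, field_validator, model_validator

FindingStage = Literal["history", "physical"]
NavStage = Literal["introduction", "history", "physical", "investigations"]
DxjLabelKind = Literal["required_increase", "required_decrease", "neutral", "wrong"]
TestLabelKind = Literal["required", "neutral", "inappropriate"]
Direction = Literal["increases", "decreases"]

#: stage order used for snapshots and navigation
STAGES: tuple[str, ...] = ("introduction", "history", "physical", "investigations")
MAX_DDX = 5


class Finding(BaseModel):
    """One history or physical-exam datum presented by the case."""

    finding_id: str
    stage: FindingStage
    text: str = ""


class TestDefinition(BaseModel):
    """An orderable investigation; results are revealed only on order."""

    test_id: str
    name: str
    synonyms: list[str] = Field(min_length=1)
    result: str = Field(min_length=1)


class ClinicalCase(BaseModel):
    """A staged virtual-patient scenario."""

    case_id: str
    intro: str = ""
    findings: list[Finding] = Field(default_factory=list)
    tests: list[TestDefinition] = Field(default_factory=list)
    correct_diagnosis: str
    diagnosis_lexicon: dict[str, list[str]] = Field(default_factory=dict)

    @model_validator(mode="after")
    def _invariants(self) -> "ClinicalCase":
        fids = [f.finding_id for f in self.findings]
        if len(set(fids)) != len(fids):
            raise ValueError("finding_id values must be unique within a case")
        tids = [t.test_id for t in self.tests]
        if len(set(tids)) != len(tids):
            raise ValueError("test_id values must be unique within a case")
        if self.correct_diagnosis not in self.diagnosis_lexicon:
            raise ValueError(
                f"correct_diagnosis {self.correct_diagnosis!r} missing from diagnosis_lexicon"
            )
        return self

    def test_lexicon(self) -> dict[str, list[str]]:
        """test_id -> name + synonyms, for free-text test matching."""
        return {t.test_id: [t.name, *t.synonyms] for t in self.tests}

    def finding_stage(self) -> dict[str, str]:
        return {f.finding_id: f.stage for f in self.findings}


class DxjLabel(BaseModel):
    """Expert label for one (datum, diagnosis) pair."""

    datum_id: str
    diagnosis: str
    label: DxjLabelKind


class PenaltyWeights(BaseModel):
    """Points lost per penalty component."""

    excess_tests: float = 1.0
    excess_rounds: float = 1.0
    unused_result: float = 0.5
    inappropriate_test: float = 0.5


class Scorecard(BaseModel):
    """Expert rubric for one case.

    Diagnoses judged "appropriate" earn Ddx credit.  Each (datum,
    diagnosis) pair is labeled required_increase / required_decrease /
    neutral / wrong; tests are labeled required / neutral / inappropriate.
    Thresholds for the excess-test and excess-round penalties are explicit
    counts or ``"auto"`` (twice the cohort mean, rounded up).
    """

    case_id: str
    correct_diagnosis: str
    appropriate_diagnoses: list[str] = Field(min_length=1)
    dxj_labels: list[DxjLabel] = Field(default_factory=list)
    test_labels: dict[str, TestLabelKind] = Field(default_factory=dict)
    second_choice_credit: float = Field(default=0.5, gt=0, lt=1)
    wrong_assignment_deduction: float = Field(default=0.5, gt=0, le=1)
    max_tests_threshold: Union[int, Literal["auto"]] = "auto"
    max_rounds_threshold: Union[int, Literal["auto"]] = "auto"
    penalty_weights: PenaltyWeights = Field(default_factory=PenaltyWeights)

    @model_validator(mode="after")
    def _invariants(self) -> "Scorecard":
        if self.correct_diagnosis not in self.appropriate_diagnoses:
            raise ValueError("correct_diagnosis must be among appropriate_diagnoses")
        if not any(
            l.diagnosis == self.correct_diagnosis and l.label == "required_increase"
            for l in self.dxj_labels
        ):
            raise ValueError(
                "scorecard needs >=1 required_increase entry for the correct diagnosis"
            )
        for name in ("max_tests_threshold", "max_rounds_threshold"):
            v = getattr(self, name)
            if v != "auto" and v <= 0:
                raise ValueError(f"{name} must be positive or 'auto'")
        return self

    # -- rubric views used by scoring and error detection ---------------

    def label_map(self) -> dict[tuple[str, str], str]:
        return {(l.datum_id, l.diagnosis): l.label for l in self.dxj_labels}

    def required_entries(self) -> list[tuple[str, str, str]]:
        """(datum_id, diagnosis, expected direction) for required labels."""
        out = []
        for l in self.dxj_labels:
            if l.label == "required_increase":
                out.append((l.datum_id, l.diagnosis, "increases"))
            elif l.label == "required_decrease":
                out.append((l.datum_id, l.diagnosis, "decreases"))
        return out

    def required_tests(self) -> set[str]:
        return {t for t, lab in self.test_labels.items() if lab == "required"}

    def inappropriate_tests(self) -> set[str]:
        return {t for t, lab in self.test_labels.items() if lab == "inappropriate"}

    def supporting_data(self, diagnosis: str) -> set[str]:
        """Datum ids labeled required_increase for ``diagnosis``."""
        return {
            l.datum_id
            for l in self.dxj_labels
            if l.diagnosis == diagnosis and l.label == "required_increase"
        }

    def ruleout_data(self, diagnosis: str) -> set[str]:
        """Datum ids labeled required_decrease for ``diagnosis``."""
        return {
            l.datum_id
            for l in self.dxj_labels
            if l.diagnosis == diagnosis and l.label == "required_decrease"
        }

    def confirmatory_tests(self, diagnosis: str) -> set[str]:
        return self.supporting_data(diagnosis) & set(self.test_labels)

    def discriminating_tests(self, diagnosis: str) -> set[str]:
        return self.ruleout_data(diagnosis) & set(self.test_labels)


class DdxSnapshot(BaseModel):
    """Differential diagnosis at one stage, with the flagged leader."""

    stage: NavStage
    diagnoses: list[str] = Field(max_length=MAX_DDX)
    most_probable: str | None = None

    @model_validator(mode="after")
    def _leader_listed(self) -> "DdxSnapshot":
        if self.most_probable is not None and self.most_probable not in self.diagnoses:
            raise ValueError("most_probable must be one of the snapshot diagnoses")
        return self


class DxjAssignment(BaseModel):
    datum_id: str
    diagnosis: str
    direction: Direction
    timestamp: str | None = None


class TestOrder(BaseModel):
    test_text: str
    round_index: int = Field(ge=1)


class NavigationEvent(BaseModel):
    """One stay in a stage; ISO-8601 timestamps."""

    stage: NavStage
    enter_time: str
    exit_time: str

    @model_validator(mode="after")
    def _ordered(self) -> "NavigationEvent":
        if datetime.fromisoformat(self.exit_time) < datetime.fromisoformat(self.enter_time):
            raise ValueError("exit_time precedes enter_time")
        return self

    def minutes(self) -> float:
        dt = datetime.fromisoformat(self.exit_time) - datetime.fromisoformat(self.enter_time)
        return dt.total_seconds() / 60.0


class StudentTrace(BaseModel):
    """Full event log of one student completing one case."""

    student_id: str
    school_id: str
    cohort: Literal["M1", "M2"] = "M1"
    case_id: str
    sequence_index: int = Field(ge=1, le=20)
    ddx_snapshots: list[DdxSnapshot] = Field(default_factory=list)
    dxj_assignments: list[DxjAssignment] = Field(default_factory=list)
    test_orders: list[TestOrder] = Field(default_factory=list)
    navigation_events: list[NavigationEvent] = Field(default_factory=list)
    final_diagnosis: str = ""
    certainty: int = Field(default=3, ge=1, le=5)

    @field_validator("test_orders")
    @classmethod
    def _rounds_contiguous(cls, v: list[TestOrder]) -> list[TestOrder]:
        rounds = sorted({o.round_index for o in v})
        if rounds and rounds != list(range(1, len(rounds) + 1)):
            raise ValueError("round_index values must be contiguous from 1")
        return v

    @field_validator("navigation_events")
    @classmethod
    def _non_overlapping(cls, v: list[NavigationEvent]) -> list[NavigationEvent]:
        spans = sorted(
            (datetime.fromisoformat(e.enter_time), datetime.fromisoformat(e.exit_time))
            for e in v
        )
        for (_, prev_exit), (nxt_enter, _) in zip(spans, spans[1:]):
            if nxt_enter < prev_exit:
                raise ValueError("navigation intervals overlap")
        return v

    def snapshot_for(self, stage: str) -> DdxSnapshot | None:
        for snap in self.ddx_snapshots:
            if snap.stage == stage:
                return snap
        return None

    def final_snapshot(self) -> DdxSnapshot | None:
        snap = self.snapshot_for("investigations")
        if snap is None and self.ddx_snapshots:
            snap = self.ddx_snapshots[-1]
        return snap

    def ddx_union(self) -> list[str]:
        """All diagnoses ever listed, in first-seen order."""
        seen: dict[str, None] = {}
        for snap in self.ddx_snapshots:
            for d in snap.diagnoses:
                seen.setdefault(d, None)
        return list(seen)


@dataclass
class CaseScore:
    """Derived per-case record: component scores, penalties, errors, navigation.

    Percent scores are on 0-100; ``*_points`` views on the 0-10 scale used
    for regression are derived downstream (pct / 10).
    """

    student_id: str
    school_id: str
    cohort: str
    case_id: str
    sequence_index: int
    ddx_pct: float = 0.0
    dxj_pct: float = 0.0
    inv_pct: float = 0.0
    final_dx_points: float = 0.0
    correct: bool = False
    excess_tests: bool = False
    excess_rounds: bool = False
    unused_results_count: int = 0
    inappropriate_tests_count: int = 0
    total_penalty_points: float = 0.0
    premature_closure: bool = False
    failure_to_rule_out: bool = False
    confirmation_bias: bool = False
    anchoring: bool = False
    search_satisficing: bool = False
    error_count: int = 0
    n_tests: int = 0
    n_rounds: int = 0
    time_history: float = 0.0
    time_physical: float = 0.0
    time_investigations: float = 0.0
    views_history: int = 0
    views_physical: int = 0
    views_investigations: int = 0
    certainty: int = 3

    def to_dict(self) -> dict:
        return asdict(self)


SCORE_COLUMNS: list[str] = [f.name for f in dc_fields(CaseScore)]

ERROR_FLAG_COLUMNS: list[str] = [
    "premature_closure",
    "failure_to_rule_out",
    "confirmation_bias",
    "anchoring",
    "search_satisficing",
]


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def write_case(case: ClinicalCase, path: str | Path) -> None:
    Path(path).write_text(case.model_dump_json(indent=2) + "\n")


def read_case(path: str | Path) -> ClinicalCase:
    return ClinicalCase.model_validate_json(Path(path).read_text())


def write_scorecard(card: Scorecard, path: str | Path) -> None:
    Path(path).write_text(card.model_dump_json(indent=2) + "\n")


def read_scorecard(path: str | Path) -> Scorecard:
    return Scorecard.model_validate_json(Path(path).read_text())


def write_traces(traces: Iterable[StudentTrace], path: str | Path) -> int:
    """Write traces as JSON-Lines (one trace per line); returns the count."""
    n = 0
    with open(path, "w") as fh:
        for tr in traces:
            fh.write(tr.model_dump_json() + "\n")
            n += 1
    return n


def read_traces(path: str | Path) -> Iterator[StudentTrace]:
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line:
                yield StudentTrace.model_validate_json(line)


def scores_to_frame(scores: Iterable[CaseScore]) -> pd.DataFrame:
    """Assemble CaseScore records into the long-format cohort table.

    Rows are ordered by (school_id, student_id, sequence_index); one row
    per (student, case).
    """
    df = pd.DataFrame([s.to_dict() for s in scores], columns=SCORE_COLUMNS)
    df = df.sort_values(["school_id", "student_id", "sequence_index"], kind="mergesort")
    return df.reset_index(drop=True)


def validate_cohort(df: pd.DataFrame) -> pd.DataFrame:
    """Check CohortDataset invariants; returns the (sorted) frame."""
    missing = [c for c in SCORE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort table missing columns: {missing}")
    if df.duplicated(["student_id", "case_id"]).any():
        raise ValueError("cohort table has duplicate (student_id, case_id) rows")
    df = df.sort_values(["school_id", "student_id", "sequence_index"], kind="mergesort")
    seq_ok = df.groupby("student_id")["sequence_index"].apply(
        lambda s: s.is_monotonic_increasing and s.is_unique
    )
    if not seq_ok.all():
        bad = seq_ok[~seq_ok].index.tolist()
        raise ValueError(f"sequence_index not strictly increasing for students: {bad[:5]}")
    return df.reset_index(drop=True)


def write_cohort(df: pd.DataFrame, path: str | Path) -> None:
    validate_cohort(df).to_csv(path, index=False)


def read_cohort(path: str | Path) -> pd.DataFrame:
    return validate_cohort(pd.read_csv(path))


def export_schemas(out_dir: str | Path) -> list[Path]:
    """Write the JSON Schemas for the shipped document types."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for model in (ClinicalCase, Scorecard, StudentTrace):
        p = out / f"{model.__name__}.schema.json"
        p.write_text(json.dumps(model.model_json_schema(), indent=2) + "\n")
        written.append(p)
    return written
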