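"""Synthetic multi-school learner cohorts with latent skills and growth.

Each learner carries a latent skill vector on the logit scale —
(ddx, dxj, inv, err) for differential building, diagnostic justification,
test ordering, and error propensity — plus per-skill learning slopes.
Skill at case ``t`` in the sequence is

    s_k(t) = a_k + beta_k * f(t) + r(t),      f(t) = log(t) by default,

where ``r`` is a shared within-student AR(1) residual (a per-case "good
day" effect; it is subtracted from the error-propensity skill).  Students
are nested in schools via school-level shifts of the skill means.

Behavior generation is hypothesis-driven: learners list appropriate
diagnoses with probability logistic(s_ddx), justify data for diagnoses
they have listed (their leading diagnosis more readily), order required
tests with probability logistic(s_inv) boosted for tests that confirm
their leader or discriminate listed competitors, and order inappropriate
tests at a rate tied to error propensity.  With probability
logistic(s_err) a case is played "anchored": an early incorrect leader is
held across stages, contradicting data are reinterpreted as supporting,
and unless the anchor is released at investigations the final diagnosis
is the anchored one.  Otherwise the final diagnosis is drawn correct with
probability

    logistic(g0 + d*f(t) + g_dxj*x_dxj + g_inv*x_inv + g_ddx*x_ddx - g_err*e)

with component performances x on the 0-10 point scale and ``e`` the count
of wrong assignments made.

Two levels of fidelity are exposed: :func:`simulate_study` emits full
StudentTrace event logs (scored by the scoring engine), and
:func:`simulate_scores` is a reduced-form generator that draws CaseScore
tables directly from the same latent-skill/link structure for fast
statistical experiments with exactly known truth.

Reproducibility: every trace's RNG is keyed by (seed, school, student,
case), so adding students or cases never perturbs existing traces.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from datetime import datetime, timedelta
from typing import Iterator, Literal

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from . import defaults
from .cases import make_case_library
from .model import (
    CaseScore,
    ClinicalCase,
    DdxSnapshot,
    DxjAssignment,
    NavigationEvent,
    Scorecard,
    StudentTrace,
    TestOrder,
    scores_to_frame,
)
from .scoring import CaseScorer, CohortStats

__all__ = [
    "SimConfig",
    "LearnerProfile",
    "sample_cohort",
    "simulate_trace",
    "iter_study",
    "simulate_study",
    "run_study",
    "simulate_scores",
]

SKILLS = ("ddx", "dxj", "inv", "err")

_BASE_TIME = datetime(2026, 1, 5, 9, 0, 0)


def _logistic(x: float) -> float:
    if x >= 0:
        return 1.0 / (1.0 + math.exp(-x))
    e = math.exp(x)
    return e / (1.0 + e)


class SimConfig(BaseModel):
    """Study-design and generator parameters; ``seed`` is mandatory."""

    seed: int
    n_schools: int = Field(default=5, ge=1)
    n_students_per_school: int = Field(default=200, ge=1)
    n_cases: int = Field(default=20, ge=1, le=20)
    cohort: Literal["M1", "M2"] = "M1"

    skill_mu: dict[str, float] = Field(default_factory=lambda: dict(defaults.SKILL_MU))
    skill_beta: dict[str, float] = Field(default_factory=lambda: dict(defaults.SKILL_BETA))
    skill_sd: dict[str, float] = Field(default_factory=lambda: dict(defaults.SKILL_SD))
    school_sd: float = Field(default=0.15, ge=0)
    rho: float = Field(default=0.4, ge=0, lt=1)
    sigma_ar: float = Field(default=0.3, gt=0)
    learning_shape: Literal["log", "linear"] = "log"

    gamma: dict[str, float] = Field(default_factory=lambda: dict(defaults.GAMMA))
    behavior: dict[str, float] = Field(default_factory=lambda: dict(defaults.BEHAVIOR))
    navigation: dict[str, float] = Field(default_factory=lambda: dict(defaults.NAVIGATION))

    #: reduced-form observable error-count logit (see defaults.REDUCED_ERR)
    reduced_err_mu: float = defaults.REDUCED_ERR["mu"]
    reduced_err_beta: float = defaults.REDUCED_ERR["beta"]

    #: M2 cohorts start with a lower error-propensity mean and run 10 cases
    m2_err_mu_delta: float = -0.15
    m2_n_cases: int = Field(default=10, ge=1, le=20)

    def shape(self, t: int) -> float:
        return math.log(t) if self.learning_shape == "log" else float(t - 1)

    def for_cohort(self) -> "SimConfig":
        """Apply the M2 adjustments if this config targets the M2 cohort."""
        if self.cohort != "M2":
            return self
        cfg = self.model_copy(deep=True)
        cfg.skill_mu["err"] += self.m2_err_mu_delta
        cfg.reduced_err_mu += self.m2_err_mu_delta
        cfg.n_cases = self.m2_n_cases
        return cfg

    def truth(self) -> dict:
        """Ground-truth generating parameters for recovery tests."""
        return {
            "seed": self.seed,
            "gamma": dict(self.gamma),
            "skill_mu": dict(self.skill_mu),
            "skill_beta": dict(self.skill_beta),
            "skill_sd": dict(self.skill_sd),
            "school_sd": self.school_sd,
            "rho": self.rho,
            "sigma_ar": self.sigma_ar,
            "learning_shape": self.learning_shape,
            "cohort": self.cohort,
            "n_schools": self.n_schools,
            "n_students_per_school": self.n_students_per_school,
            "n_cases": self.n_cases,
        }


@dataclass
class LearnerProfile:
    student_id: str
    school_id: str
    cohort: str
    a: dict[str, float]
    beta: dict[str, float]
    rho: float
    sigma_ar: float
    school_index: int
    student_index: int


def _rng(*key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(key))


def school_effects(config: SimConfig) -> np.ndarray:
    """(n_schools x n_skills) logit shifts, drawn once per school."""
    out = np.zeros((config.n_schools, len(SKILLS)))
    for i in range(config.n_schools):
        r = _rng(config.seed, 999_983, i)
        out[i] = r.normal(0.0, config.school_sd, size=len(SKILLS))
    return out


def sample_cohort(config: SimConfig) -> list[LearnerProfile]:
    """Draw the learner profiles for the configured study."""
    cfg = config.for_cohort()
    eff = school_effects(cfg)
    profiles = []
    for i in range(cfg.n_schools):
        school_id = f"school{i + 1}"
        for j in range(cfg.n_students_per_school):
            r = _rng(cfg.seed, i, j)
            a = {
                k: cfg.skill_mu[k] + eff[i, ki] + r.normal(0.0, cfg.skill_sd[k])
                for ki, k in enumerate(SKILLS)
            }
            profiles.append(
                LearnerProfile(
                    student_id=f"{school_id}-s{j + 1:04d}",
                    school_id=school_id,
                    cohort=cfg.cohort,
                    a=a,
                    beta=dict(cfg.skill_beta),
                    rho=cfg.rho,
                    sigma_ar=cfg.sigma_ar,
                    school_index=i,
                    student_index=j,
                )
            )
    return profiles


def residual_path(profile: LearnerProfile, n_cases: int, seed: int) -> np.ndarray:
    """Stationary AR(1) shared residual across the student's case sequence."""
    r = _rng(seed, profile.school_index, profile.student_index, 777)
    out = np.empty(n_cases)
    out[0] = r.normal(0.0, profile.sigma_ar)
    innov_sd = profile.sigma_ar * math.sqrt(1.0 - profile.rho**2)
    for t in range(1, n_cases):
        out[t] = profile.rho * out[t - 1] + r.normal(0.0, innov_sd)
    return out


def skills_at(
    profile: LearnerProfile, config: SimConfig, t: int, resid: float
) -> dict[str, float]:
    f = config.shape(t)
    s = {k: profile.a[k] + profile.beta[k] * f for k in SKILLS}
    for k in ("ddx", "dxj", "inv"):
        s[k] += resid
    s["err"] -= resid
    return s


def _iso(dt: datetime) -> str:
    return dt.replace(microsecond=0).isoformat()


def simulate_trace(
    profile: LearnerProfile,
    case: ClinicalCase,
    scorecard: Scorecard,
    sequence_index: int,
    config: SimConfig,
    rng: np.random.Generator,
    resid: float = 0.0,
) -> StudentTrace:
    """Generate one student-case event log from the behavior model."""
    B = config.behavior
    G = config.gamma
    s = skills_at(profile, config, sequence_index, resid)
    p_dxj_skill = _logistic(s["dxj"])

    target = scorecard.correct_diagnosis
    appropriate = list(scorecard.appropriate_diagnoses)
    competitors = [d for d in appropriate if d != target]
    herrings = [d for d in case.diagnosis_lexicon if d not in appropriate]
    req_entries = scorecard.required_entries()
    req_tests = sorted(scorecard.required_tests())
    bad_tests = sorted(scorecard.inappropriate_tests())
    neutral_tests = sorted(
        t for t, lab in scorecard.test_labels.items() if lab == "neutral"
    )
    test_ids = {t.test_id for t in case.tests}
    test_name = {t.test_id: t for t in case.tests}

    # --- differential construction -----------------------------------
    p_list = _logistic(s["ddx"])
    listed = [d for d in appropriate if rng.random() < p_list]
    listed += [d for d in herrings if rng.random() < B["p_distractor"]]

    anchored = rng.random() < _logistic(s["err"])
    anchor_dx: str | None = None
    anchor_released = False
    if anchored:
        anchor_dx = competitors[rng.integers(len(competitors))]
        if anchor_dx not in listed:
            listed.insert(0, anchor_dx)
        anchor_released = rng.random() < B["anchor_release"]

    entry_stage = {
        d: ("history" if rng.random() < B["p_entry_history"] else "physical")
        for d in listed
    }
    if anchor_dx is not None:
        entry_stage[anchor_dx] = "history"

    hist_members = [d for d in listed if entry_stage[d] == "history"][: 5]
    phys_members = (hist_members + [d for d in listed if entry_stage[d] == "physical"])[: 5]

    # the working diagnosis: the provisional leader the learner engages
    # with (justifies, confirms) before investigations settle the case
    listed_comps = [d for d in competitors if d in listed]
    if anchored:
        working_dx = anchor_dx
    elif target in listed and (rng.random() < B["p_lead_correct"] or not listed_comps):
        working_dx = target
    elif listed_comps:
        working_dx = listed_comps[rng.integers(len(listed_comps))]
    else:
        working_dx = None

    def interim_leader(members: list[str]) -> str | None:
        if not members:
            return None
        if working_dx in members:
            return working_dx
        return members[rng.integers(len(members))]

    lead_hist = interim_leader(hist_members)
    lead_phys = interim_leader(phys_members)

    # --- test ordering ------------------------------------------------
    conf_for_target = scorecard.confirmatory_tests(target)
    disc_boost = set()
    for c in competitors:
        if c in listed:
            disc_boost |= scorecard.discriminating_tests(c)
    ordered: list[str] = []
    for tid in req_tests:
        b = B["b_conf"] if tid in conf_for_target else B["b_disc"]
        if tid in disc_boost:
            b += B["b_disc_listed"]
        if rng.random() < _logistic(s["inv"] + b):
            ordered.append(tid)
    for tid in neutral_tests:
        if rng.random() < B["p_neutral_test"]:
            ordered.append(tid)
    for tid in bad_tests:
        if rng.random() < _logistic(s["err"] + B["b_bad"]):
            ordered.append(tid)
    ordered_set = set(ordered)

    # --- diagnostic justification -------------------------------------
    listed_set = set(listed)
    engaged_dx = working_dx if working_dx is not None else target
    assignments: list[DxjAssignment] = []
    n_req_correct = 0
    n_wrong_acts = 0
    for datum, dx, direction in req_entries:
        if dx not in listed_set:
            continue
        if datum in test_ids and datum not in ordered_set:
            continue
        b = B["b_target"] if dx == engaged_dx else B["b_comp"]
        if rng.random() >= _logistic(s["dxj"] + b):
            continue
        actual = direction
        if anchored and dx == anchor_dx and direction == "decreases":
            if rng.random() < B["eps_flip_anchor"]:
                actual = "increases"
        elif rng.random() < B["eps_flip"] * (1.0 - p_dxj_skill):
            actual = "increases" if direction == "decreases" else "decreases"
        assignments.append(
            DxjAssignment(datum_id=datum, diagnosis=dx, direction=actual)
        )
        if actual == direction:
            n_req_correct += 1
        else:
            n_wrong_acts += 1
    for label in scorecard.dxj_labels:
        if label.label != "wrong" or label.diagnosis not in listed_set:
            continue
        if label.datum_id in test_ids and label.datum_id not in ordered_set:
            continue
        if rng.random() < B["eps_wrong"] * (1.0 - p_dxj_skill):
            assignments.append(
                DxjAssignment(
                    datum_id=label.datum_id,
                    diagnosis=label.diagnosis,
                    direction="increases",
                )
            )
            n_wrong_acts += 1

    # --- final diagnosis ----------------------------------------------
    dxj_frac = n_req_correct / max(len(req_entries), 1)
    n_req_ordered = len(ordered_set & set(req_tests))
    n_bad_ordered = len(ordered_set & set(bad_tests))
    inv_frac = min(1.0, max(0.0, (n_req_ordered - n_bad_ordered) / max(len(req_tests), 1)))
    ddx_frac = len(listed_set & set(appropriate)) / len(appropriate)

    if anchored and not anchor_released:
        final_dx = anchor_dx
        correct = False
    else:
        lin = (
            G["intercept"]
            + G["practice"] * config.shape(sequence_index)
            + G["dxj"] * 10.0 * dxj_frac
            + G["inv"] * 10.0 * inv_frac
            + G["ddx"] * 10.0 * ddx_frac
            - G["err"] * n_wrong_acts
        )
        p_correct = _logistic(lin)
        if target not in listed_set:
            # picking a diagnosis never entertained in the Ddx requires a
            # late recall, itself a function of differential-building skill
            p_correct *= _logistic(s["ddx"] + B["b_guess"])
        correct = rng.random() < p_correct
        if correct:
            final_dx = target
        elif working_dx is not None and working_dx != target:
            # a wrong call usually lands on the engaged working diagnosis
            final_dx = working_dx
        else:
            wrong_listed = [d for d in competitors if d in listed_set]
            final_dx = (
                wrong_listed[rng.integers(len(wrong_listed))]
                if wrong_listed
                else competitors[rng.integers(len(competitors))]
            )

    inv_members = list(dict.fromkeys([final_dx] + phys_members))[: 5]
    # second-choice structure: the runner-up slot goes to the target
    # diagnosis (if listed) half the time when the leader is wrong
    rest = [d for d in inv_members if d != final_dx]
    if final_dx != target and target in rest and rng.random() < 0.5:
        rest.remove(target)
        rest.insert(0, target)
    else:
        rng.shuffle(rest)
    inv_order = [final_dx] + rest

    snapshots = []
    if hist_members:
        snapshots.append(
            DdxSnapshot(stage="history", diagnoses=hist_members, most_probable=lead_hist)
        )
    if phys_members:
        snapshots.append(
            DdxSnapshot(stage="physical", diagnoses=phys_members, most_probable=lead_phys)
        )
    snapshots.append(
        DdxSnapshot(stage="investigations", diagnoses=inv_order, most_probable=final_dx)
    )

    # --- rounds -------------------------------------------------------
    test_orders: list[TestOrder] = []
    if ordered:
        n_rounds = 1 + int(rng.binomial(min(len(ordered) - 1, 3), B["p_extra_round"]))
        bounds = np.array_split(np.arange(len(ordered)), n_rounds)
        for ridx, chunk in enumerate(bounds, start=1):
            for k in chunk:
                tdef = test_name[ordered[k]]
                text = tdef.name if rng.random() < 0.7 else tdef.synonyms[0]
                test_orders.append(TestOrder(test_text=text, round_index=ridx))

    # --- navigation ---------------------------------------------------
    NV = config.navigation
    engagement = 0.5 + _logistic(s["dxj"])
    events: list[NavigationEvent] = []
    clock = _BASE_TIME
    intro_min = 0.3 + 0.4 * rng.random()
    events.append(
        NavigationEvent(
            stage="introduction",
            enter_time=_iso(clock),
            exit_time=_iso(clock + timedelta(minutes=intro_min)),
        )
    )
    clock += timedelta(minutes=intro_min + 0.1)
    visits: list[tuple[str, float]] = []
    for stage in ("history", "physical", "investigations"):
        views = 1 + int(rng.poisson(NV[f"lam_{stage}"] * (engagement - 0.4)))
        total = float(
            np.exp(rng.normal(math.log(NV[f"m_{stage}"] * (0.4 + 0.6 * engagement)), NV["sdlog"]))
        )
        per = total / views
        for _ in range(views):
            visits.append((stage, per))
    # first pass in stage order, revisits appended afterwards
    first = {"history": False, "physical": False, "investigations": False}
    ordered_visits: list[tuple[str, float]] = []
    extras: list[tuple[str, float]] = []
    for stage, dur in visits:
        if not first[stage]:
            first[stage] = True
            ordered_visits.append((stage, dur))
        else:
            extras.append((stage, dur))
    ordered_visits += extras
    for stage, dur in ordered_visits:
        events.append(
            NavigationEvent(
                stage=stage,
                enter_time=_iso(clock),
                exit_time=_iso(clock + timedelta(minutes=dur)),
            )
        )
        clock += timedelta(minutes=dur + 0.05)

    certainty = int(np.clip(round(2.5 + 0.7 * s["dxj"] + 0.6 * rng.normal()), 1, 5))
    final_text = (
        final_dx
        if rng.random() < 0.6
        else case.diagnosis_lexicon[final_dx][0]
        if case.diagnosis_lexicon.get(final_dx)
        else final_dx
    )

    return StudentTrace(
        student_id=profile.student_id,
        school_id=profile.school_id,
        cohort=profile.cohort,
        case_id=case.case_id,
        sequence_index=sequence_index,
        ddx_snapshots=snapshots,
        dxj_assignments=assignments,
        test_orders=test_orders,
        navigation_events=events,
        final_diagnosis=final_text,
        certainty=certainty,
    )


def _case_sequence(
    config: SimConfig,
    school_index: int,
    cases: dict[str, ClinicalCase],
) -> list[str]:
    """Case order for a school: the library rotated by school index."""
    ids = list(cases)
    k = school_index % len(ids)
    return ids[k:] + ids[:k]


def iter_study(
    config: SimConfig,
    cases: dict[str, ClinicalCase] | None = None,
    scorecards: dict[str, Scorecard] | None = None,
) -> Iterator[StudentTrace]:
    """Stream all student-case traces for the configured study."""
    cfg = config.for_cohort()
    if cases is None or scorecards is None:
        cases, scorecards = make_case_library(cfg.n_cases)
    if len(cases) < cfg.n_cases:
        raise ValueError("need at least n_cases cases")
    for profile in sample_cohort(config):
        seq = _case_sequence(cfg, profile.school_index, cases)
        resid = residual_path(profile, cfg.n_cases, cfg.seed)
        for t in range(1, cfg.n_cases + 1):
            cid = seq[t - 1]
            rng = _rng(cfg.seed, profile.school_index, profile.student_index, 1000 + t)
            yield simulate_trace(
                profile, cases[cid], scorecards[cid], t, cfg, rng, resid[t - 1]
            )


def simulate_study(
    config: SimConfig,
    cases: dict[str, ClinicalCase] | None = None,
    scorecards: dict[str, Scorecard] | None = None,
) -> tuple[list[StudentTrace], dict]:
    """All traces plus the ground-truth generating parameter record."""
    return list(iter_study(config, cases, scorecards)), config.for_cohort().truth()


def run_study(
    config: SimConfig,
    cases: dict[str, ClinicalCase] | None = None,
    scorecards: dict[str, Scorecard] | None = None,
    cohort_stats: CohortStats | None = None,
) -> pd.DataFrame:
    """Simulate and score the whole study, returning the cohort table.

    Penalty thresholds default to "auto" (twice the cohort mean), which
    needs cohort means first; the study is simulated twice — the first
    pass only accumulates test/round counts.  Both passes are driven by
    the same per-(student, case) RNG keys, so the traces are identical.
    """
    cfg = config.for_cohort()
    if cases is None or scorecards is None:
        cases, scorecards = make_case_library(cfg.n_cases)
    if cohort_stats is None:
        n = t_sum = r_sum = 0
        for tr in iter_study(config, cases, scorecards):
            n += 1
            t_sum += len(tr.test_orders)
            r_sum += len({o.round_index for o in tr.test_orders})
        cohort_stats = CohortStats(mean_tests=t_sum / n, mean_rounds=r_sum / n)
    scorers = {
        cid: CaseScorer(cases[cid], scorecards[cid]) for cid in cases
    }
    scores: list[CaseScore] = []
    for tr in iter_study(config, cases, scorecards):
        scores.append(scorers[tr.case_id].score(tr, cohort_stats))
    return scores_to_frame(scores)


# ---------------------------------------------------------------------------
# Reduced-form score-level simulator
# ---------------------------------------------------------------------------


def simulate_scores(config: SimConfig) -> tuple[pd.DataFrame, dict]:
    """Draw a CohortDataset directly from the latent-skill/link model.

    Components are binomial draws on the rubric denominators (4 Ddx
    diagnoses, 18 DxJ items, 4 required tests), the error count is
    binomial over the five error classes with rate logistic(s_err), and
    correctness follows the configured link exactly — so the generating
    coefficients are known without trace mechanics.  Useful for
    parameter-recovery and null-calibration experiments at scale.
    """
    cfg = config.for_cohort()
    G = cfg.gamma
    rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, 424_243)))
    n_sch, n_per, n_cases = cfg.n_schools, cfg.n_students_per_school, cfg.n_cases
    n_students = n_sch * n_per
    f = np.array([cfg.shape(t) for t in range(1, n_cases + 1)])

    school_idx = np.repeat(np.arange(n_sch), n_per)
    eff = rng.normal(0.0, cfg.school_sd, size=(n_sch, len(SKILLS)))

    # AR(1) shared residual, stationary
    resid = np.empty((n_students, n_cases))
    resid[:, 0] = rng.normal(0.0, cfg.sigma_ar, size=n_students)
    innov = cfg.sigma_ar * math.sqrt(1.0 - cfg.rho**2)
    for t in range(1, n_cases):
        resid[:, t] = cfg.rho * resid[:, t - 1] + rng.normal(0.0, innov, size=n_students)

    s = {}
    for ki, k in enumerate(SKILLS):
        # the error dimension is on the observable flag-rate scale here
        mu = cfg.reduced_err_mu if k == "err" else cfg.skill_mu[k]
        beta = cfg.reduced_err_beta if k == "err" else cfg.skill_beta[k]
        a = mu + eff[school_idx, ki] + rng.normal(
            0.0, cfg.skill_sd[k], size=n_students
        )
        sk = a[:, None] + beta * f[None, :]
        s[k] = sk + (resid if k != "err" else -resid)

    expit = lambda x: 1.0 / (1.0 + np.exp(-x))
    ddx = rng.binomial(4, expit(s["ddx"])) / 4.0
    dxj = rng.binomial(18, expit(s["dxj"])) / 18.0
    inv = rng.binomial(4, expit(s["inv"])) / 4.0
    err = rng.binomial(5, expit(s["err"]))
    lin = (
        G["intercept"]
        + G["practice"] * f[None, :]
        + G["dxj"] * 10.0 * dxj
        + G["inv"] * 10.0 * inv
        + G["ddx"] * 10.0 * ddx
        - G["err"] * err
    )
    correct = rng.random(lin.shape) < expit(lin)

    students = [
        f"school{i + 1}-s{j + 1:04d}" for i in range(n_sch) for j in range(n_per)
    ]
    df = pd.DataFrame(
        {
            "student_id": np.repeat(students, n_cases),
            "school_id": np.repeat([f"school{i + 1}" for i in school_idx], n_cases),
            "cohort": cfg.cohort,
            "case_id": [f"case{t:02d}" for _ in students for t in range(1, n_cases + 1)],
            "sequence_index": np.tile(np.arange(1, n_cases + 1), n_students),
            "ddx_pct": 100.0 * ddx.ravel(),
            "dxj_pct": 100.0 * dxj.ravel(),
            "inv_pct": 100.0 * inv.ravel(),
            "error_count": err.ravel(),
            "correct": correct.ravel(),
        }
    )
    return df, cfg.truth()
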