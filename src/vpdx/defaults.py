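"""Default simulator calibration constants.

The synthetic cohort is calibrated so that, under the default study
design (5 schools, 1,000 students, 20 sequenced cases), the cohort-mean
learning curves start and end at the study's reference endpoints:

* Ddx building        79%   -> 90.7%
* diagnostic justification 27% -> 46.5%
* test ordering       46%   -> 64.5%
* cognitive errors    0.87  -> 0.43 per student-case
* misdiagnosis rate   27%   -> 9%

``SKILL_MU`` / ``SKILL_BETA`` (logit intercepts and log-time slopes) and
the link intercept/practice terms below were produced by
:func:`vpdx.calibration.calibrate`, which root-finds them against those
endpoint targets using the trace-level simulator itself; rerun that
routine if the behavior constants or case structure change.  Everything
else here is a behavioral realism constant chosen a priori.
"""

from __future__ import annotations

#: (first-case, last-case) cohort-mean endpoint targets
CALIBRATION_TARGETS: dict[str, tuple[float, float]] = {
    "ddx_pct": (79.0, 90.7),
    "dxj_pct": (27.0, 46.5),
    "inv_pct": (46.0, 64.5),
    "error_count": (0.87, 0.43),
    "misdiagnosis": (0.27, 0.09),
}

#: latent-skill logit intercepts (calibrated)
SKILL_MU: dict[str, float] = {
    "ddx": 1.264,
    "dxj": -0.578,
    "inv": -1.052,
    "err": -5.0,
}

#: per-log(case) learning slopes on the logit scale (calibrated)
SKILL_BETA: dict[str, float] = {
    "ddx": 0.324,
    "dxj": 0.27,
    "inv": 0.267,
    "err": -2.0,
}

#: reduced-form observable error-count logit (per-flag rate on 0..5):
#: endpoints logit(0.87/5) -> logit(0.43/5) over log(1..20); the
#: trace-level error counts emerge from the detectors instead
REDUCED_ERR: dict[str, float] = {"mu": -1.556, "beta": -0.270}

#: between-student skill sd (logit scale)
SKILL_SD: dict[str, float] = {"ddx": 0.6, "dxj": 0.6, "inv": 0.6, "err": 0.5}

#: final-diagnosis link: logit P(correct) = intercept + practice*log(t)
#: + dxj*points + inv*points + ddx*points - err*error_signal, points on 0-10
GAMMA: dict[str, float] = {
    "intercept": -0.731,  # calibrated
    "practice": 0.207,    # calibrated
    "dxj": 0.29,
    "inv": 0.18,
    "ddx": 0.12,
    "err": 0.42,
}

#: behavioral realism constants (set a priori, not calibrated)
BEHAVIOR: dict[str, float] = {
    # DxJ engagement offsets: learners justify their leading diagnosis more
    "b_target": 1.2,
    "b_comp": -0.1,
    # direction-flip / spurious wrong-assignment rates, scaled by (1 - skill)
    "eps_flip": 0.05,
    "eps_wrong": 0.05,
    # anchored learners reinterpret contradicting data as supporting
    "eps_flip_anchor": 0.5,
    # anchored learners sometimes break the anchor at investigations
    "anchor_release": 0.3,
    # hypothesis-driven test ordering
    "b_conf": 0.3,
    "b_disc": -0.3,
    "b_disc_listed": 1.4,
    "p_neutral_test": 0.25,
    "b_bad": -1.2,
    # final-diagnosis recall of a never-listed target
    "b_guess": -1.0,
    # Ddx construction
    "p_distractor": 0.25,
    "p_lead_correct": 0.85,
    "p_entry_history": 0.75,
    # rounds of test ordering
    "p_extra_round": 0.3,
}

#: navigation generator: per-stage base median minutes and view intensity
NAVIGATION: dict[str, float] = {
    "m_history": 7.0,
    "m_physical": 4.2,
    "m_investigations": 4.5,
    "lam_history": 1.4,
    "lam_physical": 1.2,
    "lam_investigations": 0.9,
    "sdlog": 0.5,
}
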