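"""Endpoint calibration of the synthetic-cohort generator.

The generator's defaults are required to reproduce the reference
first-case / last-case cohort means (see
:data:`vpdx.defaults.CALIBRATION_TARGETS`).  Behavioral realism constants
are fixed a priori; this module root-finds only the latent-skill logit
intercepts/slopes and the two free link parameters (intercept, practice
offset) against those targets, using the trace-level simulator itself so
there is no surrogate-model drift.

Each (intercept, slope) pair is solved sequentially: the intercept
against the first-case target (the log-time basis is 0 at t=1), then the
slope against the last-case target.  Cohort-mean endpoints are monotone
in each parameter, and common random numbers across bisection iterations
make the solve deterministic.  Cross-dependencies (e.g. inappropriate
test orders depend on error propensity) are handled by cycling.

Run :func:`calibrate` offline and freeze the result into
``vpdx.defaults``; the shipped constants were produced this way.
"""

from __future__ import annotations

import math

import numpy as np

from . import defaults
from .cases import make_case_library
from .cohort import SimConfig, _rng, residual_path, sample_cohort, simulate_trace
from .scoring import CaseScorer, CohortStats

__all__ = ["endpoint_means", "calibrate"]

_STATS = CohortStats(mean_tests=4.0, mean_rounds=2.0)


def endpoint_means(config: SimConfig, t: int, n_students: int, seed: int) -> dict[str, float]:
    """Cohort means of the calibrated metrics for case position ``t``.

    Simulates ``n_students`` learners playing only the case at sequence
    position ``t`` (the AR(1) residual marginal is stationary, so a
    single draw suffices) and scores them.
    """
    # many small schools so school-effect draws average out of the
    # calibrated constants (the study design itself still uses 5)
    cfg = config.model_copy(deep=True)
    cfg.seed = seed
    cfg.n_schools = 25
    cfg.n_students_per_school = max(1, n_students // 25)
    cases, cards = make_case_library(1)
    case, card = cases["case01"], cards["case01"]
    scorer = CaseScorer(case, card)
    sums = {"ddx_pct": 0.0, "dxj_pct": 0.0, "inv_pct": 0.0, "error_count": 0.0, "misdiagnosis": 0.0}
    profiles = sample_cohort(cfg)
    for p in profiles:
        rng = _rng(cfg.seed, p.school_index, p.student_index, 1000 + t)
        resid = _rng(cfg.seed, p.school_index, p.student_index, 777).normal(0.0, p.sigma_ar)
        tr = simulate_trace(p, case, card, t, cfg, rng, resid)
        sc = scorer.score(tr, _STATS)
        sums["ddx_pct"] += sc.ddx_pct
        sums["dxj_pct"] += sc.dxj_pct
        sums["inv_pct"] += sc.inv_pct
        sums["error_count"] += sc.error_count
        sums["misdiagnosis"] += 0.0 if sc.correct else 1.0
    n = len(profiles)
    return {k: v / n for k, v in sums.items()}


def _bisect(fn, lo: float, hi: float, target: float, increasing: bool, iters: int = 16) -> float:
    """Deterministic bisection of a monotone simulated response."""
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        val = fn(mid)
        high_side = val > target
        if increasing == high_side:
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


def calibrate(
    n_students: int = 5000,
    seed: int = 912_662,
    cycles: int = 3,
    targets: dict[str, tuple[float, float]] | None = None,
    verbose: bool = True,
) -> SimConfig:
    """Solve the calibrated constants; returns the calibrated config."""
    targets = targets or defaults.CALIBRATION_TARGETS
    cfg = SimConfig(seed=seed)
    t_last = cfg.n_cases
    f_last = cfg.shape(t_last)

    skill_metric = {"ddx": "ddx_pct", "dxj": "dxj_pct", "inv": "inv_pct", "err": "error_count"}

    for cycle in range(cycles):
        for skill in ("ddx", "inv", "dxj", "err"):
            metric = skill_metric[skill]
            lo_t, hi_t = targets[metric]

            def at_mu(mu, skill=skill, metric=metric):
                cfg.skill_mu[skill] = mu
                return endpoint_means(cfg, 1, n_students, seed)[metric]

            cfg.skill_mu[skill] = _bisect(at_mu, -5.0, 5.0, lo_t, increasing=True)

            def at_beta(beta, skill=skill, metric=metric):
                cfg.skill_beta[skill] = beta
                return endpoint_means(cfg, t_last, n_students, seed)[metric]

            cfg.skill_beta[skill] = _bisect(at_beta, -2.0, 2.0, hi_t, increasing=True)

        mis_lo, mis_hi = targets["misdiagnosis"]

        def at_g0(g0):
            cfg.gamma["intercept"] = g0
            return endpoint_means(cfg, 1, n_students, seed)["misdiagnosis"]

        cfg.gamma["intercept"] = _bisect(at_g0, -12.0, 4.0, mis_lo, increasing=False)

        def at_delta(d):
            cfg.gamma["practice"] = d
            return endpoint_means(cfg, t_last, n_students, seed)["misdiagnosis"]

        cfg.gamma["practice"] = _bisect(at_delta, -1.0, 2.5, mis_hi, increasing=False)

        if verbose:
            first = endpoint_means(cfg, 1, n_students, seed)
            last = endpoint_means(cfg, t_last, n_students, seed)
            print(f"cycle {cycle + 1}:")
            for k in first:
                print(f"  {k:12s} {first[k]:7.3f} -> {last[k]:7.3f}  (target {targets[k]})")
    if verbose:
        print("skill_mu  ", {k: round(v, 3) for k, v in cfg.skill_mu.items()})
        print("skill_beta", {k: round(v, 3) for k, v in cfg.skill_beta.items()})
        print("gamma     ", {k: round(v, 3) for k, v in cfg.gamma.items()})
    return cfg


if __name__ == "__main__":  # pragma: no cover
    calibrate()
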