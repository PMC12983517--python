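"""Reference study-design summary the synthetic cohort emulates.

These are the headline counts and learning-curve endpoints of the
multi-school virtual-patient clinical-reasoning curriculum the simulator
is calibrated against.  The helper functions compute the derived
fractions and changes from the raw counts, so every reported summary is
an arithmetic consequence of the primitive figures rather than a quoted
number.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["ReferenceStudy", "REFERENCE", "percent_change", "fold_change"]


def percent_change(start: float, end: float) -> float:
    """Relative change from start to end, in percent."""
    return (end - start) / start * 100.0


def fold_change(start: float, end: float) -> float:
    """start / end — e.g. a 27% -> 9% misdiagnosis rate is a 3-fold drop."""
    return start / end


@dataclass(frozen=True)
class ReferenceStudy:
    """Primitive counts and endpoints of the emulated study."""

    n_students_consented: int = 1_066
    n_students_eligible: int = 1_269
    n_schools: int = 5
    n_cases_completed: int = 12_400
    n_misdiagnosed: int = 2_494
    max_cases_per_student: int = 20
    mean_cases_per_student: float = 13.6
    datapoints_per_case: float = 125.0

    # first-case -> last-case cohort means (the calibration endpoints)
    ddx_pct_start: float = 79.0
    ddx_pct_end: float = 90.7
    dxj_pct_start: float = 27.0
    dxj_pct_end: float = 46.5
    inv_pct_start: float = 46.0
    inv_pct_end: float = 64.5
    errors_start: float = 0.87
    errors_end: float = 0.43
    misdx_start: float = 0.27
    misdx_end: float = 0.09

    # -- derived quantities -------------------------------------------

    def misdiagnosis_rate(self) -> float:
        """Fraction of completed cases with an incorrect final diagnosis."""
        return self.n_misdiagnosed / self.n_cases_completed

    def consent_rate(self) -> float:
        return self.n_students_consented / self.n_students_eligible

    def total_datapoints(self) -> float:
        return self.n_cases_completed * self.datapoints_per_case

    def dxj_gain_pct(self) -> float:
        return percent_change(self.dxj_pct_start, self.dxj_pct_end)

    def inv_gain_pct(self) -> float:
        return percent_change(self.inv_pct_start, self.inv_pct_end)

    def error_fold_reduction(self) -> float:
        return fold_change(self.errors_start, self.errors_end)

    def misdx_fold_reduction(self) -> float:
        return fold_change(self.misdx_start, self.misdx_end)


REFERENCE = ReferenceStudy()
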