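"""Wear-day classification, the patient inclusion rule, and completeness reports.

A study day is FULL when its recorded step count exceeds 100, PARTIAL
when a count of at most 100 was recorded (0 included), and NONE when
no count was recorded at all.  Patients are adequate when they have at
least three FULL days in each of the two phases.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional, Union

from .cohort import (
    Cohort,
    StepSeries,
    ValidationError,
    phase_days,
    phase_length,
    step_series_of,
)
from .util import round_half_up

#: FULL requires strictly more steps than this.
FULL_THRESHOLD = 100

#: FULL days required in each phase for a patient to count as adequate.
MIN_FULL_DAYS = 3


class DayClass(enum.Enum):
    FULL = "full"
    PARTIAL = "partial"
    NONE = "none"


def classify_day(steps: Optional[int]) -> DayClass:
    """Classify one study day from its recorded step count (None = no recording)."""
    if steps is None:
        return DayClass.NONE
    if not isinstance(steps, int) or isinstance(steps, bool):
        raise ValidationError(f"steps must be an integer or None, got {steps!r}")
    if steps < 0:
        raise ValidationError(f"steps must be non-negative, got {steps}")
    return DayClass.FULL if steps > FULL_THRESHOLD else DayClass.PARTIAL


def count_full_days(series: StepSeries, phase: str) -> int:
    return sum(
        1
        for d in phase_days(phase)
        if classify_day(series.records.get(d)) is DayClass.FULL
    )


def is_adequate(series: StepSeries) -> bool:
    """True iff the series has >= 3 FULL days in both phases."""
    return (
        count_full_days(series, "pre") >= MIN_FULL_DAYS
        and count_full_days(series, "post") >= MIN_FULL_DAYS
    )


@dataclass(frozen=True)
class ExclusionRecord:
    patient_id: str
    failed_phases: tuple[str, ...]


def filter_cohort(cohort: Cohort) -> tuple[Cohort, list[ExclusionRecord]]:
    """Split a cohort into adequate patients and an exclusion log.

    A patient with no step series at all fails both phases.  Idempotent:
    filtering an already-filtered cohort changes nothing.
    """
    exclusions: list[ExclusionRecord] = []
    keep: set[str] = set()
    for meta in cohort.patients:
        series = cohort.step_series(meta.patient_id)
        if series is None:
            series = StepSeries(meta.patient_id, {})
        failed = tuple(
            ph for ph in ("pre", "post") if count_full_days(series, ph) < MIN_FULL_DAYS
        )
        if failed:
            exclusions.append(ExclusionRecord(meta.patient_id, failed))
        else:
            keep.add(meta.patient_id)
    included = Cohort(
        patients=[p for p in cohort.patients if p.patient_id in keep],
        steps=[s for s in cohort.steps if s.patient_id in keep],
        msas_pre={k: v for k, v in cohort.msas_pre.items() if k in keep},
        msas_post={k: v for k, v in cohort.msas_post.items() if k in keep},
    )
    return included, exclusions


@dataclass
class CompletenessReport:
    """Cohort-level wear completeness for one phase.

    ``pct_partial`` and ``pct_none`` are the raw percentages rounded
    half-up to integers; ``pct_full`` is their complement to 100 so the
    three printed figures always total 100 (see the module notes on
    rounding in the README).
    """

    phase: str
    n_patients: int
    n_days_total: int
    n_full: int
    n_partial: int
    n_none: int
    pct_full: int
    pct_partial: int
    pct_none: int
    mean_full_days_per_patient: int
    full_days_by_patient: dict[str, int] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "phase": self.phase,
            "n_patients": self.n_patients,
            "n_days_total": self.n_days_total,
            "n_full": self.n_full,
            "n_partial": self.n_partial,
            "n_none": self.n_none,
            "pct_full": self.pct_full,
            "pct_partial": self.pct_partial,
            "pct_none": self.pct_none,
            "mean_full_days_per_patient": self.mean_full_days_per_patient,
            "full_days_by_patient": dict(self.full_days_by_patient),
        }


def completeness_report(
    cohort: Union[Cohort, list[StepSeries]], phase: str
) -> CompletenessReport:
    """Count FULL / PARTIAL / NONE days over every patient supplied.

    The denominator is n_patients x phase length; patients are NOT
    filtered for adequacy first, so the totals reflect the enrolled
    tracker-wearing cohort.
    """
    series_list = step_series_of(cohort)
    if not series_list:
        raise ValidationError("completeness report requires a non-empty cohort")
    days = phase_days(phase)
    n_full = n_partial = 0
    by_patient: dict[str, int] = {}
    for series in series_list:
        full_here = 0
        for d in days:
            cls = classify_day(series.records.get(d))
            if cls is DayClass.FULL:
                full_here += 1
            elif cls is DayClass.PARTIAL:
                n_partial += 1
        n_full += full_here
        by_patient[series.patient_id] = full_here
    n_patients = len(series_list)
    n_days_total = n_patients * phase_length(phase)
    n_none = n_days_total - n_full - n_partial
    pct_partial = round_half_up(100.0 * n_partial / n_days_total)
    pct_none = round_half_up(100.0 * n_none / n_days_total)
    pct_full = 100 - pct_partial - pct_none
    return CompletenessReport(
        phase=phase,
        n_patients=n_patients,
        n_days_total=n_days_total,
        n_full=n_full,
        n_partial=n_partial,
        n_none=n_none,
        pct_full=pct_full,
        pct_partial=pct_partial,
        pct_none=pct_none,
        mean_full_days_per_patient=round_half_up(n_full / n_patients),
        full_days_by_patient=by_patient,
    )
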