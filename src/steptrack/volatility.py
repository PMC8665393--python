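"""Day-over-day step volatility and its annualized summary.

The daily statistic is the relative change between strictly consecutive
recorded days:

    sigma(t) = (S(t) - S(t-1)) / S(t-1)

Pairs that span a gap, include an unrecorded day, or divide by a
zero-step previous day are skipped (and logged), never bridged.  The
per-patient summary is the sample standard deviation (divisor n-1) of
the sigma values scaled by sqrt(365); "annualized variance" is its
square.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Union

from .cohort import Cohort, StepSeries, phase_days, step_series_of
from .util import Absent

ANNUALIZATION_DAYS = 365.0


@dataclass
class VolatilitySeries:
    """Per-day sigma(t) for one patient within one phase.

    ``values`` is keyed by the later day t of each usable pair;
    ``skipped`` records pairs that could not be used and why.
    """

    patient_id: str
    phase: str
    values: dict[int, float] = field(default_factory=dict)
    n_usable_pairs: int = 0
    skipped: list[tuple[int, str]] = field(default_factory=list)


@dataclass
class AnnualizedVolatility:
    patient_id: str
    phase: str
    sigma_daily_sd: float
    annualized_vol: float
    annualized_var: float
    n: int


def daily_volatility(series: StepSeries, phase: str) -> VolatilitySeries:
    """sigma(t) over every usable consecutive-day pair of a phase."""
    days = phase_days(phase)
    values: dict[int, float] = {}
    skipped: list[tuple[int, str]] = []
    for prev_day, day in zip(days, days[1:]):
        prev = series.records.get(prev_day)
        cur = series.records.get(day)
        if prev is None or cur is None:
            skipped.append((day, "missing day"))
            continue
        if prev == 0:
            skipped.append((day, "zero steps on previous day"))
            continue
        values[day] = (cur - prev) / prev
    return VolatilitySeries(
        patient_id=series.patient_id,
        phase=phase,
        values=values,
        n_usable_pairs=len(values),
        skipped=skipped,
    )


def annualized_volatility(
    series: StepSeries, phase: str
) -> Union[AnnualizedVolatility, Absent]:
    """Annualized dispersion of sigma(t); Absent below 2 usable pairs."""
    vol = daily_volatility(series, phase)
    sigmas = list(vol.values.values())
    n = len(sigmas)
    if n < 2:
        return Absent("insufficient data: fewer than 2 usable day pairs")
    mean = sum(sigmas) / n
    sd = math.sqrt(sum((s - mean) ** 2 for s in sigmas) / (n - 1))
    ann = sd * math.sqrt(ANNUALIZATION_DAYS)
    return AnnualizedVolatility(
        patient_id=series.patient_id,
        phase=phase,
        sigma_daily_sd=sd,
        annualized_vol=ann,
        annualized_var=ann * ann,
        n=n,
    )


@dataclass(frozen=True)
class DirectionCounts:
    n_up: int
    n_down: int
    n_flat: int

    @property
    def total(self) -> int:
        return self.n_up + self.n_down + self.n_flat


def direction_day_counts(cohort, phase: str) -> DirectionCounts:
    """Pooled counts of days with increased / decreased / unchanged steps."""
    n_up = n_down = n_flat = 0
    for series in step_series_of(cohort):
        for sigma in daily_volatility(series, phase).values.values():
            if sigma > 0:
                n_up += 1
            elif sigma < 0:
                n_down += 1
            else:
                n_flat += 1
    return DirectionCounts(n_up, n_down, n_flat)


@dataclass(frozen=True)
class PrePostChange:
    pre_var: float
    post_var: float

    @property
    def increased(self) -> bool:
        return self.post_var > self.pre_var


@dataclass
class ChangeSummary:
    """Per-patient annualized-variance change, plus counts by ECOG group."""

    per_patient: dict[str, PrePostChange] = field(default_factory=dict)
    excluded: dict[str, str] = field(default_factory=dict)
    by_ecog: dict[int, dict[str, int]] = field(default_factory=dict)

    @property
    def n_increased(self) -> int:
        return sum(1 for c in self.per_patient.values() if c.increased)

    @property
    def n_decreased_or_flat(self) -> int:
        return len(self.per_patient) - self.n_increased


def annualized_change_summary(cohort: Cohort) -> ChangeSummary:
    """Compare each patient's pre vs post annualized variance."""
    summary = ChangeSummary()
    for meta in cohort.patients:
        series = cohort.step_series(meta.patient_id)
        if series is None:
            summary.excluded[meta.patient_id] = "no step series"
            continue
        pre = annualized_volatility(series, "pre")
        post = annualized_volatility(series, "post")
        if isinstance(pre, Absent):
            summary.excluded[meta.patient_id] = f"pre: {pre.reason}"
            continue
        if isinstance(post, Absent):
            summary.excluded[meta.patient_id] = f"post: {post.reason}"
            continue
        change = PrePostChange(pre_var=pre.annualized_var, post_var=post.annualized_var)
        summary.per_patient[meta.patient_id] = change
        group = summary.by_ecog.setdefault(meta.ecog, {"n_increased": 0, "n_total": 0})
        group["n_total"] += 1
        if change.increased:
            group["n_increased"] += 1
    return summary
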