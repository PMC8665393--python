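"""Cohort-level statistics: phase summaries, correlation matrices,
per-day correlation profiles, and group comparisons.

Phase summaries (mean / median / max / min daily steps) are computed
over FULL days only; days with at most 100 recorded steps are treated
as non-wear.  Correlations default to Pearson; two-group location
comparisons use the Mann-Whitney U test (exact when both groups have
at most 20 observations and there are no ties) alongside a Spearman
rank correlation for ordinal trends.  All p-values are two-sided and
uncorrected.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np
from scipy import stats as sps

from .adherence import FULL_THRESHOLD
from .cohort import Cohort, StepSeries, phase_days
from .msas import SUBSCALES, ImprovementResult, msas_improvement, score_msas
from .util import Absent

SUMMARY_STATS = ("mean", "median", "max", "min")

EXACT_MWU_MAX_N = 20


class InsufficientDataError(ValueError):
    pass


@dataclass(frozen=True)
class PhaseSummary:
    patient_id: str
    phase: str
    mean: float
    median: float
    max: float
    min: float
    n_days_used: int

    def stat(self, name: str) -> float:
        if name not in SUMMARY_STATS:
            raise ValueError(f"unknown summary statistic {name!r}")
        return getattr(self, name)


@dataclass(frozen=True)
class CorrelationResult:
    statistic: str  # pearson | spearman
    estimate: float
    p_value: float
    n: int


@dataclass(frozen=True)
class GroupStats:
    label: str
    n: int
    mean: float
    median: float


@dataclass
class GroupComparison:
    grouping: str
    groups: list[GroupStats]
    test: Optional[str] = None
    statistic: Optional[float] = None
    p_value: Optional[float] = None
    effect_size: Optional[float] = None  # rank-biserial for two-group MWU


def full_day_steps(series: StepSeries, phase: str) -> list[int]:
    """Step counts of the FULL days of a phase, in day order."""
    return [
        v
        for d in phase_days(phase)
        if (v := series.records.get(d)) is not None and v > FULL_THRESHOLD
    ]


def phase_summary(series: StepSeries, phase: str) -> Union[PhaseSummary, Absent]:
    """Order statistics of a patient's FULL-day step counts in a phase."""
    values = full_day_steps(series, phase)
    if not values:
        return Absent("no full days in phase")
    return PhaseSummary(
        patient_id=series.patient_id,
        phase=phase,
        mean=sum(values) / len(values),
        median=float(statistics.median(values)),
        max=float(max(values)),
        min=float(min(values)),
        n_days_used=len(values),
    )


def _summaries(cohort: Cohort, phase: str) -> dict[str, PhaseSummary]:
    out = {}
    for series in cohort.steps:
        s = phase_summary(series, phase)
        if not isinstance(s, Absent):
            out[series.patient_id] = s
    return out


def _pearson(x: np.ndarray, y: np.ndarray) -> Union[CorrelationResult, Absent]:
    if len(x) < 3:
        return Absent("n<3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return Absent("zero variance")
    r = sps.pearsonr(x, y)
    return CorrelationResult("pearson", float(r.statistic), float(r.pvalue), len(x))


def prepost_summary_correlation(
    cohort: Cohort,
) -> dict[tuple[str, str], CorrelationResult]:
    """4x4 across-patient Pearson matrix: post statistic i vs pre statistic j.

    Keys are (post_stat, pre_stat).  Patients lacking either phase
    summary are excluded pairwise-complete (the same n for all cells).
    """
    pre = _summaries(cohort, "pre")
    post = _summaries(cohort, "post")
    ids = [pid for pid in pre if pid in post]
    if len(ids) < 3:
        raise InsufficientDataError(
            f"insufficient patients: need >=3 with both phase summaries, got {len(ids)}"
        )
    matrix: dict[tuple[str, str], CorrelationResult] = {}
    for i in SUMMARY_STATS:
        x = np.array([post[pid].stat(i) for pid in ids], dtype=float)
        for j in SUMMARY_STATS:
            y = np.array([pre[pid].stat(j) for pid in ids], dtype=float)
            result = _pearson(x, y)
            if isinstance(result, Absent):
                result = CorrelationResult("pearson", float("nan"), float("nan"), len(ids))
            matrix[(i, j)] = result
    return matrix


def daywise_correlation(
    cohort: Cohort, phase: str, statistic: str = "mean"
) -> dict[int, Union[CorrelationResult, Absent]]:
    """Per study day: correlation of that day's steps with each patient's
    opposite-phase summary statistic.

    Interpretation note: the correlated pair is (steps on day d of
    ``phase``, patient-level ``statistic`` over the other phase's FULL
    days); days recorded for fewer than 3 patients are Absent.
    """
    if statistic not in SUMMARY_STATS:
        raise ValueError(f"unknown summary statistic {statistic!r}")
    other = "post" if phase == "pre" else "pre"
    summaries = _summaries(cohort, other)
    out: dict[int, Union[CorrelationResult, Absent]] = {}
    for day in phase_days(phase):
        xs, ys = [], []
        for series in cohort.steps:
            v = series.records.get(day)
            if v is None or series.patient_id not in summaries:
                continue
            xs.append(float(v))
            ys.append(summaries[series.patient_id].stat(statistic))
        out[day] = _pearson(np.array(xs), np.array(ys))
    return out


def _mannwhitney(a: list[float], b: list[float]) -> tuple[float, float]:
    has_ties = len(set(a) | set(b)) < len(a) + len(b)
    method = (
        "exact"
        if max(len(a), len(b)) <= EXACT_MWU_MAX_N and not has_ties
        else "asymptotic"
    )
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


@dataclass
class EcogStepResult:
    comparison: GroupComparison
    correlation: Union[CorrelationResult, Absent]


def steps_vs_ecog(cohort: Cohort, phase: str) -> EcogStepResult:
    """Per-ECOG-group step summaries, a two-group Mann-Whitney test, and
    a Spearman correlation of ECOG against per-patient phase-mean steps."""
    by_group: dict[int, list[float]] = {}
    ecogs, means = [], []
    summaries = _summaries(cohort, phase)
    for meta in cohort.patients:
        s = summaries.get(meta.patient_id)
        if s is None:
            continue
        by_group.setdefault(meta.ecog, []).append(s.mean)
        ecogs.append(meta.ecog)
        means.append(s.mean)
    groups = [
        GroupStats(
            label=str(level),
            n=len(vals),
            mean=sum(vals) / len(vals),
            median=float(statistics.median(vals)),
        )
        for level, vals in sorted(by_group.items())
    ]
    comparison = GroupComparison(grouping="ecog", groups=groups)
    if len(by_group) == 2:
        (a, b) = (vals for _, vals in sorted(by_group.items()))
        stat, p = _mannwhitney(a, b)
        comparison.test = "mannwhitneyu"
        comparison.statistic = stat
        comparison.p_value = p
        comparison.effect_size = 2.0 * stat / (len(a) * len(b)) - 1.0
    if len(set(ecogs)) < 2:
        correlation: Union[CorrelationResult, Absent] = Absent(
            "single ECOG group: correlation undefined"
        )
    else:
        rho = sps.spearmanr(ecogs, means)
        correlation = CorrelationResult(
            "spearman", float(rho.statistic), float(rho.pvalue), len(ecogs)
        )
    return EcogStepResult(comparison=comparison, correlation=correlation)


@dataclass(frozen=True)
class ImprovementGroupRow:
    improved: bool
    n: int
    pre_mean_steps: float
    post_mean_steps: float


def improvement_step_comparison(
    cohort: Cohort, subscale: str
) -> dict[str, Union[ImprovementGroupRow, Absent]]:
    """Mean daily steps (both phases) for patients whose subscale score
    improved between visits versus those whose did not."""
    if subscale not in SUBSCALES:
        raise ValueError(f"unknown subscale {subscale!r}")
    pre_sum = _summaries(cohort, "pre")
    post_sum = _summaries(cohort, "post")
    partitions: dict[bool, list[tuple[float, float]]] = {True: [], False: []}
    for meta in cohort.patients:
        pid = meta.patient_id
        if pid not in cohort.msas_pre or pid not in cohort.msas_post:
            continue
        if pid not in pre_sum or pid not in post_sum:
            continue
        change = msas_improvement(
            score_msas(cohort.msas_pre[pid]), score_msas(cohort.msas_post[pid])
        )[subscale]
        if isinstance(change, Absent):
            continue
        partitions[change.improved].append((pre_sum[pid].mean, post_sum[pid].mean))
    out: dict[str, Union[ImprovementGroupRow, Absent]] = {}
    for improved, label in ((True, "improved"), (False, "not_improved")):
        pairs = partitions[improved]
        if not pairs:
            out[label] = Absent("empty partition")
            continue
        out[label] = ImprovementGroupRow(
            improved=improved,
            n=len(pairs),
            pre_mean_steps=sum(p for p, _ in pairs) / len(pairs),
            post_mean_steps=sum(q for _, q in pairs) / len(pairs),
        )
    return out


@dataclass
class AgeSplitResult:
    threshold: float
    phase: str
    younger: Union[GroupStats, Absent]
    older: Union[GroupStats, Absent]
    p_value: Union[float, Absent] = Absent("not computed")


def age_split_comparison(
    cohort: Cohort, phase: str, threshold: float = 60.0
) -> AgeSplitResult:
    """Median of per-patient phase-median steps for age < threshold vs >=."""
    young, old = [], []
    summaries = _summaries(cohort, phase)
    for meta in cohort.patients:
        s = summaries.get(meta.patient_id)
        if s is None:
            continue
        (young if meta.age < threshold else old).append(s.median)
    result = AgeSplitResult(
        threshold=threshold,
        phase=phase,
        younger=_age_group(f"<{threshold:g}", young),
        older=_age_group(f">={threshold:g}", old),
    )
    if young and old:
        _, p = _mannwhitney(young, old)
        result.p_value = p
    else:
        result.p_value = Absent("one age group is empty")
    return result


def _age_group(label: str, values: list[float]) -> Union[GroupStats, Absent]:
    if not values:
        return Absent("empty group")
    return GroupStats(
        label=label,
        n=len(values),
        mean=sum(values) / len(values),
        median=float(statistics.median(values)),
    )
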