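"""Core data types, study-day timeline conventions, and tabular I/O.

Study days are integers relative to the first treatment administration
(day 0).  The baseline window spans days -7..-1, the follow-up window
days 1..14; day 0 (the clinic/infusion day) belongs to neither window.

A step record can be present (a non-negative count, 0 included) or an
explicit absent marker (``None``): a day with no recording is a distinct
state from a day with zero steps, and every transformation in the
package preserves that distinction.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

DAY_MIN = -7
DAY_MAX = 14
PRE_DAYS: tuple[int, ...] = tuple(range(-7, 0))
POST_DAYS: tuple[int, ...] = tuple(range(1, 15))
PHASES = ("pre", "post")

CHEMO_TYPES = ("adjuvant", "neoadjuvant", "metastatic")
SEXES = ("M", "F")


class CohortError(Exception):
    """Base class for data-model errors."""


class ValidationError(CohortError):
    """A value violates a domain invariant."""


class ParseError(CohortError):
    """A tabular file could not be parsed; carries the offending line number."""

    def __init__(self, message: str, line: Optional[int] = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class DuplicateRecordError(ValidationError):
    """Two rows describe the same (patient, study day)."""


def phase_days(phase: str) -> tuple[int, ...]:
    """Study days belonging to a phase ('pre' -> -7..-1, 'post' -> 1..14)."""
    if phase == "pre":
        return PRE_DAYS
    if phase == "post":
        return POST_DAYS
    raise ValidationError(f"unknown phase {phase!r}; expected 'pre' or 'post'")


def phase_length(phase: str) -> int:
    return len(phase_days(phase))


def validate_study_day(day: int) -> int:
    if not isinstance(day, int) or isinstance(day, bool):
        raise ValidationError(f"study day must be an integer, got {day!r}")
    if not DAY_MIN <= day <= DAY_MAX:
        raise ValidationError(
            f"study day {day} outside the [{DAY_MIN}, {DAY_MAX}] window"
        )
    return day


@dataclass(frozen=True)
class PatientMeta:
    """Baseline metadata for one patient."""

    patient_id: str
    ecog: int
    age: float
    sex: str
    chemo_type: str

    def __post_init__(self) -> None:
        if not self.patient_id:
            raise ValidationError("patient_id must be non-empty")
        if not isinstance(self.ecog, int) or not 0 <= self.ecog <= 5:
            raise ValidationError(
                f"ecog must be an integer in [0, 5], got {self.ecog!r}"
            )
        if not self.age > 0:
            raise ValidationError(f"age must be positive, got {self.age!r}")
        if self.sex not in SEXES:
            raise ValidationError(f"sex must be one of {SEXES}, got {self.sex!r}")
        if self.chemo_type not in CHEMO_TYPES:
            raise ValidationError(
                f"chemo_type must be one of {CHEMO_TYPES}, got {self.chemo_type!r}"
            )


@dataclass
class StepSeries:
    """One patient's daily step counts on the study-day axis.

    ``records`` maps study day -> step count, or -> ``None`` for a day
    explicitly known to have no recording.  Days missing from the
    mapping are equally treated as unrecorded by every consumer; the
    explicit marker exists so files can round-trip absent days.
    """

    patient_id: str
    records: dict[int, Optional[int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.patient_id:
            raise ValidationError("patient_id must be non-empty")
        for day, steps in self.records.items():
            validate_study_day(day)
            if steps is not None:
                if not isinstance(steps, int) or isinstance(steps, bool):
                    raise ValidationError(
                        f"steps on day {day} must be an integer, got {steps!r}"
                    )
                if steps < 0:
                    raise ValidationError(
                        f"steps on day {day} must be non-negative, got {steps}"
                    )

    def get(self, day: int) -> Optional[int]:
        """Recorded steps on a day, or None when there is no recording."""
        return self.records.get(day)

    def recorded_days(self, phase: str) -> list[int]:
        return [d for d in phase_days(phase) if self.records.get(d) is not None]

    def phase_values(self, phase: str) -> dict[int, int]:
        """day -> steps for recorded days of a phase."""
        out = {}
        for d in phase_days(phase):
            v = self.records.get(d)
            if v is not None:
                out[d] = v
        return out


@dataclass
class Cohort:
    """The full study dataset: metadata, wear logs, and questionnaires."""

    patients: list[PatientMeta] = field(default_factory=list)
    steps: list[StepSeries] = field(default_factory=list)
    msas_pre: dict[str, "object"] = field(default_factory=dict)
    msas_post: dict[str, "object"] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [p.patient_id for p in self.patients]
        if len(ids) != len(set(ids)):
            raise ValidationError("duplicate patient_id in metadata")
        known = set(ids)
        series_ids = [s.patient_id for s in self.steps]
        if len(series_ids) != len(set(series_ids)):
            raise ValidationError("more than one step series for a patient")
        for sid in series_ids:
            if sid not in known:
                raise ValidationError(f"step series for unknown patient {sid!r}")
        for label, responses in (("msas_pre", self.msas_pre), ("msas_post", self.msas_post)):
            for pid in responses:
                if pid not in known:
                    raise ValidationError(f"{label} response for unknown patient {pid!r}")

    @property
    def patient_ids(self) -> list[str]:
        return [p.patient_id for p in self.patients]

    def meta(self, patient_id: str) -> PatientMeta:
        for p in self.patients:
            if p.patient_id == patient_id:
                return p
        raise KeyError(patient_id)

    def step_series(self, patient_id: str) -> Optional[StepSeries]:
        for s in self.steps:
            if s.patient_id == patient_id:
                return s
        return None

    def __len__(self) -> int:
        return len(self.patients)


def step_series_of(cohort_or_series) -> list[StepSeries]:
    """Accept a Cohort or a plain sequence of StepSeries."""
    if isinstance(cohort_or_series, Cohort):
        return list(cohort_or_series.steps)
    return list(cohort_or_series)


# ---------------------------------------------------------------------------
# Tabular readers / writers.  Dialect: comma-separated, UTF-8, header row
# required; an empty steps field encodes a day with no recording.
# ---------------------------------------------------------------------------

STEPS_COLUMNS = ("patient_id", "study_day", "steps")
PATIENTS_COLUMNS = ("patient_id", "ecog", "age", "sex", "chemo_type")


def _open_reader(path: Path, required: Sequence[str]) -> tuple[csv.DictReader, "object"]:
    handle = open(path, newline="", encoding="utf-8")
    reader = csv.DictReader(handle)
    if reader.fieldnames is None:
        return reader, handle  # empty file: caller yields nothing
    missing = [c for c in required if c not in reader.fieldnames]
    if missing:
        handle.close()
        raise ParseError(f"missing required column(s) {missing} in {path}", line=1)
    return reader, handle


def read_step_log(path) -> list[StepSeries]:
    """Read a long-format wear log (patient_id, study_day, steps).

    Blank ``steps`` fields become explicit absent days.  Duplicate
    (patient, day) rows and out-of-range study days are rejected.
    """
    path = Path(path)
    reader, handle = _open_reader(path, STEPS_COLUMNS)
    per_patient: dict[str, dict[int, Optional[int]]] = {}
    order: list[str] = []
    try:
        for lineno, row in enumerate(reader, start=2):
            pid = (row.get("patient_id") or "").strip()
            if not pid:
                raise ParseError("empty patient_id", line=lineno)
            raw_day = (row.get("study_day") or "").strip()
            try:
                day = int(raw_day)
            except ValueError:
                raise ParseError(f"study_day {raw_day!r} is not an integer", line=lineno)
            try:
                validate_study_day(day)
            except ValidationError as exc:
                raise ValidationError(f"line {lineno}: {exc}") from exc
            raw_steps = (row.get("steps") or "").strip()
            if raw_steps == "":
                steps: Optional[int] = None
            else:
                try:
                    steps = int(raw_steps)
                except ValueError:
                    raise ParseError(
                        f"steps {raw_steps!r} is not an integer", line=lineno
                    )
                if steps < 0:
                    raise ValidationError(
                        f"line {lineno}: steps must be non-negative, got {steps}"
                    )
            if pid not in per_patient:
                per_patient[pid] = {}
                order.append(pid)
            if day in per_patient[pid]:
                raise DuplicateRecordError(
                    f"line {lineno}: duplicate record for patient {pid!r}, day {day}"
                )
            per_patient[pid][day] = steps
    finally:
        handle.close()
    return [StepSeries(pid, per_patient[pid]) for pid in order]


def read_patient_meta(path) -> list[PatientMeta]:
    """Read patient metadata (patient_id, ecog, age, sex, chemo_type)."""
    path = Path(path)
    reader, handle = _open_reader(path, PATIENTS_COLUMNS)
    out: list[PatientMeta] = []
    seen: set[str] = set()
    try:
        for lineno, row in enumerate(reader, start=2):
            pid = (row.get("patient_id") or "").strip()
            if pid in seen:
                raise DuplicateRecordError(
                    f"line {lineno}: duplicate patient_id {pid!r}"
                )
            seen.add(pid)
            try:
                meta = PatientMeta(
                    patient_id=pid,
                    ecog=int(row["ecog"]),
                    age=float(row["age"]),
                    sex=(row.get("sex") or "").strip(),
                    chemo_type=(row.get("chemo_type") or "").strip(),
                )
            except (ValueError, KeyError) as exc:
                raise ParseError(f"malformed metadata row: {exc}", line=lineno)
            except ValidationError as exc:
                raise ValidationError(f"line {lineno}: {exc}") from exc
            out.append(meta)
    finally:
        handle.close()
    return out


def write_step_log(series_list: Iterable[StepSeries], path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle)
        writer.writerow(STEPS_COLUMNS)
        for series in series_list:
            for day in sorted(series.records):
                steps = series.records[day]
                writer.writerow(
                    [series.patient_id, day, "" if steps is None else steps]
                )


def write_patient_meta(patients: Iterable[PatientMeta], path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle)
        writer.writerow(PATIENTS_COLUMNS)
        for p in patients:
            age = int(p.age) if float(p.age).is_integer() else p.age
            writer.writerow([p.patient_id, p.ecog, age, p.sex, p.chemo_type])


def write_cohort(cohort: Cohort, directory) -> dict[str, Path]:
    """Write a cohort as steps.csv / patients.csv / msas_pre.csv / msas_post.csv.

    The produced files round-trip exactly through :func:`read_cohort`,
    including the distinction between absent days and zero-step days.
    """
    from . import msas as _msas  # deferred: avoids a cycle at import time

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "patients": directory / "patients.csv",
        "steps": directory / "steps.csv",
    }
    write_patient_meta(cohort.patients, paths["patients"])
    write_step_log(cohort.steps, paths["steps"])
    for label, responses in (("msas_pre", cohort.msas_pre), ("msas_post", cohort.msas_post)):
        if responses:
            paths[label] = directory / f"{label}.csv"
            _msas.write_msas_responses(responses.values(), paths[label])
    return paths


def read_cohort(directory) -> Cohort:
    """Read a cohort directory written by :func:`write_cohort`."""
    from . import msas as _msas

    directory = Path(directory)
    patients = read_patient_meta(directory / "patients.csv")
    steps_path = directory / "steps.csv"
    steps = read_step_log(steps_path) if steps_path.exists() else []
    msas_pre: dict[str, object] = {}
    msas_post: dict[str, object] = {}
    pre_path = directory / "msas_pre.csv"
    post_path = directory / "msas_post.csv"
    if pre_path.exists():
        msas_pre = _msas.read_msas_responses(pre_path)
    if post_path.exists():
        msas_post = _msas.read_msas_responses(post_path)
    return Cohort(patients=patients, steps=steps, msas_pre=msas_pre, msas_post=msas_post)
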