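"""Scoring of the 32-item short-form symptom questionnaire.

Four derived scores, each an arithmetic mean of its member items:

* GDI   -- 10 items: the 4 psychological-frequency items plus 6 physical
  distress items.
* PHYS  -- 12 physical items.
* PSYCH -- 6 psychological items.
* TMSAS -- all 32 items.

Item values live on a common 0..4 range; for frequency items a 0
encodes "not present".  A subscale is prorated over observed items when
at least half of its members are present, otherwise reported absent.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional

import yaml

from .cohort import ParseError, ValidationError
from .util import Absent

SUBSCALES = ("gdi", "phys", "psych", "tmsas")


@dataclass(frozen=True)
class MsasItemCatalog:
    """The canonical item vocabulary and subscale memberships."""

    severity_items: tuple[str, ...]
    frequency_items: tuple[str, ...]
    gdi_items: tuple[str, ...]
    phys_items: tuple[str, ...]
    psych_items: tuple[str, ...]
    aliases: dict[str, str] = field(default_factory=dict, hash=False, compare=False)

    def __post_init__(self) -> None:
        items = set(self.all_items)
        if len(items) != len(self.all_items):
            raise ValidationError("duplicate item names in catalog")
        for name, members in (
            ("gdi", self.gdi_items),
            ("phys", self.phys_items),
            ("psych", self.psych_items),
        ):
            unknown = set(members) - items
            if unknown:
                raise ValidationError(f"{name} members not in catalog: {sorted(unknown)}")

    @property
    def all_items(self) -> tuple[str, ...]:
        return self.severity_items + self.frequency_items

    def members(self, subscale: str) -> tuple[str, ...]:
        if subscale == "gdi":
            return self.gdi_items
        if subscale == "phys":
            return self.phys_items
        if subscale == "psych":
            return self.psych_items
        if subscale == "tmsas":
            return self.all_items
        raise ValidationError(f"unknown subscale {subscale!r}")

    def canonical_name(self, column: str) -> Optional[str]:
        """Map a column header to a canonical item name, or None."""
        key = column.strip()
        if key in self.all_items:
            return key
        low = key.lower()
        if low in self.aliases:
            return self.aliases[low]
        snake = low.replace(" ", "_").replace("-", "_")
        if snake in self.all_items:
            return snake
        return None


@lru_cache(maxsize=1)
def default_catalog() -> MsasItemCatalog:
    raw = yaml.safe_load(
        resources.files("steptrack.data").joinpath("msas_items.yaml").read_text()
    )
    return MsasItemCatalog(
        severity_items=tuple(raw["severity_items"]),
        frequency_items=tuple(raw["frequency_items"]),
        gdi_items=tuple(raw["subscales"]["gdi"]),
        phys_items=tuple(raw["subscales"]["phys"]),
        psych_items=tuple(raw["subscales"]["psych"]),
        aliases={k.lower(): v for k, v in raw.get("aliases", {}).items()},
    )


@dataclass
class MsasResponse:
    """One patient's item responses at one visit; None = item not answered."""

    patient_id: str
    items: dict[str, Optional[int]] = field(default_factory=dict)


@dataclass
class MsasScores:
    """Subscale scores; a subscale with too many missing items is None."""

    patient_id: str
    gdi: Optional[float]
    phys: Optional[float]
    psych: Optional[float]
    tmsas: Optional[float]
    n_items_used: dict[str, int] = field(default_factory=dict)

    def score(self, subscale: str) -> Optional[float]:
        if subscale not in SUBSCALES:
            raise ValidationError(f"unknown subscale {subscale!r}")
        return getattr(self, subscale)


def _subscale_mean(
    response: MsasResponse, members: tuple[str, ...]
) -> tuple[Optional[float], int]:
    values = []
    for item in members:
        v = response.items.get(item)
        if v is None:
            continue
        if not isinstance(v, int) or isinstance(v, bool) or not 0 <= v <= 4:
            raise ValidationError(
                f"item {item!r} value {v!r} outside the 0..4 scale"
            )
        values.append(v)
    # prorate only when at least half of the members were observed
    if len(values) * 2 < len(members):
        return None, len(values)
    return sum(values) / len(values), len(values)


def score_msas(
    response: MsasResponse, catalog: Optional[MsasItemCatalog] = None
) -> MsasScores:
    """Compute the four subscale scores for one response."""
    catalog = catalog or default_catalog()
    unknown = set(response.items) - set(catalog.all_items)
    if unknown:
        raise ValidationError(f"unknown item(s) in response: {sorted(unknown)}")
    scores = {}
    used = {}
    for name in SUBSCALES:
        scores[name], used[name] = _subscale_mean(response, catalog.members(name))
    return MsasScores(
        patient_id=response.patient_id,
        gdi=scores["gdi"],
        phys=scores["phys"],
        psych=scores["psych"],
        tmsas=scores["tmsas"],
        n_items_used=used,
    )


@dataclass(frozen=True)
class ImprovementResult:
    improved: bool
    delta: float


def msas_improvement(pre: MsasScores, post: MsasScores) -> dict[str, object]:
    """Per-subscale change between visits.

    A subscale improved iff the later score is strictly lower (lower
    score = lower burden); delta = pre - post, so positive delta means
    improvement.  Subscales absent at either visit yield Absent.
    """
    out: dict[str, object] = {}
    for name in SUBSCALES:
        a, b = pre.score(name), post.score(name)
        if a is None or b is None:
            out[name] = Absent("subscale absent at one or both visits")
        else:
            out[name] = ImprovementResult(improved=b < a, delta=a - b)
    return out


# ---------------------------------------------------------------------------
# Questionnaire I/O: patient_id plus one column per canonical item,
# integers 0..4, empty field = item not answered.
# ---------------------------------------------------------------------------


def read_msas_responses(path, catalog: Optional[MsasItemCatalog] = None) -> dict[str, MsasResponse]:
    catalog = catalog or default_catalog()
    path = Path(path)
    with open(path, newline="", encoding="utf-8") as handle:
        reader = csv.DictReader(handle)
        if reader.fieldnames is None:
            return {}
        if "patient_id" not in reader.fieldnames:
            raise ParseError(f"missing patient_id column in {path}", line=1)
        column_map: dict[str, str] = {}
        for col in reader.fieldnames:
            if col == "patient_id":
                continue
            canon = catalog.canonical_name(col)
            if canon is None:
                raise ParseError(f"unrecognized item column {col!r} in {path}", line=1)
            if canon in column_map.values():
                raise ParseError(f"duplicate item column for {canon!r} in {path}", line=1)
            column_map[col] = canon
        out: dict[str, MsasResponse] = {}
        for lineno, row in enumerate(reader, start=2):
            pid = (row.get("patient_id") or "").strip()
            if not pid:
                raise ParseError("empty patient_id", line=lineno)
            if pid in out:
                raise ParseError(f"duplicate response for patient {pid!r}", line=lineno)
            items: dict[str, Optional[int]] = {}
            for col, canon in column_map.items():
                raw = (row.get(col) or "").strip()
                if raw == "":
                    items[canon] = None
                    continue
                try:
                    value = int(raw)
                except ValueError:
                    raise ParseError(
                        f"item {canon!r} value {raw!r} is not an integer", line=lineno
                    )
                if not 0 <= value <= 4:
                    raise ValidationError(
                        f"line {lineno}: item {canon!r} value {value} outside 0..4"
                    )
                items[canon] = value
            out[pid] = MsasResponse(patient_id=pid, items=items)
    return out


def write_msas_responses(
    responses: Iterable[MsasResponse], path, catalog: Optional[MsasItemCatalog] = None
) -> None:
    catalog = catalog or default_catalog()
    columns = ["patient_id", *catalog.all_items]
    with open(path, "w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle)
        writer.writerow(columns)
        for resp in responses:
            row = [resp.patient_id]
            for item in catalog.all_items:
                v = resp.items.get(item)
                row.append("" if v is None else v)
            writer.writerow(row)


def write_scores(scores: Iterable[MsasScores], path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle)
        writer.writerow(["patient_id", *SUBSCALES])
        for s in scores:
            writer.writerow(
                [s.patient_id]
                + ["" if s.score(name) is None else f"{s.score(name):.6g}" for name in SUBSCALES]
            )
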