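"""Small shared helpers."""

from __future__ import annotations

import math
from dataclasses import dataclass


@dataclass(frozen=True)
class Absent:
    """Marker returned when a statistic cannot be computed; carries the reason."""

    reason: str

    def __bool__(self) -> bool:
        return False


def round_half_up(x: float) -> int:
    """Round to the nearest integer, ties away from zero toward +inf.

    Matches the hand-rounding convention of printed percentages
    (e.g. 67.5 -> 68), unlike Python's banker's rounding.
    """
    return int(math.floor(x + 0.5))
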