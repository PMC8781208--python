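"""B-factor mobility statistics.

The isotropic crystallographic temperature factor B (A^2) maps to a
root-mean-square displacement <U> (A) through

    <U> = sqrt(B / (8 * pi^2))

so B = 8*pi^2 (~78.96 A^2) corresponds to a displacement of exactly 1 A.
Group summaries follow crystallographic reporting conventions: the group
<U> is computed from the group's *mean B* (not the mean of per-atom U),
mean B is printed to the nearest integer and U to one decimal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

__all__ = ["b_to_u", "MobilitySummary", "group_mobility"]

_EIGHT_PI_SQ = 8.0 * math.pi**2


def b_to_u(b: float) -> float:
    """Root-mean-square displacement (A) from an isotropic B factor (A^2)."""
    if b < 0:
        raise ValueError(f"B factor must be non-negative, got {b}")
    return math.sqrt(b / _EIGHT_PI_SQ)


@dataclass(frozen=True)
class MobilitySummary:
    """Mobility of a named atom group."""

    n: int
    mean_b: float
    u_from_mean_b: float  # <U> of the group's mean B
    mean_u: float  # arithmetic mean of per-atom U
    min_b: float
    max_b: float

    @property
    def mean_b_rounded(self) -> int:
        return round(self.mean_b)

    @property
    def u_rounded(self) -> float:
        return round(self.u_from_mean_b, 1)


def group_mobility(b_factors: Iterable[float]) -> MobilitySummary:
    """Summarise the mobility of a group of atoms given their B factors."""
    values = [float(b) for b in b_factors]
    if not values:
        raise ValueError("group_mobility requires at least one atom")
    mean_b = sum(values) / len(values)
    return MobilitySummary(
        n=len(values),
        mean_b=mean_b,
        u_from_mean_b=b_to_u(mean_b),
        mean_u=sum(b_to_u(v) for v in values) / len(values),
        min_b=min(values),
        max_b=max(values),
    )
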