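"""Service-quality observation indicators.

Overall satisfaction on a three-level survey is
(satisfied + generally satisfied) / total × 100%.  Rate indicators
(compensation, petition) are plain count/n percentages.  Group
comparisons on 2×2 tables use the closed-form chi-square statistic

    X² = N(ad − bc)² / ((a+b)(c+d)(a+c)(b+d))

with one degree of freedom; Yates' continuity correction (subtracting
N/2 from |ad − bc|, floored at zero) is available but off by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP

from scipy.stats import chi2

from .errors import InputError


@dataclass
class SatisfactionTable:
    """Counts of the three survey response levels for one group."""

    satisfied: int
    generally_satisfied: int
    dissatisfied: int

    def __post_init__(self):
        for name in ("satisfied", "generally_satisfied", "dissatisfied"):
            value = getattr(self, name)
            if not isinstance(value, int) or value < 0:
                raise InputError(f"{name} must be a non-negative integer, got {value!r}")

    @property
    def total(self) -> int:
        return self.satisfied + self.generally_satisfied + self.dissatisfied


@dataclass
class TwoByTwo:
    """2×2 contingency table: rows = groups, columns = outcome / non-outcome."""

    a: int
    b: int
    c: int
    d: int

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def margins(self) -> dict[str, int]:
        return {
            "row1": self.a + self.b,
            "row2": self.c + self.d,
            "col1": self.a + self.c,
            "col2": self.b + self.d,
        }


def round_half_up(value: float, places: int = 2) -> float:
    """Decimal half-up rounding for display (3.245 → 3.25, not banker's)."""
    quant = Decimal(1).scaleb(-places)
    return float(Decimal(repr(value)).quantize(quant, rounding=ROUND_HALF_UP))


def overall_satisfaction(table: SatisfactionTable) -> tuple[int, float]:
    """(combined satisfied count, percent at full precision)."""
    if table.total == 0:
        raise InputError("overall_satisfaction: zero total responses")
    combined = table.satisfied + table.generally_satisfied
    return combined, combined / table.total * 100.0


def proportion_rate(count: int, n: int) -> float:
    """count/n as a percentage."""
    if n <= 0:
        raise InputError(f"proportion_rate: n must be > 0, got {n}")
    if not 0 <= count <= n:
        raise InputError(f"proportion_rate: count {count} outside 0..{n}")
    return count / n * 100.0


def chi_square_2x2(table: TwoByTwo, yates: bool = False) -> tuple[float, float]:
    """(statistic, p-value) for independence on a 2×2 table, 1 df."""
    for name, margin in table.margins().items():
        if margin <= 0:
            raise InputError(f"chi_square_2x2: zero margin {name}")
    a, b, c, d = table.a, table.b, table.c, table.d
    n = table.n
    diff = abs(a * d - b * c)
    if yates:
        diff = max(diff - n / 2.0, 0.0)
    stat = n * diff**2 / (
        (a + b) * (c + d) * (a + c) * (b + d)
    )
    return float(stat), float(chi2.sf(stat, df=1))
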