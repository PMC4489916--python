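"""Standardization of raw menstrual-cycle days onto an adjusted 28-day cycle.

Cycles differ in length, so raw days are mapped piecewise-linearly onto a
reference 28-day cycle anchored at three points: menses onset (raw day 1 ->
adjusted day 1), the urinary LH surge (-> adjusted day 14, one day before
assumed ovulation) and the final day of the cycle, i.e. the day before the
next menses (-> adjusted day 28).  Days before the surge advance by
13/(lh_day - 1) adjusted days per raw day; days after it by
14/(length - lh_day).

Conception-risk values for an adjusted day come from a user-supplied
actuarial table over the integer days 1..28, linearly interpolated for
non-integer adjusted days.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

__all__ = ["CycleSpec", "RiskTable", "adjust_day", "adjust_day_recursive",
           "conception_risk", "CycleInputError"]

ADJUSTED_CYCLE_LENGTH = 28
LH_ADJUSTED_DAY = 14


class CycleInputError(ValueError):
    """Invalid cycle specification or out-of-range day."""


@dataclass(frozen=True)
class CycleSpec:
    """One observed cycle: LH-surge day and final day, menses onset = day 1.

    ``length`` is the cycle's final day (the day preceding the next menses
    onset), so a textbook cycle has length 28 and lh_day 14.
    """

    lh_day: int
    length: int

    def __post_init__(self):
        if self.lh_day != int(self.lh_day) or self.length != int(self.length):
            raise CycleInputError("lh_day and length must be integers")
        if not (1 < self.lh_day < self.length):
            raise CycleInputError(
                f"need 1 < lh_day < length, got lh_day={self.lh_day}, "
                f"length={self.length}"
            )


def _check_day(d, spec: CycleSpec) -> int:
    if d != int(d):
        raise CycleInputError(
            f"raw cycle days are whole days, got {d!r}"
        )
    d = int(d)
    if not (1 <= d <= spec.length):
        raise CycleInputError(
            f"day {d} outside cycle 1..{spec.length}"
        )
    return d


def adjust_day(d: int, spec: CycleSpec) -> float:
    """Map raw cycle day ``d`` onto the adjusted 28-day cycle (closed form).

    Returns a real adjusted day in [1, 28], with day 1, the LH-surge day and
    the final day mapping exactly to 1, 14 and 28.  Full precision is kept;
    round only for presentation (the conventional report is 2 decimals).
    """
    d = _check_day(d, spec)
    if d <= spec.lh_day:
        return 1.0 + (LH_ADJUSTED_DAY - 1) * (d - 1) / (spec.lh_day - 1)
    return LH_ADJUSTED_DAY + (ADJUSTED_CYCLE_LENGTH - LH_ADJUSTED_DAY) * (
        d - spec.lh_day
    ) / (spec.length - spec.lh_day)


def adjust_day_recursive(d: int, spec: CycleSpec) -> float:
    """Day-by-day recursion equivalent to :func:`adjust_day`.

    Each raw day adds a constant increment to the previous adjusted day:
    13/(lh_day - 1) before the surge, 14/(length - lh_day) after it.
    Retained as an independent formulation for cross-checking.
    """
    d = _check_day(d, spec)
    da = 1.0
    for day in range(2, d + 1):
        if day <= spec.lh_day:
            da += (LH_ADJUSTED_DAY - 1) / (spec.lh_day - 1)
        else:
            da += (ADJUSTED_CYCLE_LENGTH - LH_ADJUSTED_DAY) / (
                spec.length - spec.lh_day
            )
    return da


@dataclass(frozen=True)
class RiskTable:
    """Conception probability after a single intercourse act, by adjusted day.

    Keys must cover every integer day 1..28; values are probabilities.
    The package does not bundle actuarial values — supply your own table
    (``synthetic_data.placeholder_risk_table`` provides a clearly labeled
    synthetic one for tests and demonstrations).
    """

    values: Mapping[int, float]

    def __post_init__(self):
        vals = {int(k): float(v) for k, v in dict(self.values).items()}
        missing = set(range(1, ADJUSTED_CYCLE_LENGTH + 1)) - set(vals)
        if missing:
            raise CycleInputError(f"risk table missing days {sorted(missing)}")
        bad = {k: v for k, v in vals.items() if not (0.0 <= v <= 1.0)}
        if bad:
            raise CycleInputError(f"risk values outside [0, 1]: {bad}")
        object.__setattr__(self, "values", vals)

    def __getitem__(self, day: int) -> float:
        return self.values[day]

    @classmethod
    def from_csv(cls, path) -> "RiskTable":
        import pandas as pd

        df = pd.read_csv(path, comment="#")
        day_col, risk_col = df.columns[:2]
        return cls(dict(zip(df[day_col].astype(int), df[risk_col])))


def conception_risk(adjusted_day: float, table: RiskTable) -> float:
    """Linearly interpolated conception risk at a (possibly fractional) day.

    Integer adjusted days return the table value exactly; a day like 10.5
    returns the midpoint of the day-10 and day-11 values.
    """
    if not np.isfinite(adjusted_day) or not (
        1.0 <= adjusted_day <= ADJUSTED_CYCLE_LENGTH
    ):
        raise CycleInputError(
            f"adjusted day {adjusted_day!r} outside [1, {ADJUSTED_CYCLE_LENGTH}]"
        )
    lo = int(np.floor(adjusted_day))
    hi = min(lo + 1, ADJUSTED_CYCLE_LENGTH)
    frac = adjusted_day - lo
    return (1.0 - frac) * table[lo] + frac * table[hi]
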