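"""Workflow turnaround-time arithmetic.

Summary statistics for turnaround-time samples (mean with a 95%
confidence interval), percent reductions between two workflows, and the
evaluable-record fraction.  Units are explicit (minutes, hours, days;
1 d = 24 h = 1440 min) and conversions are exact, so a reduction from
days to minutes is computed on a common scale.
"""
from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy import stats

from .errors import ParameterError, QtcdxError


class TimeUnit(str, Enum):
    MINUTES = "minutes"
    HOURS = "hours"
    DAYS = "days"


_TO_MINUTES = {TimeUnit.MINUTES: 1.0, TimeUnit.HOURS: 60.0, TimeUnit.DAYS: 1440.0}


class InsufficientDataError(QtcdxError):
    pass


@dataclass(frozen=True)
class Duration:
    value: float
    unit: TimeUnit

    def __post_init__(self) -> None:
        if not self.value > 0:
            raise ParameterError(f"durations must be positive, got {self.value}")

    def to_minutes(self) -> float:
        return self.value * _TO_MINUTES[TimeUnit(self.unit)]


@dataclass
class TurnaroundSample:
    """Turnaround durations for one workflow, in a single explicit unit."""

    values: list[float]
    unit: TimeUnit
    label: str = ""

    def __post_init__(self) -> None:
        self.unit = TimeUnit(self.unit)
        if any(v <= 0 for v in self.values):
            raise ParameterError("all durations must be positive")


def mean_ci(sample: TurnaroundSample, level: float = 0.95,
            method: str = "normal") -> tuple[float, float, float]:
    """Mean and symmetric confidence interval, in the sample's unit.

    ``method='normal'`` uses mean +/- z * SE; ``method='t'`` uses the
    Student-t critical value instead.
    """
    v = np.asarray(sample.values, dtype=float)
    if v.size < 2:
        raise InsufficientDataError("need at least 2 values for a confidence interval")
    mean = float(np.mean(v))
    se = float(np.std(v, ddof=1) / np.sqrt(v.size))
    if method == "normal":
        crit = float(stats.norm.ppf(0.5 + level / 2.0))
    elif method == "t":
        crit = float(stats.t.ppf(0.5 + level / 2.0, df=v.size - 1))
    else:
        raise ParameterError(f"unknown CI method {method!r}")
    return mean, mean - crit * se, mean + crit * se


def percent_reduction(before: Duration, after: Duration) -> float:
    """Percent reduction from ``before`` to ``after``: 100 (b - a) / b.

    Full precision is returned; round to the nearest integer for
    display.  Invariant under any common rescaling of both inputs.
    """
    b, a = before.to_minutes(), after.to_minutes()
    return 100.0 * (b - a) / b


def evaluable_fraction(n_total: int, n_evaluable: int) -> float:
    """Percentage of evaluable records; display to one decimal."""
    if n_total <= 0:
        raise ParameterError("n_total must be positive")
    if not 0 <= n_evaluable <= n_total:
        raise ParameterError(
            f"n_evaluable {n_evaluable} outside [0, {n_total}]"
        )
    return 100.0 * n_evaluable / n_total
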