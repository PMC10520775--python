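"""CTCAE v5.0 QTc-prolongation grading, sex-specific status and TdP risk.

Grades follow the CTCAE v5.0 bands for "electrocardiogram QT corrected
interval prolonged":

* grade 1 — average QTc 450-480 ms
* grade 2 — average QTc 481-500 ms
* grade 3 — average QTc above 500 ms, or an increase of more than
  60 ms over the patient's baseline QTc
* grade 4 — torsade de pointes, polymorphic ventricular tachycardia or
  another serious arrhythmia (an external clinical flag here: the
  library does not detect arrhythmias from the signal)

CTCAE states the bands on integer ms; for non-integer QTc the open
interval (480, 481) is assigned to the grade-1 band, i.e. the bands are
[450, 481) and [481, 500], so every positive real value maps to exactly
one grade.

The descriptive normal/borderline/prolonged status uses the sex-specific
conventions for average QTc (male: normal <=430 ms, borderline
430-450 ms, prolonged >450 ms; female: normal <=450 ms, borderline
450-470 ms, prolonged >470 ms).

Torsade-de-pointes risk rises roughly exponentially with QTc, about 5%
to 7% per 10 ms; :func:`tdp_relative_risk` compounds that rate from a
reference QTc (default 440 ms).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum

from .errors import ParameterError

log = logging.getLogger(__name__)


class Sex(str, Enum):
    MALE = "male"
    FEMALE = "female"


class QtcStatus(str, Enum):
    NORMAL = "normal"
    BORDERLINE = "borderline"
    PROLONGED = "prolonged"


class GradeRule(str, Enum):
    NORMAL = "normal"
    BAND_450_480 = "band_450_480"
    BAND_481_500 = "band_481_500"
    ABOVE_500 = "above_500"
    BASELINE_DELTA = "baseline_delta"
    TDP_ARRHYTHMIA = "tdp_arrhythmia"


@dataclass(frozen=True)
class GradingThresholds:
    """CTCAE band edges (ms).  Overriding the defaults departs from the
    published CTCAE v5.0 definitions and is loudly logged."""

    band1_low: float = 450.0
    band2_low: float = 481.0
    band3_low: float = 500.0    # grade 3 strictly above this
    delta_ms: float = 60.0      # grade 3 when increase over baseline exceeds this

    def __post_init__(self) -> None:
        if not (self.band1_low < self.band2_low <= self.band3_low):
            raise ParameterError("grading bands must be ordered")
        if (self.band1_low, self.band2_low, self.band3_low, self.delta_ms) != \
                (450.0, 481.0, 500.0, 60.0):
            log.warning("non-standard CTCAE grading thresholds in effect: %s", self)


@dataclass(frozen=True)
class GradingInput:
    qtcf_mean_ms: float
    baseline_qtcf_ms: float | None = None
    tdp_or_serious_arrhythmia: bool = False
    sex: Sex | None = None

    def __post_init__(self) -> None:
        if not self.qtcf_mean_ms > 0:
            raise ParameterError(f"qtcf_mean_ms must be positive, got {self.qtcf_mean_ms}")
        if self.baseline_qtcf_ms is not None and not self.baseline_qtcf_ms > 0:
            raise ParameterError(f"baseline_qtcf_ms must be positive, got {self.baseline_qtcf_ms}")


@dataclass(frozen=True)
class CTCAEDiagnosis:
    grade: int
    triggered_rule: GradeRule
    delta_ms: float | None = None
    status: QtcStatus | None = None

    def to_dict(self) -> dict:
        return {
            "grade": self.grade,
            "triggered_rule": self.triggered_rule.value,
            "delta_ms": None if self.delta_ms is None else round(self.delta_ms, 2),
            "status": None if self.status is None else self.status.value,
        }


def ctcae_grade(inp: GradingInput,
                thresholds: GradingThresholds | None = None) -> CTCAEDiagnosis:
    """Grade an average QTcF per CTCAE v5.0.

    Rule precedence: arrhythmia flag (grade 4), then the grade-3
    criteria (QTc above 500 ms, or more than 60 ms above baseline),
    then the 481-500 and 450-480 bands, else grade 0.  Only increases
    over baseline count towards the delta rule.
    """
    th = thresholds or GradingThresholds()
    q = inp.qtcf_mean_ms
    delta = None
    if inp.baseline_qtcf_ms is not None:
        delta = q - inp.baseline_qtcf_ms
    status = sex_status(q, inp.sex) if inp.sex is not None else None

    if inp.tdp_or_serious_arrhythmia:
        return CTCAEDiagnosis(4, GradeRule.TDP_ARRHYTHMIA, delta, status)
    if q > th.band3_low:
        return CTCAEDiagnosis(3, GradeRule.ABOVE_500, delta, status)
    if delta is not None and delta > th.delta_ms:
        return CTCAEDiagnosis(3, GradeRule.BASELINE_DELTA, delta, status)
    if th.band2_low <= q <= th.band3_low:
        return CTCAEDiagnosis(2, GradeRule.BAND_481_500, delta, status)
    if th.band1_low <= q < th.band2_low:
        return CTCAEDiagnosis(1, GradeRule.BAND_450_480, delta, status)
    return CTCAEDiagnosis(0, GradeRule.NORMAL, delta, status)


def sex_status(qtcf_mean_ms: float, sex: Sex | str) -> QtcStatus:
    """Descriptive normal/borderline/prolonged status for an average QTc."""
    if not qtcf_mean_ms > 0:
        raise ParameterError(f"qtcf_mean_ms must be positive, got {qtcf_mean_ms}")
    sex = Sex(sex)
    if sex is Sex.MALE:
        normal_hi, prolonged_lo = 430.0, 450.0
    else:
        normal_hi, prolonged_lo = 450.0, 470.0
    if qtcf_mean_ms <= normal_hi:
        return QtcStatus.NORMAL
    if qtcf_mean_ms <= prolonged_lo:
        return QtcStatus.BORDERLINE
    return QtcStatus.PROLONGED


def tdp_relative_risk(qtc_ms: float, reference_ms: float = 440.0,
                      per10_low: float = 0.05,
                      per10_high: float = 0.07) -> tuple[float, float]:
    """Fractional excess torsade-de-pointes risk versus a reference QTc.

    Compounds a 5%-7% risk increase per 10 ms of QTc:
    ``(1 + p) ** ((qtc - ref) / 10) - 1`` for p in (low, high).  A QTc
    of 540 ms versus the 440 ms reference gives (0.629, 0.967): a 63%
    to 97% higher TdP risk.  Defined for QTc at or above the reference
    only.
    """
    if qtc_ms < reference_ms:
        raise ParameterError(
            f"qtc_ms {qtc_ms} below reference {reference_ms}; the risk scaling "
            "is defined upward only"
        )
    steps = (qtc_ms - reference_ms) / 10.0
    return ((1.0 + per10_low) ** steps - 1.0, (1.0 + per10_high) ** steps - 1.0)
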