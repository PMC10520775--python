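"""Core domain containers shared across the pipeline.

Conventions used throughout the package:

* sample indices are 0-based integers on the record's own sampling grid;
* times are seconds, intervals are reported in milliseconds;
* voltages are millivolts.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterator

import numpy as np

from .errors import ParameterError, UnsupportedRateError

#: Supported sampling-rate range (Hz).  Handheld single-lead recorders
#: ship anywhere from a few hundred Hz up to 1 kHz; rates outside this
#: band are rejected rather than silently resampled.
FS_MIN = 100.0
FS_MAX = 2000.0


@dataclass
class ECGRecord:
    """A uniformly sampled single-lead ECG voltage series.

    Parameters
    ----------
    signal
        Voltage samples in mV, one dimensional, no gaps (NaN/inf is an
        input error, not missing data to be imputed).
    fs
        Sampling frequency in Hz, within [100, 2000].
    record_id
        Opaque identifier carried through to reports.
    lead_label
        Lead name; handheld two-electrode devices record lead I.
    """

    signal: np.ndarray
    fs: float
    record_id: str = "record"
    lead_label: str = "I"

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 1:
            raise ParameterError("signal must be one-dimensional")
        if not np.all(np.isfinite(self.signal)):
            raise ParameterError("signal contains non-finite samples (gaps are an input error)")
        if not (self.fs > 0):
            raise ParameterError(f"sampling rate must be positive, got {self.fs}")
        if not (FS_MIN <= self.fs <= FS_MAX):
            raise UnsupportedRateError(
                f"sampling rate {self.fs} Hz outside supported range [{FS_MIN:g}, {FS_MAX:g}] Hz"
            )

    @property
    def n_samples(self) -> int:
        return self.signal.size

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def require_duration(self, min_s: float) -> None:
        """Raise if the record is shorter than ``min_s`` seconds."""
        if self.duration_s < min_s:
            raise ParameterError(
                f"record {self.record_id!r} is {self.duration_s:.2f} s; "
                f"at least {min_s:g} s required"
            )


@dataclass(frozen=True)
class BeatFiducials:
    """Per-beat landmark set: R peak, QRS onset and T-wave offset.

    All three are 0-based sample indices on the parent record's grid.
    The QT interval of the beat is (t_offset - qrs_onset) / fs * 1000 ms.
    """

    r_peak: int
    qrs_onset: int
    t_offset: int

    def __post_init__(self) -> None:
        if not (self.qrs_onset < self.r_peak < self.t_offset):
            raise ParameterError(
                f"fiducials must satisfy qrs_onset < r_peak < t_offset, "
                f"got {self.qrs_onset}, {self.r_peak}, {self.t_offset}"
            )

    def qt_ms(self, fs: float) -> float:
        return (self.t_offset - self.qrs_onset) / fs * 1000.0


class AnnotationSource(str, Enum):
    GROUND_TRUTH = "ground_truth"
    DELINEATOR = "delineator"


@dataclass
class AnnotationSet:
    """An ordered collection of beat fiducials for one record."""

    beats: list[BeatFiducials] = field(default_factory=list)
    source: AnnotationSource = AnnotationSource.DELINEATOR

    def __post_init__(self) -> None:
        peaks = [b.r_peak for b in self.beats]
        if any(b <= a for a, b in zip(peaks, peaks[1:])):
            raise ParameterError("beats must be sorted by strictly increasing r_peak")

    def __len__(self) -> int:
        return len(self.beats)

    def __iter__(self) -> Iterator[BeatFiducials]:
        return iter(self.beats)

    def qt_ms(self, fs: float) -> np.ndarray:
        """Per-beat QT intervals in ms."""
        return np.array([b.qt_ms(fs) for b in self.beats])
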