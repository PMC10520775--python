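"""Synthetic single-lead ECG generation with exact ground-truth fiducials.

Each beat is a sum of five Gaussian bumps (P, Q, R, S, T), in the spirit
of dynamical ECG simulators but with analytically known landmarks: the
QRS onset is defined as three Gaussian widths before the Q-wave centre
and the T offset as three widths after the T-wave centre, and the T wave
is placed so that (T offset - QRS onset) equals the requested QT
interval exactly, before any jitter or corruption is applied.  Noise and
baseline wander are added only after the fiducials are fixed, so the
ground truth is invariant to them by construction.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import AnnotationSet, AnnotationSource, BeatFiducials, ECGRecord
from .errors import ParameterError

# Wave morphology: (centre relative to R in ms, sigma in ms, amplitude in mV).
# Widths quoted as total durations of ~6 sigma: P 80 ms, Q 20 ms, R 24 ms,
# S 20 ms, T 120 ms at the reference QT of 400 ms.
_P = (-180.0, 80.0 / 6.0, 0.15)
_Q = (-24.0, 20.0 / 6.0, -0.10)
_R = (0.0, 24.0 / 6.0, 1.0)
_S = (24.0, 20.0 / 6.0, -0.15)
_T_SIGMA_REF = 120.0 / 6.0   # at QT = 400 ms; scales linearly with QT
_QT_REF = 400.0

#: QRS onset relative to R (ms): Q centre minus 3 Q-widths.
QRS_ONSET_MS = _Q[0] - 3.0 * _Q[1]


def _t_wave(qt_ms: float) -> tuple[float, float, float]:
    """T-wave (centre, sigma, amplitude) giving exactly ``qt_ms`` from QRS onset."""
    sigma = _T_SIGMA_REF * qt_ms / _QT_REF
    centre = QRS_ONSET_MS + qt_ms - 3.0 * sigma
    return centre, sigma, 0.3


@dataclass
class SynthParams:
    """Generator configuration.

    Defaults emulate a 30 s handheld single-lead recording of a resting
    subject: 60 bpm with 20 ms RR jitter, a normal 400 ms QT, 0.02 mV
    wideband noise and slow 0.05 mV respiratory baseline wander.
    """

    duration_s: float = 30.0
    hr_bpm: float = 60.0
    qt_ms: float = 400.0
    rr_jitter_ms: float = 20.0
    noise_mv: float = 0.02
    wander_mv: float = 0.05
    wander_hz: float = 0.3
    fs: float = 500.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (40.0 <= self.hr_bpm <= 140.0):
            raise ParameterError(f"hr_bpm {self.hr_bpm} outside [40, 140]")
        if not (300.0 <= self.qt_ms <= 600.0):
            raise ParameterError(f"qt_ms {self.qt_ms} outside [300, 600]")
        rr = 60000.0 / self.hr_bpm
        if not self.qt_ms < 0.9 * rr:
            raise ParameterError(
                f"qt_ms {self.qt_ms} must be < 90% of the mean RR ({rr:.0f} ms) at {self.hr_bpm} bpm"
            )
        if self.duration_s < 5.0:
            raise ParameterError("duration_s must be at least 5 s")
        if min(self.rr_jitter_ms, self.noise_mv, self.wander_mv, self.wander_hz) < 0:
            raise ParameterError("jitter, noise and wander parameters must be non-negative")


@dataclass
class GroundTruth:
    """Exact per-beat fiducials and intervals for a generated record."""

    annotations: AnnotationSet
    true_qt_ms: np.ndarray          # per beat, from the integer fiducial indices
    rr_draws_ms: np.ndarray         # realized RR sequence between retained beats
    qt_nominal_ms: float            # the requested QT, before index rounding
    fs: float = field(repr=False, default=500.0)

    @property
    def true_mean_rr_ms(self) -> float:
        return float(np.mean(self.rr_draws_ms))

    @property
    def r_peaks(self) -> np.ndarray:
        return np.array([b.r_peak for b in self.annotations.beats])


def beat_template(t_ms: np.ndarray, qt_ms: float = 400.0) -> np.ndarray:
    """Noise-free single-beat waveform at times ``t_ms`` relative to the R peak."""
    t_ms = np.asarray(t_ms, dtype=float)
    out = np.zeros_like(t_ms)
    for centre, sigma, amp in (_P, _Q, _R, _S, _t_wave(qt_ms)):
        out += amp * np.exp(-0.5 * ((t_ms - centre) / sigma) ** 2)
    return out


def generate_ecg(params: SynthParams) -> tuple[ECGRecord, GroundTruth]:
    """Generate a synthetic single-lead ECG with known fiducials.

    Deterministic given ``params.seed``.  Beats whose T wave would not
    complete inside the record are dropped from both the signal and the
    ground truth; the P wave of the first beat is kept inside the record
    by starting it 0.4 s in.
    """
    rng = np.random.default_rng(params.seed)
    fs = params.fs
    n = int(round(params.duration_s * fs))
    rr_mean = 60000.0 / params.hr_bpm
    t_centre, t_sigma, _ = _t_wave(params.qt_ms)
    tail_ms = t_centre + 3.0 * t_sigma      # end of the T bump, relative to R

    # R-peak times (ms): cumulative jittered RR, first beat fully inside.
    # The end margin (at least 350 ms) keeps every ground-truth beat clear
    # of the record edge, so detection works on the full truth set.
    end_margin = max(tail_ms, 350.0)
    r_times = []
    t_r = 400.0
    rr_list = []
    while t_r + end_margin < params.duration_s * 1000.0:
        r_times.append(t_r)
        jitter = rng.normal(0.0, params.rr_jitter_ms) if params.rr_jitter_ms > 0 else 0.0
        jitter = float(np.clip(jitter, -3.0 * params.rr_jitter_ms, 3.0 * params.rr_jitter_ms))
        rr = rr_mean + jitter
        rr_list.append(rr)
        t_r = t_r + rr
    if not r_times:
        raise ParameterError("record too short to hold a single complete beat")

    t_ms = np.arange(n) / fs * 1000.0
    signal = np.zeros(n)
    beats = []
    onset_rel = QRS_ONSET_MS
    for r in r_times:
        signal += beat_template(t_ms - r, params.qt_ms)
        r_idx = int(round(r * fs / 1000.0))
        on_idx = r_idx + int(round(onset_rel * fs / 1000.0))
        off_idx = on_idx + int(round(params.qt_ms * fs / 1000.0))
        beats.append(BeatFiducials(r_peak=r_idx, qrs_onset=on_idx, t_offset=off_idx))

    # corruption applied only after fiducials are fixed
    if params.wander_mv > 0:
        signal += params.wander_mv * np.sin(2.0 * np.pi * params.wander_hz * t_ms / 1000.0)
    if params.noise_mv > 0:
        signal += rng.normal(0.0, params.noise_mv, size=n)

    ann = AnnotationSet(beats=beats, source=AnnotationSource.GROUND_TRUTH)
    truth = GroundTruth(
        annotations=ann,
        true_qt_ms=ann.qt_ms(fs),
        rr_draws_ms=np.array(rr_list[:-1]) if len(rr_list) > 1 else np.empty(0),
        qt_nominal_ms=params.qt_ms,
        fs=fs,
    )
    rec = ECGRecord(signal=signal, fs=fs,
                    record_id=f"synth-hr{params.hr_bpm:g}-qt{params.qt_ms:g}-s{params.seed}")
    return rec, truth


def generate_flat(duration_s: float, fs: float = 500.0) -> ECGRecord:
    """All-zero record: the negative control for beat detection."""
    if duration_s < 1.0:
        raise ParameterError("duration_s must be at least 1 s")
    n = int(round(duration_s * fs))
    return ECGRecord(signal=np.zeros(n), fs=fs, record_id="flat")
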