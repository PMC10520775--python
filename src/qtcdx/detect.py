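"""R-peak detection for single-lead ECG.

A Pan-Tompkins-style energy pipeline: zero-phase 5-15 Hz band-pass,
differentiation, squaring, 150 ms moving-window integration, then
adaptive dual-threshold peak picking with a 200 ms refractory period and
a half-threshold searchback for missed beats.  Each accepted peak is
finally refined to the local maximum of the raw signal within +/-50 ms,
so the reported indices land on the R wave itself rather than on the
integrated envelope.

The pipeline is invariant to positive amplitude scaling: all thresholds
are relative to running signal/noise peak estimates.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .core import ECGRecord
from .errors import InsufficientBeatsError, ParameterError

REFRACTORY_S = 0.2
_EDGE_EXCLUDE_S = 0.3     # filter transients at the record edges
_INTEGRATION_S = 0.150
_REFINE_S = 0.05


@dataclass
class RPeakList:
    """Strictly increasing R-peak sample indices with their sampling rate."""

    indices: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=int)
        if self.indices.size > 1:
            d = np.diff(self.indices)
            if np.any(d <= 0):
                raise ParameterError("R-peak indices must be strictly increasing")
            if np.any(d < REFRACTORY_S * self.fs):
                raise ParameterError("R peaks closer than the 200 ms refractory period")

    def __len__(self) -> int:
        return self.indices.size


def detect_rpeaks(rec: ECGRecord) -> RPeakList:
    """Locate R peaks in a record of at least 2 s.

    Returns an empty list when no QRS energy is present (e.g. a flat
    trace); this is not an error.
    """
    rec.require_duration(2.0)
    fs = rec.fs
    x = rec.signal

    # band-pass 5-15 Hz, zero phase
    sos = sps.butter(2, [5.0, 15.0], btype="bandpass", fs=fs, output="sos")
    filt = sps.sosfiltfilt(sos, x)
    deriv = np.gradient(filt)
    energy = deriv * deriv
    win = max(1, int(round(_INTEGRATION_S * fs)))
    integ = np.convolve(energy, np.ones(win) / win, mode="same")

    peak = float(np.max(integ))
    if peak <= 0.0:
        return RPeakList(indices=np.empty(0, dtype=int), fs=fs)

    refractory = int(round(REFRACTORY_S * fs))
    edge = int(round(_EDGE_EXCLUDE_S * fs))
    cand, _ = sps.find_peaks(integ, distance=refractory)
    cand = cand[(cand >= edge) & (cand < integ.size - edge)]
    if cand.size == 0:
        return RPeakList(indices=np.empty(0, dtype=int), fs=fs)

    slope = np.abs(np.gradient(x))
    accepted = _adaptive_select(integ, cand, fs, slope)
    refined = _refine_to_raw(x, accepted, fs)
    return RPeakList(indices=refined, fs=fs)


def _max_slope(slope: np.ndarray, idx: int, fs: float) -> float:
    half = int(round(0.04 * fs))
    lo, hi = max(0, idx - half), min(slope.size, idx + half + 1)
    return float(slope[lo:hi].max())


def _adaptive_select(integ: np.ndarray, cand: np.ndarray, fs: float,
                     slope: np.ndarray) -> np.ndarray:
    """Adaptive dual-threshold classification with T-wave rejection and
    searchback.

    A candidate within 360 ms of the previous accepted beat whose
    steepest raw-signal slope is under half that of the previous beat is
    a T wave, not a QRS (the classic slope criterion)."""
    # initialize estimates from the first 2 s of candidates
    head = integ[: int(2 * fs)]
    spk = float(np.max(head)) if head.size else float(np.max(integ))
    npk = float(np.mean(head)) * 0.5 if head.size else 0.0
    thr1 = npk + 0.25 * (spk - npk)

    accepted: list[int] = []
    recent_rr: list[float] = []
    refractory = int(round(REFRACTORY_S * fs))

    # running estimate of the QRS slope, seeded from the steepest
    # candidate of the first 2 s; waves with under 40% of it (T and P
    # waves, noise bumps) are vetoed however large their band energy
    head_cand = cand[cand < int(2 * fs)]
    seed_pool = head_cand if head_cand.size else cand
    slope_ref = max(_max_slope(slope, int(c), fs) for c in seed_pool)

    for idx in cand:
        # T waves can trail the QRS by well over 360 ms at slow rates with a
        # long QT, so the rejection window adapts to the running RR estimate.
        twave_window = int(round(max(0.36 * fs,
                                     0.7 * np.mean(recent_rr) if recent_rr else 0.0)))
        v = float(integ[idx])
        if accepted and idx - accepted[-1] < refractory:
            continue
        if v >= thr1:
            this_slope = _max_slope(slope, idx, fs)
            if this_slope < 0.4 * slope_ref:
                # T or P wave: reject, and leave the noise estimate
                # untouched — their energy is far above baseline noise
                # and would inflate the threshold past small QRS complexes
                continue
            if accepted and idx - accepted[-1] < twave_window and \
                    this_slope < 0.5 * _max_slope(slope, accepted[-1], fs):
                continue
            # searchback first: did we miss a beat in a long gap?
            if accepted and recent_rr:
                _searchback(integ, cand, accepted, recent_rr, idx, thr1, refractory,
                            slope, fs)
            if accepted:
                recent_rr.append(float(idx - accepted[-1]))
                recent_rr[:] = recent_rr[-8:]
            accepted.append(int(idx))
            spk = 0.125 * v + 0.875 * spk
            slope_ref = 0.125 * this_slope + 0.875 * slope_ref
        else:
            npk = 0.125 * v + 0.875 * npk
        thr1 = npk + 0.25 * (spk - npk)

    # trailing searchback: a missed final beat after the last accepted one
    if accepted and recent_rr:
        _searchback(integ, cand, accepted, recent_rr, integ.size, thr1, refractory,
                    slope, fs)
    return np.array(sorted(set(accepted)), dtype=int)


def _searchback(integ: np.ndarray, cand: np.ndarray, accepted: list[int],
                recent_rr: list[float], upto: int, thr1: float, refractory: int,
                slope: np.ndarray, fs: float) -> None:
    """Recover a beat at half threshold when a gap exceeds 1.66x the recent RR."""
    rr_avg = float(np.mean(recent_rr))
    last = accepted[-1]
    if upto - last <= 1.66 * rr_avg:
        return
    gap = cand[(cand > last + refractory) & (cand < upto - refractory)]
    if gap.size == 0:
        return
    vals = integ[gap]
    best = gap[int(np.argmax(vals))]
    if integ[best] >= 0.5 * thr1 and \
            _max_slope(slope, best, fs) >= 0.5 * _max_slope(slope, last, fs):
        accepted.append(int(best))
        accepted.sort()


def _refine_to_raw(x: np.ndarray, peaks: np.ndarray, fs: float) -> np.ndarray:
    """Snap each peak to the raw-signal local maximum within +/-50 ms."""
    if peaks.size == 0:
        return peaks
    half = int(round(_REFINE_S * fs))
    out = []
    for p in peaks:
        lo, hi = max(0, p - half), min(x.size, p + half + 1)
        out.append(lo + int(np.argmax(x[lo:hi])))
    out = sorted(set(out))
    # refinement may merge neighbours; enforce refractory keeping the earlier
    refractory = REFRACTORY_S * fs
    kept: list[int] = []
    for p in out:
        if not kept or p - kept[-1] >= refractory:
            kept.append(p)
    return np.array(kept, dtype=int)


def rr_intervals(peaks: RPeakList) -> np.ndarray:
    """Consecutive RR intervals in ms; requires at least two peaks."""
    if len(peaks) < 2:
        raise InsufficientBeatsError(
            f"need at least 2 R peaks for RR intervals, got {len(peaks)}"
        )
    return np.diff(peaks.indices) / peaks.fs * 1000.0


def heart_rate_bpm(peaks: RPeakList) -> float:
    """Mean heart rate in beats/min from the mean RR interval."""
    rr = rr_intervals(peaks)
    return 60000.0 / float(np.mean(rr))
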