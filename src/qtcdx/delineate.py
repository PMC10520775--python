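"""Wavelet-based QRS-onset / T-offset delineation.

The QT boundaries are located on a dyadic stationary wavelet transform
(a-trous scheme) with the quadratic-spline mother wavelet, the classic
choice for ECG delineation: at each scale the transform is proportional
to a smoothed derivative of the signal, so wave boundaries appear as the
flanks of modulus maxima and wave peaks as zero crossings between
modulus-maximum pairs.

The signal is analysed at 250 Hz (resampled internally when the record
is at another rate) so that the dyadic scales keep their standard
frequency meaning; all returned indices are mapped back to the record's
own sampling grid.

Per beat:

* **QRS onset** — scan left from the first significant modulus maximum
  of |W at scale 4| inside the QRS window until the modulus falls below
  ``gamma_on`` times the window maximum or the transform crosses zero,
  capped at 80 ms before the R peak.
* **T offset** — inside a window from R+100 ms to R+min(0.7 RR, 600 ms),
  require T-wave energy (window maximum of |W at scale 16| at least
  four times its median, and the later of the two above an absolute
  floor), take the last significant modulus maximum after the T-peak
  zero crossing, and place the offset at the first point after it where
  the modulus drops below ``gamma_t`` times that maximum.

Beats without T energy, with inverted fiducial order, or with a QT
outside the physiologically evaluable 200-700 ms band are flagged
unevaluable rather than reported.
"""
from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import signal as sps

from .core import AnnotationSet, AnnotationSource, BeatFiducials, ECGRecord
from .detect import RPeakList, rr_intervals
from .errors import InsufficientBeatsError, RecordUnevaluableError

_FS_INTERNAL = 250.0
# quadratic-spline a-trous filter pair at the base scale
_H = np.array([1.0, 3.0, 3.0, 1.0]) / 8.0   # smoothing, group delay 1.5
_G = np.array([2.0, -2.0])                   # derivative, group delay 0.5

QT_EVALUABLE_MS = (200.0, 700.0)


@dataclass
class DelineationConfig:
    """Tunable thresholds; defaults follow the published delineator family."""

    gamma_on: float = 0.05        # QRS-onset stop threshold, x window max |W2|
    gamma_t: float = 0.25         # T-offset stop threshold, x last-mm modulus
    gamma_sig: float = 0.06       # significance of a QRS modulus maximum
    t_window_max_ms: float = 600.0
    t_window_min_ms: float = 100.0
    t_energy_ratio: float = 4.0   # max/median |W4| required in the T window
    qrs_onset_cap_ms: float = 80.0
    qrs_halfwin_ms: float = 60.0


@dataclass
class DelineationSummary:
    total: int
    evaluable: int
    unevaluable: int


def swt_scales(x: np.ndarray, levels: int = 5) -> list[np.ndarray]:
    """Stationary wavelet detail coefficients W at scales 2^1 .. 2^levels.

    A-trous cascade: the detail at level k is the signal filtered by the
    derivative filter upsampled by 2^(k-1), preceded by the cascaded
    smoothing filters of all finer levels.  Each equivalent filter has
    generalized linear phase with group delay 2^k - 1.5 samples; outputs
    are delay-compensated so modulus maxima align with the signal slopes
    that produced them.
    """
    out = []
    smooth = np.array([1.0])
    for k in range(1, levels + 1):
        eq = np.convolve(smooth, _upsample(_G, 2 ** (k - 1)))
        d = (eq.size - 1) // 2        # floor of the true half-sample delay
        w = np.convolve(x, eq, mode="full")[d:d + x.size + 1]
        # the equivalent filter delay is d + 0.5; interpolate onto the
        # integer grid so maxima align with the slopes that produced them
        w = 0.5 * (w[:-1] + w[1:]) if w.size > x.size else w[:x.size]
        out.append(w)
        smooth = np.convolve(smooth, _upsample(_H, 2 ** (k - 1)))
    return out


def _upsample(f: np.ndarray, factor: int) -> np.ndarray:
    if factor == 1:
        return f
    out = np.zeros((f.size - 1) * factor + 1)
    out[::factor] = f
    return out


def _resample_to_internal(rec: ECGRecord) -> tuple[np.ndarray, float]:
    """Return (signal at 250 Hz, ratio internal/original)."""
    if rec.fs == _FS_INTERNAL:
        return rec.signal, 1.0
    frac = Fraction(_FS_INTERNAL / rec.fs).limit_denominator(1000)
    y = sps.resample_poly(rec.signal, frac.numerator, frac.denominator)
    return y, float(frac)


def _local_maxima(a: np.ndarray) -> np.ndarray:
    """Indices of strict local maxima of ``a`` (interior points)."""
    if a.size < 3:
        return np.empty(0, dtype=int)
    idx = np.flatnonzero((a[1:-1] >= a[:-2]) & (a[1:-1] > a[2:])) + 1
    return idx


class _RecordDelineator:
    """Holds the wavelet transforms of one record so beats share them."""

    def __init__(self, rec: ECGRecord, config: DelineationConfig | None = None):
        self.rec = rec
        self.config = config or DelineationConfig()
        y, self.ratio = _resample_to_internal(rec)
        scales = swt_scales(y, levels=4)
        self.w2 = scales[1]   # scale 4: QRS band
        self.w4 = scales[3]   # scale 16: T band
        self.n = y.size

    def _to_internal(self, idx: int) -> int:
        return int(round(idx * self.ratio))

    def _to_original(self, idx: float) -> int:
        return int(round(idx / self.ratio))

    def delineate_beat(self, r_peak: int, rr_ms: float,
                       next_rr_ms: float | None = None) -> BeatFiducials | None:
        r = self._to_internal(r_peak)
        onset = self._qrs_onset(r)
        offset = self._t_offset(r, rr_ms, next_rr_ms)
        if onset is None or offset is None:
            return None
        onset_o = self._to_original(onset)
        offset_o = self._to_original(offset)
        if not (onset_o < r_peak < offset_o):
            return None
        qt = (offset_o - onset_o) / self.rec.fs * 1000.0
        if not (QT_EVALUABLE_MS[0] <= qt <= QT_EVALUABLE_MS[1]):
            return None
        return BeatFiducials(r_peak=int(r_peak), qrs_onset=onset_o, t_offset=offset_o)

    def _qrs_onset(self, r: int) -> int | None:
        cfg = self.config
        half = int(round(cfg.qrs_halfwin_ms / 1000.0 * _FS_INTERNAL))
        cap = r - int(round(cfg.qrs_onset_cap_ms / 1000.0 * _FS_INTERNAL))
        lo, hi = max(0, r - half), min(self.n, r + half + 1)
        if hi - lo < 3:
            return None
        seg = np.abs(self.w2[lo:hi])
        a_max = float(seg.max())
        if a_max <= 0:
            return None
        # leftmost significant modulus maximum of the QRS complex
        mm = _local_maxima(seg)
        mm = mm[seg[mm] >= cfg.gamma_sig * a_max]
        mm = mm[mm + lo >= cap]
        if mm.size == 0:
            return None
        start = lo + int(mm[0])
        thr = cfg.gamma_on * a_max
        w = self.w2
        sign0 = np.sign(w[start]) or 1.0
        j = start
        while j > max(cap, 0):
            if np.sign(w[j - 1]) not in (sign0, 0.0):
                return float(j - 1)
            if abs(w[j - 1]) < thr:
                # sub-sample crossing of the threshold between j-1 and j
                a, b = abs(w[j - 1]), abs(w[j])
                frac = (thr - a) / (b - a) if b > a else 0.0
                return j - 1 + float(frac)
            j -= 1
        return float(max(cap, 0))

    def _t_offset(self, r: int, rr_ms: float,
                  next_rr_ms: float | None = None) -> int | None:
        cfg = self.config
        fs = _FS_INTERNAL
        lo = r + int(round(cfg.t_window_min_ms / 1000.0 * fs))
        hi_ms = min(0.7 * rr_ms, cfg.t_window_max_ms)
        if next_rr_ms is not None:
            # never search into the next beat's P wave
            hi_ms = min(hi_ms, next_rr_ms - 220.0)
        hi = r + int(round(hi_ms / 1000.0 * fs))
        hi = min(hi, self.n)
        if hi - lo < 5:
            return None
        seg = np.abs(self.w4[lo:hi])
        a_max = float(seg.max())
        med = float(np.median(seg))
        if a_max <= 0 or a_max < cfg.t_energy_ratio * med:
            return None
        mm = _local_maxima(seg)
        mm = mm[seg[mm] >= cfg.gamma_t * a_max]
        if mm.size == 0:
            return None
        # T peak: zero crossing of W4 between opposite-sign modulus maxima
        w = self.w4
        zc = None
        for a, b in zip(mm[:-1], mm[1:]):
            if np.sign(w[lo + a]) != np.sign(w[lo + b]):
                cross = np.flatnonzero(np.diff(np.sign(w[lo + a: lo + b + 1])) != 0)
                if cross.size:
                    zc = lo + a + int(cross[0])
        if zc is None:
            return None
        # last significant modulus maximum after the T-peak zero crossing
        after = mm[lo + mm > zc]
        if after.size == 0:
            return None
        last = lo + int(after[-1])
        peak_val = abs(w[last])
        thr = cfg.gamma_t * peak_val
        # scan right; allow a short overrun past the window for the decay
        limit = min(self.n, hi + int(round(0.1 * fs)))
        j = last
        while j + 1 < limit:
            j += 1
            if abs(w[j]) < thr:
                # sub-sample crossing between j-1 and j
                a, b = abs(w[j - 1]), abs(w[j])
                frac = (a - thr) / (a - b) if a > b else 1.0
                return j - 1 + float(frac)
        return None


def delineate_beat(rec: ECGRecord, r_peak: int, rr_ms: float,
                   next_rr_ms: float | None = None,
                   config: DelineationConfig | None = None) -> BeatFiducials | None:
    """Delineate a single beat; ``None`` marks it unevaluable."""
    return _RecordDelineator(rec, config).delineate_beat(r_peak, rr_ms, next_rr_ms)


def delineate_record(rec: ECGRecord, peaks: RPeakList,
                     config: DelineationConfig | None = None
                     ) -> tuple[AnnotationSet, DelineationSummary]:
    """Delineate every interior beat of a record.

    The first and last detected beats are skipped (incomplete
    neighbourhoods at the record edges).  Raises
    :class:`RecordUnevaluableError` when fewer than three beats can be
    delineated — the record cannot support a QTc diagnosis.
    """
    if len(peaks) < 3:
        raise InsufficientBeatsError(
            f"need at least 3 detected beats to delineate a record, got {len(peaks)}"
        )
    rr = rr_intervals(peaks)
    deli = _RecordDelineator(rec, config)
    beats: list[BeatFiducials] = []
    total = len(peaks) - 2
    for i in range(1, len(peaks) - 1):
        fid = deli.delineate_beat(int(peaks.indices[i]), float(rr[i - 1]),
                                  next_rr_ms=float(rr[i]))
        if fid is not None:
            beats.append(fid)
    summary = DelineationSummary(total=total, evaluable=len(beats),
                                 unevaluable=total - len(beats))
    if len(beats) < 3:
        raise RecordUnevaluableError(
            f"only {len(beats)} of {total} beats evaluable; at least 3 required"
        )
    return AnnotationSet(beats=beats, source=AnnotationSource.DELINEATOR), summary
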