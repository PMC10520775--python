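import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from qtcdx import (AnnotationSet, BeatFiducials, ECGRecord, build_overlay,
                   compute_qtc_result, detect_rpeaks, fridericia)
from qtcdx.detect import RPeakList
from qtcdx.errors import OverlayError, ParameterError, RecordUnevaluableError
from qtcdx.synth import beat_template


def _annotations(fs, qt_samples, spacing):
    """Evenly spaced beats with the given per-beat QT in samples."""
    beats = []
    r = 1000
    for q in qt_samples:
        beats.append(BeatFiducials(r_peak=r, qrs_onset=r - 20, t_offset=r - 20 + q))
        r += spacing
    return AnnotationSet(beats=beats)


class TestFridericia:
    def test_identity_at_1s_rr(self):
        assert fridericia(400.0, 1000.0) == pytest.approx(400.0)

    @pytest.mark.parametrize("qt,rr,expected", [
        (380.0, 800.0, 409.34),   # 380 / 0.8^(1/3), 0.8^(1/3)=0.928318
        (300.0, 600.0, 355.69),   # 300 / 0.6^(1/3), 0.6^(1/3)=0.843433
    ])
    def test_hand_oracle(self, qt, rr, expected):
        assert fridericia(qt, rr) == pytest.approx(expected, abs=0.01)

    def test_nonpositive_rejected(self):
        for qt, rr in [(0, 1000), (400, 0), (-5, 800)]:
            with pytest.raises(ParameterError):
                fridericia(qt, rr)

    @given(qt=st.floats(200, 700), rr=st.floats(300, 2000))
    @settings(max_examples=100, derandomize=True)
    def test_monotone_in_both_arguments(self, qt, rr):
        assert fridericia(qt + 10, rr) > fridericia(qt, rr)
        assert fridericia(qt, rr + 50) < fridericia(qt, rr)


class TestComputeQtc:
    def test_identical_beats_zero_sd(self):
        ann = _annotations(500, [200, 200, 200], spacing=500)  # QT 400 ms, RR 1000
        res = compute_qtc_result(ann, ECGRecord(np.zeros(5000), 500))
        assert res.qt_sd_ms == 0.0
        assert res.qtcf_mean_ms == pytest.approx(400.0)
        assert res.bpm == pytest.approx(60000.0 / res.rr_mean_ms, rel=1e-6)

    def test_sample_sd_of_three(self):
        ann = _annotations(500, [195, 200, 205], spacing=500)  # 390/400/410 ms
        res = compute_qtc_result(ann, ECGRecord(np.zeros(5000), 500))
        assert res.qt_sd_ms == pytest.approx(10.0)
        assert res.qtcf_mean_ms == pytest.approx(400.0)
        assert res.n_beats_used == 3

    def test_requires_three_beats(self):
        ann = _annotations(500, [200, 200], spacing=500)
        with pytest.raises(RecordUnevaluableError):
            compute_qtc_result(ann, ECGRecord(np.zeros(5000), 500))

    def test_implausible_rr_excluded(self):
        # one beat after a double-length gap (missed detection in between)
        beats = [BeatFiducials(r, r - 20, r + 180)
                 for r in (1000, 1500, 2000, 3000, 3500)]
        res = compute_qtc_result(AnnotationSet(beats=beats),
                                 ECGRecord(np.zeros(6000), 500))
        assert res.n_beats_rr_excluded == 1
        assert res.n_beats_used == 4

    def test_synthetic_qtcf_recovery(self, clean_record, clean_peaks):
        rec, _ = clean_record
        from qtcdx import delineate_record
        ann, _ = delineate_record(rec, clean_peaks)
        res = compute_qtc_result(ann, rec)
        assert res.qtcf_mean_ms == pytest.approx(400.0, abs=12.0)


class TestOverlay:
    def test_identical_beats_zero_sd(self, clean_record, clean_peaks):
        rec, _ = clean_record
        ov = build_overlay(rec, clean_peaks)
        assert ov.n_beats >= 8
        assert np.max(ov.sd_cycle) < 1e-9

    def test_antisymmetric_beats_zero_mean(self):
        sig = np.zeros(5000)
        t = np.arange(-150, 251)
        bump = np.exp(-0.5 * (t / 30.0) ** 2)
        sig[1000 - 150:1000 + 251] = bump
        sig[3000 - 150:3000 + 251] = -bump
        rec = ECGRecord(signal=sig, fs=500, record_id="pm")
        ov = build_overlay(rec, RPeakList(indices=np.array([1000, 3000]), fs=500))
        assert np.max(np.abs(ov.mean_cycle)) < 1e-12

    def test_mean_cycle_matches_template(self, clean_record, clean_peaks):
        rec, truth = clean_record
        ov = build_overlay(rec, clean_peaks)
        template = beat_template(ov.time_ms, truth.qt_nominal_ms)
        r = np.corrcoef(ov.mean_cycle, template)[0, 1]
        assert r > 0.99

    def test_out_of_range_beats_counted(self, clean_record):
        rec, _ = clean_record
        peaks = RPeakList(indices=np.array([50, 2000, 4000]), fs=500)
        ov = build_overlay(rec, peaks)   # first window starts before sample 0
        assert ov.n_excluded == 1
        assert ov.n_beats == 2

    def test_too_few_beats(self, clean_record):
        rec, _ = clean_record
        with pytest.raises(OverlayError):
            build_overlay(rec, RPeakList(indices=np.array([100, 2000]), fs=500))
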