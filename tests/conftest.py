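import numpy as np
import pytest

from qtcdx import SynthParams, detect_rpeaks, generate_ecg


@pytest.fixture(scope="session")
def clean_record():
    """10 s, 60 bpm, QT 400 ms, no jitter/noise/wander: every quantity exact."""
    params = SynthParams(duration_s=10, hr_bpm=60, qt_ms=400, rr_jitter_ms=0,
                         noise_mv=0, wander_mv=0, fs=500, seed=1)
    return generate_ecg(params)


@pytest.fixture(scope="session")
def noisy_record():
    """30 s, 75 bpm with jitter and noise: realistic detection conditions."""
    params = SynthParams(duration_s=30, hr_bpm=75, qt_ms=380, rr_jitter_ms=20,
                         noise_mv=0.05, wander_mv=0.05, fs=500, seed=3)
    return generate_ecg(params)


@pytest.fixture(scope="session")
def clean_peaks(clean_record):
    rec, _ = clean_record
    return detect_rpeaks(rec)


def match_counts(detected: np.ndarray, truth: np.ndarray, tol: int):
    """Greedy fiducial matching: true positives within ``tol`` samples."""
    tp = sum(1 for t in truth if detected.size and np.min(np.abs(detected - t)) <= tol)
    fp = sum(1 for d in detected if truth.size and np.min(np.abs(truth - d)) > tol)
    return tp, fp
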