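# Methods

This note documents the models and numerical choices behind `qtcdx`:
what each stage computes, which parameters matter, what the synthetic
generator does and does not emulate, and the known limits of the
pipeline.

## Signal model and conventions

A record is a uniformly sampled single-lead voltage series in mV with a
sampling rate in [100, 2000] Hz (handheld two-electrode devices record
lead I at a few hundred Hz; the reader accepts the whole plausible range
rather than assuming a device constant). Sample indices are 0-based,
times are seconds, intervals are reported in ms. Gaps (NaN) are an
input error — the pipeline never imputes. Records shorter than 2 s are
rejected at analysis entry.

## R-peak detection

A Pan–Tompkins-style pipeline: zero-phase Butterworth band-pass
5–15 Hz, first difference, squaring, 150 ms moving-window integration,
then adaptive dual-threshold peak classification (signal/noise running
estimates with 1/8 update weight, threshold = noise + 0.25·(signal −
noise)), a 200 ms refractory period, and a searchback at half threshold
when a gap exceeds 1.66× the running RR mean. Accepted peaks are
refined to the raw-signal maximum within ±50 ms. Candidates in the
first and last 0.3 s are excluded (zero-phase filtering still leaves
edge transients; 0.3 s clears them at every supported rate while
keeping early beats detectable).

Two slope rules suppress non-QRS waves, both using the steepest raw
slope within ±40 ms of a candidate:

* a candidate within max(360 ms, 0.7·mean recent RR) of the previous
  beat with under half its slope is a T wave (the classic criterion,
  with the window widened at fast rates where a long-QT T wave trails
  the QRS by more than 360 ms);
* any candidate with under 40 % of the running QRS-slope estimate is
  vetoed outright. QRS complexes are defined by their steep slope —
  T and P waves here reach at most ~15 % of the R slope — and this
  veto is what keeps the adaptive thresholds from locking onto T waves
  on records where the first beats are ambiguous. Rejected waves do
  not update the noise estimate: their energy is far above baseline
  noise and would otherwise inflate the threshold past genuine beats.

All thresholds are relative, so detection is invariant under positive
amplitude scaling. A flat or empty record yields zero peaks, not an
error.

## Wavelet delineation

QT boundaries are located on the dyadic stationary wavelet transform
with the quadratic-spline mother (à-trous filter pair h = [1,3,3,1]/8,
g = [2,−2]), the standard construction in ECG delineation: each scale
is a smoothed derivative, so wave peaks are zero crossings between
modulus-maximum (mm) pairs and wave boundaries are the flanks of mm's.
Analysis runs at 250 Hz — records at other rates are polyphase-resampled
internally so the dyadic scales keep their frequency meaning — and
fiducials are mapped back to the record's own grid. Equivalent filters
have half-integer group delays (2^k − 1.5 samples at level k); outputs
are aligned by integer slicing plus half-sample linear interpolation,
and threshold crossings are located with sub-sample interpolation
before rounding, which removes roughly 4 ms of systematic late bias
that integer quantization would otherwise add.

Per beat, with R from the detector:

* **QRS onset** — in a ±60 ms window around R on the scale-4 transform
  (W2), find the leftmost modulus maximum exceeding `gamma_sig` = 0.06
  of the window maximum (this is the Q-wave flank when a Q wave exists,
  the R upslope otherwise), then scan left until |W2| falls below
  `gamma_on` = 0.05 of the window maximum or the transform crosses
  zero, capped at 80 ms before R. Scanning from the first *significant*
  mm of the complex, rather than from the R-associated pair itself,
  is what handles Q waves: a scan from the R upslope would stop at the
  Q-trough zero crossing and clip the onset.
* **T offset** — in a window from R+100 ms to
  R + min(0.7·RR, 600 ms, RR_next − 220 ms) on the scale-16 transform
  (W4): require T energy (window max ≥ 4× window median of |W4|),
  locate the T peak as the zero crossing between opposite-sign mm's,
  take the last mm above `gamma_t` = 0.25 of the window maximum after
  that crossing (a biphasic T's later component then defines the
  offset), and place the offset at the sub-sample point where |W4|
  decays below `gamma_t` times that mm. The RR_next − 220 ms cap keeps
  the search out of the next beat's P wave, which at fast rates enters
  the 0.7·RR window and would otherwise masquerade as a late T
  component.

Beats failing the energy test, with inverted fiducial order, or with QT
outside 200–700 ms are unevaluable. Record-level delineation skips the
first and last detected beats (incomplete neighbourhoods) and requires
at least three evaluable beats, else the record is unevaluable — the
operationalization of "non-evaluable" used throughout; pure-noise
records fail it.

All delineation thresholds are exposed in `DelineationConfig`.

## QT/QTc aggregation

Each evaluable beat is corrected with its own preceding RR (the first,
which has none, uses its following RR — the convention that keeps every
evaluable beat correctable); the record QTcF is the arithmetic mean of
per-beat QTcF values rather than the Fridericia correction of the mean
QT — at normal RR variability the two differ only in second order. QT
SD uses the n−1 sample denominator. Beats whose RR falls outside
0.5–1.5× the median RR are excluded from the averages and counted
(guards against missed or doubled detections turning one bad interval
into a biased mean). The cycle overlay aligns beats on R over a
(−300, +500) ms window and reports the pointwise mean and population
SD; beats whose window leaves the record are excluded and counted.

## Grading, risk, and reports

CTCAE v5.0 states its QTc bands on integer ms, leaving (480, 481) ms
undefined for real-valued inputs; the grade-1 band is taken as
[450, 481) so every positive value maps to exactly one grade, which an
exhaustive sweep verifies. The >60 ms baseline rule counts increases
only, and uses a strict inequality. Grade 4 is an external clinical
flag — nothing in a single-lead QT measurement identifies TdP. Band
edges are configurable but overriding them logs a prominent warning,
since the defaults *are* the published definition.

TdP relative risk compounds 5–7 % per 10 ms:
(1+p)^((QTc−440)/10) − 1, defined for QTc at or above the reference;
the risk factor is multiplicative over increments by construction.

A finalized report is sealed: attribute assignment raises, and a
SHA-256 hash over the canonical serialization (sorted keys, ms values
rounded to 2 decimals, UTC ISO-8601 timestamp) is stored and
re-verified on load, so post-hoc edits of a stored report are detected
rather than silently accepted. Identical inputs plus an explicit
finalization timestamp give byte-identical reports.

## Synthetic generator

Each beat is a sum of five Gaussian bumps. Centres relative to R:
P −180 ms, Q −24 ms, R 0, S +24 ms; amplitudes 0.15 / −0.10 / 1.0 /
−0.15 / 0.30 mV; widths (as ≈6σ total durations) 80 / 20 / 24 / 20 /
120 ms, chosen as typical adult surface-ECG wave durations. QRS onset
is defined as 3σ before the Q centre and T offset as 3σ after the T
centre; the T centre and width (scaled linearly with QT) are placed so
that offset − onset equals the requested QT exactly before corruption.
RR intervals are 60000/HR plus clipped-at-±3σ Gaussian jitter; noise
and sinusoidal baseline wander are added only after the fiducials are
fixed, so ground truth is corruption-invariant by construction. The
first beat starts 0.4 s into the record and the last must finish at
least 350 ms before its end, keeping every truth beat inside the
detector's working region. Defaults (30 s, 60 bpm, QT 400 ms, 20 ms RR
jitter, 0.02 mV noise, 0.05 mV wander at 0.3 Hz, 500 Hz, seeded RNG)
emulate a calm resting recording on a handheld device.

What the generator does *not* emulate — and hence what passing tests do
not show about real data: real T-wave morphology variants (flat,
notched, inverted), U waves, ectopic and aberrant beats, atrial
fibrillation, electrode motion artifacts, mains interference, and
device-specific filtering. Validation on the generator demonstrates
correctness of the computation under its stated model, not clinical
accuracy on device recordings.

## Validation conditions and known limits

The parameter-recovery suite uses twenty 30 s records spanning
50–90 bpm × QT 340–500 ms with 20 ms jitter and 0.02 mV noise — sizes
chosen so the full suite exercises every heart-rate/QT combination while
each record still contains ≥20 beats. On this grid the detector reaches
sensitivity and positive predictive value of 1.0 and the measured mean
QTcF lands within 12 ms of ground truth on at least 18 of 20 records
across seed families.

Known limits:

* The fastest-rate/longest-QT corner (90 bpm with QT ≥ 460 ms) is
  where the T wave runs into the next beat's P wave; the T search
  window is then truncated and QT is underestimated by ~15–20 ms, or
  the record becomes unevaluable. This T–P fusion regime is a genuine
  limitation of offset-by-threshold delineation, not only of the
  synthetic model.
* The offset definition (decay below 0.25 of the last mm) measures a
  slightly different quantity than the generator's analytic 3σ truth;
  the residual bias is about +9 ms at QT 340 ms, shrinking to ≈0 near
  QT 500 ms.
* Grading reproduces exactly the published band summary; the full
  CTCAE text attaches clinical qualifiers that no signal computation
  can evaluate.
* Turnaround confidence intervals default to the normal approximation
  (mean ± 1.96·SE); a Student-t variant is available via
  `mean_ci(..., method="t")`. Published summary intervals of this kind
  rarely state their construction, so neither variant is claimed as
  "the" reference method.
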