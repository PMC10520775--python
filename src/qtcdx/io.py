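"""Reading and writing single-lead ECG records and fiducial annotations.

Two on-disk signal formats are supported:

* a two-column CSV ``time_s,voltage_mV`` (header optional on read,
  always written), comma separated, dot decimal;
* a WFDB header/data pair (``.hea`` + ``.dat``), signal format 16
  (16-bit little-endian two's complement).  Only the subset of the WFDB
  header needed for a plain digitized signal is handled here; gain and
  baseline are honoured so physical units round-trip to one LSB.

Annotations travel as a TSV with one row per beat:
``r_peak<TAB>qrs_onset<TAB>t_offset`` (0-based sample indices).
"""
from __future__ import annotations

import logging
import re
from pathlib import Path

import numpy as np
import pandas as pd

from .core import AnnotationSet, AnnotationSource, BeatFiducials, ECGRecord
from .errors import FormatError, NonUniformSamplingError, ParameterError

log = logging.getLogger(__name__)

#: digital resolution used when writing WFDB format 16: 1 LSB = 1 uV
_WFDB_GAIN = 1000.0
_ANN_HEADER = "r_peak\tqrs_onset\tt_offset"

_UNIT_TO_MV = {"mV": 1.0, "mv": 1.0, "uV": 1e-3, "uv": 1e-3, "V": 1e3, "v": 1e3}


def read_ecg(path: str | Path, format: str | None = None) -> ECGRecord:
    """Read a single-lead ECG record.

    Parameters
    ----------
    path
        CSV file, or WFDB record path (with or without the ``.hea``
        extension).
    format
        ``"csv"`` or ``"wfdb"``; inferred from the file extension when
        omitted.
    """
    path = Path(path)
    if format is None:
        format = "csv" if path.suffix.lower() == ".csv" else "wfdb"
    if format == "csv":
        return _read_csv(path)
    if format == "wfdb":
        return _read_wfdb(path)
    raise ParameterError(f"unknown format {format!r}; expected 'csv' or 'wfdb'")


def write_ecg(rec: ECGRecord, path: str | Path, format: str | None = None) -> None:
    """Write ``rec`` so that :func:`read_ecg` recovers it.

    Sampling rate round-trips exactly; voltages round-trip to the
    declared amplitude resolution (float formatting for CSV, 1 uV for
    WFDB format 16).
    """
    path = Path(path)
    if format is None:
        format = "csv" if path.suffix.lower() == ".csv" else "wfdb"
    if format == "csv":
        _write_csv(rec, path)
    elif format == "wfdb":
        _write_wfdb(rec, path)
    else:
        raise ParameterError(f"unknown format {format!r}; expected 'csv' or 'wfdb'")


# ---------------------------------------------------------------------------
# CSV

def _read_csv(path: Path) -> ECGRecord:
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path, header=None, comment="#")
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise FormatError(f"could not parse {path}: {exc}") from exc
    # optional header row
    if df.shape[1] < 2:
        raise FormatError(f"{path}: expected two columns (time_s, voltage_mV)")
    first = df.iloc[0]
    if isinstance(first.iloc[0], str) and not _is_number(first.iloc[0]):
        df = df.iloc[1:]
    try:
        t = df.iloc[:, 0].astype(float).to_numpy()
        v = df.iloc[:, 1].astype(float).to_numpy()
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric data: {exc}") from exc
    if t.size < 2:
        raise FormatError(f"{path}: need at least two samples")
    dt = np.diff(t)
    med = float(np.median(dt))
    if med <= 0:
        raise NonUniformSamplingError(f"{path}: time column is not increasing")
    tol = max(1e-6, 1e-3 * med)
    if np.any(np.abs(dt - med) > tol):
        worst = int(np.argmax(np.abs(dt - med)))
        raise NonUniformSamplingError(
            f"{path}: non-uniform sampling (delta {dt[worst]:.6g} s at row {worst + 1} "
            f"vs median {med:.6g} s)"
        )
    return ECGRecord(signal=v, fs=1.0 / med, record_id=path.stem)


def _is_number(s: str) -> bool:
    try:
        float(s)
        return True
    except (TypeError, ValueError):
        return False


def _write_csv(rec: ECGRecord, path: Path) -> None:
    t = np.arange(rec.n_samples) / rec.fs
    df = pd.DataFrame({"time_s": t, "voltage_mV": rec.signal})
    df.to_csv(path, index=False, float_format="%.9g")


# ---------------------------------------------------------------------------
# WFDB (format 16 subset)

def _read_wfdb(path: Path) -> ECGRecord:
    hea = path if path.suffix == ".hea" else path.with_suffix(".hea")
    if not hea.exists():
        raise FileNotFoundError(hea)
    lines = [
        ln.strip() for ln in hea.read_text().splitlines()
        if ln.strip() and not ln.startswith("#")
    ]
    head = lines[0].split()
    record_name = head[0]
    n_sig = int(head[1])
    fs = float(head[2]) if len(head) > 2 else 250.0
    if n_sig < 1:
        raise FormatError(f"{hea}: record has no signal channels")
    if n_sig > 1:
        log.warning("%s: %d channels present; using the first (single-lead analysis)",
                    hea.name, n_sig)
    sig_lines = lines[1:1 + n_sig]
    if len(sig_lines) < n_sig:
        raise FormatError(f"{hea}: header declares {n_sig} signals but lists {len(sig_lines)}")

    spec0 = sig_lines[0].split()
    dat_name, fmt = spec0[0], spec0[1]
    if fmt.split("x")[0] != "16":
        raise FormatError(f"{hea}: unsupported WFDB signal format {fmt!r} (only 16)")
    gain, baseline, units = _parse_gain(spec0[2] if len(spec0) > 2 else "200")
    lead = spec0[8] if len(spec0) > 8 else "I"

    dat = hea.parent / dat_name
    if not dat.exists():
        raise FileNotFoundError(dat)
    raw = np.fromfile(dat, dtype="<i2")
    if n_sig > 1:
        raw = raw.reshape(-1, n_sig)[:, 0]
    scale = _UNIT_TO_MV.get(units, 1.0)
    signal = (raw.astype(float) - baseline) / gain * scale
    return ECGRecord(signal=signal, fs=fs, record_id=record_name, lead_label=lead)


def _parse_gain(token: str) -> tuple[float, float, str]:
    """Parse WFDB 'gain(baseline)/units' with all parts optional."""
    m = re.match(r"^([0-9.eE+-]+)?(\(([-0-9]+)\))?(/(\S+))?$", token)
    if not m:
        raise FormatError(f"bad WFDB gain specification {token!r}")
    gain = float(m.group(1)) if m.group(1) else 200.0
    if gain == 0:
        gain = 200.0
    baseline = float(m.group(3)) if m.group(3) else 0.0
    units = m.group(5) or "mV"
    return gain, baseline, units


def _write_wfdb(rec: ECGRecord, path: Path) -> None:
    base = path.with_suffix("") if path.suffix == ".hea" else path
    name = base.name
    digital = np.round(rec.signal * _WFDB_GAIN)
    if np.any(np.abs(digital) > 32767):
        raise ParameterError("signal exceeds the dynamic range of WFDB format 16 at 1 uV/LSB")
    digital = digital.astype("<i2")
    checksum = int(np.sum(digital.astype(np.int64)) & 0xFFFF)
    if checksum >= 0x8000:
        checksum -= 0x10000
    first = int(digital[0]) if digital.size else 0
    hea = (
        f"{name} 1 {rec.fs:g} {rec.n_samples}\n"
        f"{name}.dat 16 {_WFDB_GAIN:g}(0)/mV 16 0 {first} {checksum} 0 {rec.lead_label}\n"
    )
    base.with_suffix(".hea").write_text(hea)
    digital.tofile(base.with_suffix(".dat"))


# ---------------------------------------------------------------------------
# Annotations

def write_annotations(ann: AnnotationSet, path: str | Path) -> None:
    """Write fiducials as a TSV (header + one row per beat)."""
    path = Path(path)
    rows = [_ANN_HEADER]
    rows += [f"{b.r_peak}\t{b.qrs_onset}\t{b.t_offset}" for b in ann.beats]
    path.write_text("\n".join(rows) + "\n")


def read_annotations(path: str | Path,
                     source: AnnotationSource = AnnotationSource.DELINEATOR) -> AnnotationSet:
    """Read a fiducial TSV written by :func:`write_annotations`.

    Raises :class:`FormatError` naming the offending line on malformed
    rows; fiducial-ordering violations surface as
    :class:`~qtcdx.errors.ParameterError` from :class:`BeatFiducials`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    beats: list[BeatFiducials] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line or lineno == 1 and line.replace(" ", "") == _ANN_HEADER.replace("\t", ""):
            continue
        if lineno == 1 and not line[0].isdigit():
            continue  # header
        parts = line.split("\t")
        if len(parts) != 3:
            raise FormatError(f"{path}:{lineno}: expected 3 tab-separated fields, got {len(parts)}")
        try:
            r, on, off = (int(p) for p in parts)
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: non-integer index: {exc}") from exc
        try:
            beats.append(BeatFiducials(r_peak=r, qrs_onset=on, t_offset=off))
        except ParameterError as exc:
            raise ParameterError(f"{path}:{lineno}: {exc}") from exc
    return AnnotationSet(beats=beats, source=source)
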