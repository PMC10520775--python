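"""Immutable diagnostic reports and the diagnosis status colour code.

Once finalized, a report cannot be modified: attribute assignment
raises, and the canonical JSON serialization carries a SHA-256 content
hash that is re-verified on load, so any tampering with a stored report
is detected.  This realizes, at library level, the clinical requirement
that a submitted diagnostic report can never change afterwards.
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from enum import Enum
from pathlib import Path

from .errors import AlreadyFinalizedError, ImmutabilityError, IntegrityError, ParameterError
from .grading import CTCAEDiagnosis, GradeRule, QtcStatus
from .qtc import QTcResult


class StatusColor(str, Enum):
    """Diagnosis status colour: gray while pending, then green for
    grade 0, orange for grade 1, red for grade 2 or higher."""

    GRAY = "gray"
    GREEN = "green"
    ORANGE = "orange"
    RED = "red"


def status_color(diagnosis: CTCAEDiagnosis | None) -> StatusColor:
    """Colour code for a (possibly still pending) diagnosis."""
    if diagnosis is None:
        return StatusColor.GRAY
    if diagnosis.grade == 0:
        return StatusColor.GREEN
    if diagnosis.grade == 1:
        return StatusColor.ORANGE
    return StatusColor.RED


class DiagnosticReport:
    """Diagnosis artifact; mutable as a draft, sealed by :func:`finalize_report`."""

    _MUTABLE_WHILE_DRAFT = {"comment", "patient_id"}

    def __init__(self, patient_id: str, record_id: str, result: QTcResult,
                 diagnosis: CTCAEDiagnosis, comment: str | None = None):
        object.__setattr__(self, "finalized", False)
        self.patient_id = patient_id
        self.record_id = record_id
        self.result = result
        self.diagnosis = diagnosis
        self.comment = comment
        self.created_at: str | None = None
        self.content_hash: str | None = None

    def __setattr__(self, name, value):
        if getattr(self, "finalized", False):
            raise ImmutabilityError(
                f"report is finalized; cannot set {name!r}"
            )
        object.__setattr__(self, name, value)

    # -- serialization ----------------------------------------------------

    def _payload(self) -> dict:
        return {
            "patient_id": self.patient_id,
            "record_id": self.record_id,
            "result": self.result.to_dict(),
            "diagnosis": self.diagnosis.to_dict(),
            "status_color": status_color(self.diagnosis).value,
            "comment": self.comment,
            "created_at": self.created_at,
        }

    def canonical_json(self) -> str:
        """Canonical serialization: sorted keys, fixed separators, ms
        values rounded to 2 decimals — stable across platforms."""
        return json.dumps(self._payload(), sort_keys=True, separators=(",", ":"),
                          ensure_ascii=True, allow_nan=False)

    def to_json(self) -> str:
        body = self._payload()
        body["content_hash"] = self.content_hash
        return json.dumps(body, sort_keys=True, indent=2)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json() + "\n")

    def render_text(self) -> str:
        """Human-readable report."""
        d, r = self.diagnosis, self.result
        lines = [
            "QTc diagnostic report",
            "=====================",
            f"patient:        {self.patient_id}",
            f"record:         {self.record_id}",
            f"created (UTC):  {self.created_at or 'draft'}",
            "",
            f"beats used:     {r.n_beats_used} (RR-excluded: {r.n_beats_rr_excluded})",
            f"mean QT:        {r.qt_mean_ms:.1f} ms (SD {r.qt_sd_ms:.1f} ms)",
            f"mean RR:        {r.rr_mean_ms:.1f} ms  ({r.bpm:.1f} bpm)",
            f"mean QTcF:      {r.qtcf_mean_ms:.1f} ms",
            "",
            f"CTCAE grade:    {d.grade} ({d.triggered_rule.value})",
            f"status colour:  {status_color(d).value}",
        ]
        if d.delta_ms is not None:
            lines.append(f"baseline delta: {d.delta_ms:+.1f} ms")
        if d.status is not None:
            lines.append(f"sex status:     {d.status.value}")
        if self.comment:
            lines += ["", f"comment: {self.comment}"]
        if self.content_hash:
            lines += ["", f"content hash: {self.content_hash}"]
        return "\n".join(lines)


def finalize_report(draft: DiagnosticReport,
                    created_at: datetime | None = None) -> DiagnosticReport:
    """Seal a draft report: timestamp it, hash it, and freeze it.

    Raises :class:`AlreadyFinalizedError` if called twice on the same
    report.  After sealing, every attribute assignment raises
    :class:`ImmutabilityError`.
    """
    if draft.finalized:
        raise AlreadyFinalizedError("report is already finalized")
    if draft.result is None or draft.diagnosis is None:
        raise ParameterError("a report needs both a QTcResult and a CTCAEDiagnosis")
    ts = (created_at or datetime.now(timezone.utc)).astimezone(timezone.utc)
    draft.created_at = ts.isoformat(timespec="seconds")
    draft.content_hash = hashlib.sha256(draft.canonical_json().encode()).hexdigest()
    object.__setattr__(draft, "finalized", True)
    return draft


def load_report(path: str | Path) -> DiagnosticReport:
    """Load a finalized report, verifying its content hash.

    Raises :class:`IntegrityError` when any field was altered after
    finalization.
    """
    body = json.loads(Path(path).read_text())
    stored_hash = body.pop("content_hash", None)
    if stored_hash is None:
        raise IntegrityError(f"{path}: missing content hash")

    res = body["result"]
    import numpy as np
    result = QTcResult(
        qt_ms_per_beat=np.array(res["qt_ms_per_beat"], dtype=float),
        qt_mean_ms=res["qt_mean_ms"], qt_sd_ms=res["qt_sd_ms"],
        rr_mean_ms=res["rr_mean_ms"], bpm=res["bpm"],
        qtcf_per_beat=np.empty(0),
        qtcf_mean_ms=res["qtcf_mean_ms"],
        n_beats_used=res["n_beats_used"],
        n_beats_rr_excluded=res.get("n_beats_rr_excluded", 0),
    )
    dia = body["diagnosis"]
    diagnosis = CTCAEDiagnosis(
        grade=dia["grade"], triggered_rule=GradeRule(dia["triggered_rule"]),
        delta_ms=dia["delta_ms"],
        status=None if dia["status"] is None else QtcStatus(dia["status"]),
    )
    report = DiagnosticReport(patient_id=body["patient_id"], record_id=body["record_id"],
                              result=result, diagnosis=diagnosis, comment=body["comment"])
    report.created_at = body["created_at"]
    report.content_hash = stored_hash
    recomputed = hashlib.sha256(report.canonical_json().encode()).hexdigest()
    if recomputed != stored_hash:
        raise IntegrityError(f"{path}: content hash mismatch — report was modified")
    object.__setattr__(report, "finalized", True)
    return report
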