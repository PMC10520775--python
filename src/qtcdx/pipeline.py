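"""End-to-end convenience: raw record in, finalized diagnostic report out."""
from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime

from .core import AnnotationSet, ECGRecord
from .delineate import DelineationConfig, DelineationSummary, delineate_record
from .detect import RPeakList, detect_rpeaks
from .grading import CTCAEDiagnosis, GradingInput, Sex, ctcae_grade
from .qtc import QTcResult, compute_qtc_result
from .report import DiagnosticReport, finalize_report


@dataclass
class AnalysisResult:
    peaks: RPeakList
    annotations: AnnotationSet
    summary: DelineationSummary
    qtc: QTcResult
    diagnosis: CTCAEDiagnosis


def analyze_record(rec: ECGRecord,
                   baseline_qtcf_ms: float | None = None,
                   sex: Sex | str | None = None,
                   tdp_or_serious_arrhythmia: bool = False,
                   config: DelineationConfig | None = None) -> AnalysisResult:
    """Run detection, delineation, QTc aggregation and CTCAE grading.

    Raises the pipeline's usual errors when the record cannot support a
    diagnosis (too few beats, too few evaluable cycles).
    """
    peaks = detect_rpeaks(rec)
    ann, summary = delineate_record(rec, peaks, config)
    qtc = compute_qtc_result(ann, rec)
    inp = GradingInput(
        qtcf_mean_ms=qtc.qtcf_mean_ms,
        baseline_qtcf_ms=baseline_qtcf_ms,
        tdp_or_serious_arrhythmia=tdp_or_serious_arrhythmia,
        sex=None if sex is None else Sex(sex),
    )
    return AnalysisResult(peaks=peaks, annotations=ann, summary=summary,
                          qtc=qtc, diagnosis=ctcae_grade(inp))


def diagnose(rec: ECGRecord,
             patient_id: str = "anonymous",
             comment: str | None = None,
             created_at: datetime | None = None,
             **kwargs) -> tuple[AnalysisResult, DiagnosticReport]:
    """Analyze a record and seal the result in a finalized report.

    Pass ``created_at`` to obtain byte-identical reports from identical
    inputs (the content hash covers the timestamp).
    """
    res = analyze_record(rec, **kwargs)
    draft = DiagnosticReport(patient_id=patient_id, record_id=rec.record_id,
                             result=res.qtc, diagnosis=res.diagnosis, comment=comment)
    return res, finalize_report(draft, created_at=created_at)
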