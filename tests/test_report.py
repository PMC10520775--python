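import json
from datetime import datetime, timezone

import numpy as np
import pytest

from qtcdx import (CTCAEDiagnosis, DiagnosticReport, QTcResult, StatusColor,
                   finalize_report, load_report, status_color)
from qtcdx.errors import AlreadyFinalizedError, ImmutabilityError, IntegrityError
from qtcdx.grading import GradeRule

TS = datetime(2024, 1, 1, 12, 0, tzinfo=timezone.utc)


def _result():
    return QTcResult(qt_ms_per_beat=np.array([398.0, 400.0, 402.0]),
                     qt_mean_ms=400.0, qt_sd_ms=2.0, rr_mean_ms=1000.0, bpm=60.0,
                     qtcf_per_beat=np.array([398.0, 400.0, 402.0]),
                     qtcf_mean_ms=400.0, n_beats_used=3)


def _report(grade=0, rule=GradeRule.NORMAL):
    return DiagnosticReport(patient_id="p-1", record_id="rec-1", result=_result(),
                            diagnosis=CTCAEDiagnosis(grade=grade, triggered_rule=rule))


class TestStatusColor:
    @pytest.mark.parametrize("grade,expected", [
        (0, StatusColor.GREEN), (1, StatusColor.ORANGE),
        (2, StatusColor.RED), (3, StatusColor.RED), (4, StatusColor.RED),
    ])
    def test_graded(self, grade, expected):
        rule = GradeRule.NORMAL if grade == 0 else GradeRule.TDP_ARRHYTHMIA
        assert status_color(CTCAEDiagnosis(grade=grade, triggered_rule=rule)) is expected

    def test_pending_is_gray(self):
        assert status_color(None) is StatusColor.GRAY


class TestFinalization:
    def test_draft_is_mutable(self):
        rep = _report()
        rep.comment = "sinus rhythm"
        assert rep.comment == "sinus rhythm"

    def test_finalized_rejects_mutation(self):
        rep = finalize_report(_report(), created_at=TS)
        with pytest.raises(ImmutabilityError):
            rep.comment = "changed my mind"

    def test_double_finalize_rejected(self):
        rep = finalize_report(_report(), created_at=TS)
        with pytest.raises(AlreadyFinalizedError):
            finalize_report(rep)

    def test_hash_is_deterministic(self):
        h1 = finalize_report(_report(), created_at=TS).content_hash
        h2 = finalize_report(_report(), created_at=TS).content_hash
        assert h1 == h2 and len(h1) == 64


class TestPersistence:
    def test_roundtrip_verifies(self, tmp_path):
        rep = finalize_report(_report(grade=1, rule=GradeRule.BAND_450_480),
                              created_at=TS)
        path = tmp_path / "rep.json"
        rep.save(path)
        back = load_report(path)
        assert back.content_hash == rep.content_hash
        assert back.diagnosis.grade == 1
        assert back.finalized

    def test_tampered_grade_detected(self, tmp_path):
        rep = finalize_report(_report(), created_at=TS)
        path = tmp_path / "rep.json"
        rep.save(path)
        body = json.loads(path.read_text())
        body["diagnosis"]["grade"] = 3
        path.write_text(json.dumps(body))
        with pytest.raises(IntegrityError):
            load_report(path)

    def test_loaded_report_is_sealed(self, tmp_path):
        rep = finalize_report(_report(), created_at=TS)
        path = tmp_path / "rep.json"
        rep.save(path)
        back = load_report(path)
        with pytest.raises(ImmutabilityError):
            back.patient_id = "someone-else"

    def test_text_rendering_mentions_key_quantities(self):
        rep = finalize_report(_report(), created_at=TS)
        text = rep.render_text()
        for needle in ("400.0 ms", "CTCAE grade", "green", rep.content_hash):
            assert needle in text
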