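"""Grade a set of worked QTcF values and show the TdP risk scaling.

No signal processing here: the grading layer is a pure function from an
average QTcF (plus optional baseline and arrhythmia flag) to a CTCAE
v5.0 grade, and the torsade-de-pointes risk compounds 5-7% per 10 ms of
QTc above a 440 ms reference.
"""
from qtcdx import GradingInput, ctcae_grade, sex_status, status_color, tdp_relative_risk

cases = [
    GradingInput(qtcf_mean_ms=440.0),
    GradingInput(qtcf_mean_ms=465.0),
    GradingInput(qtcf_mean_ms=490.0),
    GradingInput(qtcf_mean_ms=505.0),
    GradingInput(qtcf_mean_ms=470.0, baseline_qtcf_ms=400.0),
    GradingInput(qtcf_mean_ms=420.0, tdp_or_serious_arrhythmia=True),
]
for inp in cases:
    d = ctcae_grade(inp)
    extra = f" (delta {d.delta_ms:+.0f} ms)" if d.delta_ms is not None else ""
    print(f"QTcF {inp.qtcf_mean_ms:5.0f} ms -> grade {d.grade} "
          f"[{d.triggered_rule.value}]{extra} colour={status_color(d).value}")

print()
for q in (425, 440, 455):
    print(f"QTcF {q} ms: male={sex_status(q, 'male').value:10s} "
          f"female={sex_status(q, 'female').value}")

print()
for q in (450, 500, 540):
    lo, hi = tdp_relative_risk(q)
    print(f"QTc {q} ms vs 440 ms: {100 * lo:.0f}% to {100 * hi:.0f}% excess TdP risk")
# A QTc of 540 ms carries a 63-97% higher TdP risk than 440 ms: the
# risk per 10 ms compounds, it does not add.
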