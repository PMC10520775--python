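"""Turnaround-time arithmetic for ECG diagnosis workflows.

Compares a conventional workflow (days from the need for an ECG to a
cardiologist's QTc diagnosis) with an on-site single-lead recording
transferred to a tele-cardiologist, using the package's unit-aware
percent-reduction and evaluable-fraction helpers.
"""
from qtcdx import (Duration, TimeUnit, TurnaroundSample, evaluable_fraction,
                   mean_ci, percent_reduction)

routine = Duration(5.44, TimeUnit.DAYS)        # conventional workflow mean
tracker = Duration(2.67, TimeUnit.HOURS)       # tele-cardiology workflow mean
oncall = Duration(12.10, TimeUnit.MINUTES)     # with a cardiologic on-call service

for label, after in [("tele-cardiology", tracker), ("on-call service", oncall)]:
    pct = percent_reduction(routine, after)
    print(f"{label}: {pct:.2f}% reduction (displays as {round(pct)}%)")

print(f"evaluable records: {evaluable_fraction(266, 223):.1f}% (223 of 266)")

sample = TurnaroundSample([4.9, 5.3, 5.8, 6.1, 5.1], TimeUnit.DAYS, label="example")
m, lo, hi = mean_ci(sample)
print(f"example sample: mean {m:.2f} d (95% CI {lo:.2f}-{hi:.2f} d)")
# The reductions show why on-site recording with remote diagnosis
# changes monitoring practice: hours or minutes instead of days.
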