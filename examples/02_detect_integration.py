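"""Detect an injected audiovisual integration effect.

Simulates an 18 + 20 cohort in which AV responses exceed the A + V sum by
-1.5 uV at 60-100 ms over the left-anterior ROI, but only for older adults
at low stimulus intensity (inverse effectiveness).  Computes per-subject
difference waves ERP(AV) - [ERP(A) + ERP(V)], runs pointwise t-tests
against zero over 0-400 ms on the ROI-averaged waves, and prints the
windows where 12 or more consecutive samples are significant.  The
older/low cell should show a super-additive negative window overlapping
60-100 ms; the other cells should usually show none.
"""

from averp import synth
from averp.integration import (detect_windows, difference_waves,
                               pointwise_ttest, roi_average)
from averp.pipeline import baseline_correct_erp
from averp.preprocess import SubjectERP, bandpass

cfg = synth.SimConfig(seed=7, integration_effects=synth.inverse_effectiveness_effect(-1.5))
times = synth.erp_times(cfg)

diffs = []
for sid, group in cfg.subjects():
    erps = synth.simulate_subject_erps(cfg, sid, group)
    conds = {}
    for (m, inten), wave in erps.items():
        erp = SubjectERP(sid, group, m, inten, wave, times,
                         list(cfg.channel_labels), 120, True)
        erp = baseline_correct_erp(erp, (-100.0, 0.0))
        erp = bandpass(erp, 0.1, 30.0)
        conds[(m, inten)] = baseline_correct_erp(erp, (-100.0, 0.0))
    for inten in ("high", "low"):
        diffs.append(difference_waves(
            {k: v for k, v in conds.items() if k[1] == inten})[inten])

for group in ("older", "younger"):
    for inten in ("high", "low"):
        cell = [roi_average(d) for d in diffs
                if d.group == group and d.intensity == inten]
        wins = detect_windows(pointwise_ttest(cell, "left_anterior"))
        desc = "; ".join(f"{w.start_ms:.0f}-{w.end_ms:.0f} ms ({w.direction})"
                         for w in wins) or "none"
        print(f"{group:8s} {inten:5s} left_anterior windows: {desc}")
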