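"""Simulate a small cohort and summarize its behavior.

Builds a 4 + 4 subject cohort of the audiovisual oddball design (two
intensity blocks, 150 trials per modality per block: 30 targets, 120
standards), generates responses from the per-cell hit/false-alarm
probabilities and ex-Gaussian RT distributions, and prints the group-level
summary table.  Expect hit rates near ceiling, false alarms of a percent or
less, and RTs ordered AV < V < A with older adults slower.
"""

from averp import behavior, synth

cfg = synth.SimConfig(n_older=4, n_younger=4, seed=1)
bundle = synth.simulate_cohort(cfg)

events = bundle.logs["older01"]
print(f"subjects: {len(bundle.subjects)}; trials per subject: {len(events)}")

tables = behavior.behavior_tables(bundle.logs, dict(bundle.subjects))
summary = behavior.summary_table(tables["cells"])
print(summary.round(1).to_string(index=False))
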