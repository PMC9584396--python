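"""Quantify patient qPCR Ct tables against the pooled non-IBS control.

Two genes are planted (one repressed at 0.58, one induced at 2.0); ddCt
recovers their folds with a SEM over independent plate replicates.
"""

import ibstriage as ib

cfg = ib.SimulationConfig(seed=42, plate_replicates=(3, 3))
ct = ib.simulate_qpcr(cfg, {"TPH1": 0.58, "VSIG2": 2.0})
estimates = ib.ddct_fold(ct, "case_patient", "pooled_control")
summary = ib.summarize_all(estimates)
print(summary.to_string(index=False))
# mean_fold is the linear expression ratio vs the pooled control (< 1 = repressed);
# sem spreads over plates; genes need >= 2 plates to pass the replicate filter.
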