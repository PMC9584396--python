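"""1,25D treatment of cells: fold change, t-test tier, and reversal call.

Plants the four focal treatment folds (TDRD6 0.49, FLT4 0.62, SERT 3.18,
TPH1 1.48) against their patient-cohort directions; all four should classify
as direction reversals.
"""

import ibstriage as ib

cfg = ib.SimulationConfig(seed=42, ct_noise_sd=0.15, treatment_replicates=6)
fold_map = {"TDRD6": 0.49, "FLT4": 0.62, "SERT": 3.18, "TPH1": 1.48}
patient_dir = {"TDRD6": 1.3, "FLT4": 1.5, "SERT": 0.96, "TPH1": 0.58}

ct = ib.simulate_qpcr(cfg, fold_map, arms=("vehicle", "treated"))
result = ib.analyze_treatment(ct, patient_dir)
print(result.to_string(index=False))
# fold_1_25d is treated/vehicle; 'reversal' is True when it points opposite
# to the gene's dysregulation in the patient cohort.
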