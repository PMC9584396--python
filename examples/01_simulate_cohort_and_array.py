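"""Simulate a study cohort and microarray matrix with planted truth.

The cohort reproduces the study margins (18 controls, 11 cases split 8F/3M
across IBS subtypes); the array plants 200 differentially expressed genes
among 2000 with known log2 effects.
"""

import ibstriage as ib

cfg = ib.SimulationConfig(seed=42)
cohort = ib.simulate_cohort(cfg)
matrix = ib.simulate_microarray(cfg, cohort)

print(cohort["classification"].value_counts().to_string())
print(cohort[cohort["classification"] == "case"]["subtype"].value_counts().to_string())
print(f"matrix: {len(matrix.gene_ids)} genes x {len(matrix.sample_ids)} samples, "
      f"{len(matrix.planted_truth)} planted effects")
# The planted_truth sidecar is the oracle every downstream stage is tested against.
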