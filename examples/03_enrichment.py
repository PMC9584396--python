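"""Rank toy gene sets by hypergeometric over-representation of the DE list.

A few simulated terms are deliberately enriched in the planted genes; they
should surface at the top of the ranking, mimicking how serotonin-related
terms dominated the real analysis.
"""

import ibstriage as ib

cfg = ib.SimulationConfig(seed=42)
cohort = ib.simulate_cohort(cfg)
matrix = ib.simulate_microarray(cfg, cohort)
de = ib.run_de_screen(matrix, cohort)

terms = ib.simulate_annotations(cfg, matrix.planted_truth, matrix.gene_ids)
annotations = [ib.AnnotationSet(t, n, frozenset(g)) for t, n, g in terms]
de_genes = set(de.loc[de["significant"], "gene"])
enr = ib.hypergeometric_enrichment(de_genes, annotations, matrix.gene_ids)
print(enr.head(6)[["term_id", "term_name", "k", "K", "p_value"]].to_string(index=False))
# p_value is the upper-tail hypergeometric probability of seeing >= k hits in the term.
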