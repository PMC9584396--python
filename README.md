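# ibstriage

A seedable, fully synthetic re-implementation of an IBS (irritable bowel
syndrome) biomarker-triage analysis: microarray differential-expression
screening, gene-set over-representation, RT-qPCR relative quantification
against a pooled non-IBS control, a directional percent-accuracy concordance
statistic with ≥ 70% panel selection, and a 1,25-dihydroxyvitamin-D
(calcitriol) direction-reversal analysis in colorectal cells.

IBS has no molecular diagnostic test. The triage strategy this package
implements screens colonic-mucosa transcriptomes of cases vs controls for
differentially expressed genes, narrows them through ontology enrichment and
biological relevance, validates candidates by RT-qPCR against a pooled
control, and scores each candidate's diagnostic promise by how consistently
individual patients' qPCR fold changes agree in *direction* with the
microarray fold change. Because the underlying patient data are not publicly
deposited, every input here is generated by a seeded simulator with known
planted truth — the package is a testable model of the analysis, for
bioinformaticians who want to study, extend, or stress-test its statistics.

## The core statistics

**Differential expression.** Each gene is tested three ways — pooled-variance
Student *t*, Mann-Whitney *U* (exact for tie-free groups with min *n* ≤ 8),
and an empirical-Bayes moderated *t* whose gene variance is shrunk toward an
ensemble prior:

    s̃²_g = (d₀·s₀² + d_g·s²_g) / (d₀ + d_g),   t_g = Δȳ_g / (s̃_g·√(1/n₁+1/n₂))

with (d₀, s₀²) estimated by method of moments on log variances and *p* from a
*t* distribution on d₀ + d_g df. A gene is significant when any test reaches
α = 0.05 (configurable rule; no multiplicity correction by default,
Benjamini–Hochberg behind a flag).

**qPCR quantification.** Wells are averaged within (gene, arm, sample,
plate); fold = 2^(−ΔΔCt) relative to the pooled control (patients) or the
vehicle (cells), with SEM over independent plate replicates and a ≥ 2-plate
filter.

**Percent accuracy.** For gene *g* with R technical replicates,

    %Accuracy = 100 · (Σᵢ xᵢ/yᵢ) / R

where xᵢ of the yᵢ patients analyzed in replicate *i* match the microarray
direction. Genes with ≥ 70% accuracy, ≥ 2 plates, and a pathophysiology
relevance flag form the biomarker panel.

**Reversal.** A candidate gene "reverses" when its treated/vehicle fold under
10 nM 1,25D points opposite to its dysregulation direction in the patient
cohort (equal-variance *t* on the Ct scale; tiers p < 0.005 and p < 0.0005).

## Worked example

`examples/05_concordance_panel.py` recomputes the seven-gene panel from the
packaged per-replicate match counts (reconstructed to be consistent with the
published accuracies and 11 patients per replicate):

```
 SLC19A1: 100.00%  from 2 replicates
   PPARD:  92.42%  from 6 replicates
    TPH1:  84.85%  from 3 replicates
    CD36:  81.82%  from 3 replicates
     VIP:  81.82%  from 3 replicates
    SERT:  75.76%  from 3 replicates
   VSIG2:  72.73%  from 3 replicates
panel mean accuracy: 84.2%
```

Each line is one gene's percent accuracy — e.g. SERT's 75.76 is
100·(9/11 + 8/11 + 8/11)/3 — and the panel mean of 84.2% is the average
diagnostic concordance of the seven genes that pass all three panel criteria.
The other examples cover simulation (`01`), the DE screen (`02`), enrichment
(`03`), qPCR quantification (`04`), the vitamin-D reversal analysis (`06`),
and the end-to-end pipeline with its determinism manifest (`07`).

A thin CLI mirrors the stages:

```sh
ibs-triage simulate --seed 1 --out-dir run/
ibs-triage de --matrix run/expression.tsv --cohort run/cohort.csv --out run/de.tsv
ibs-triage all --seed 1 --out-dir run/
```

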