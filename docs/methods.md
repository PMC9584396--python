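# Methods

## Scope and data model

The package models a biomarker-triage workflow for IBS on fully synthetic
data: a cohort table (case/control, subtype, sex, age), a genes × samples
log2 microarray matrix with a planted-truth sidecar, and long-format qPCR Ct
tables keyed by (gene, arm, subject, plate, well). The pipeline starts at
the gene × sample matrix — probe-level array processing, RNA QC, and wet-lab
steps are out of scope, as are the real GO database (toy GMT collections
stand in) and any literature judgment of "pathophysiological relevance",
which enters only as an explicit per-gene boolean flag supplied by the user.

## Synthetic generators

All randomness flows from one integer seed through named
`numpy.random.Generator` streams (crc32 of the stream name mixed into a
`SeedSequence`); no global RNG state is touched, so identical configs give
bit-identical outputs across processes.

**Cohort.** The default config reproduces the study margins exactly:
18 controls (12F/6M) and 11 cases (8F/3M; subtypes 1 IBS-C, 4 IBS-D,
5 IBS-M, 1 unknown). Other sizes scale those margins by largest-remainder
allocation. Ages are drawn uniformly on the observed 41–60 range.

**Microarray.** Per gene: log2 intensity = baseline (N(8, 1.5²)) + planted
effect for cases + N(0, `array_noise_sd`²). Effects have magnitudes uniform
in `log2_effect_range` (default 0.5–2.0 log2) with random sign, since the
observed cohort contained both induced and repressed genes. The default is
2000 genes with 200 planted — a desk-scale analogue of the full-array
analysis chosen so the whole suite runs in minutes; the headline counts of
the original full-scale screen (858 features, 200-gene shortlist) are not
reproduced at this size, only the behaviour of the method.

**qPCR.** For each gene, the target arm's expected Ct sits log_E(fold)
cycles below the comparator's (E = amplification efficiency, default 2.0,
i.e. one cycle per doubling; other efficiencies are a config knob), with
N(0, `ct_noise_sd`²) per well (default 0.15 cycles). The pooled non-IBS
control is emulated by averaging eight simulated control subjects' Ct values
on the Ct scale — an approximation to the physical pooling of RNA that is
exact at the mean and slightly optimistic in variance. Patients share the
gene's planted fold; plate counts are drawn from 2–6 and wells from 3–6
(3-well default for cells), matching the reported replicate structure. The
treated-vs-vehicle design uses 6 replicates per arm by default (the reported
range is 3–6; per-gene counts are configurable).

**What the generators do not emulate:** dye bias, spatial artifacts or
probe-level effects; primer-efficiency curves or melt-curve QC;
between-patient biological heterogeneity in the planted fold (all patients
share one effect); RNA-quality variation. Passing tests therefore show the
estimators are correct and calibrated under idealized noise, not that the
pipeline is robust to real assay artifacts.

## Differential expression

Three per-gene tests: pooled-variance Student t (zero pooled variance with
equal means gives p = 1 by convention), Mann-Whitney U (exact null when
min(n) ≤ 8 without ties, tie-corrected normal approximation with continuity
correction otherwise; both via scipy), and a moderated t authored here. The
moderated test shrinks the gene variance toward a scaled inverse-chi-square
prior, the prior (d0, s0²) estimated by method of moments on log variances
(digamma/trigamma inversion, with Newton inversion of the trigamma);
d0 = inf (complete pooling) is returned when the spread of log variances is
no larger than chi-square sampling alone predicts. The implementation agrees
with Bioconductor limma's eBayes to ~1e-14 in p-values on shared input (a
cross-check test runs limma through Rscript), and with the ordinary t
exactly at d0 = 0.

The combination rule defaults to `any` — a gene is significant if at least
one of the three tests reaches alpha — which is the most inclusive reading
of "a combination of" three tests and the natural choice for a screening
stage; `all` and `moderated_only` are selectable, and the chosen rule is
recorded in the output's metadata. P-values are uncorrected at alpha = 0.05
by default, matching the original screen; Benjamini-Hochberg is available
behind a flag. Fold change is the ratio of arithmetic means of linear-scale
intensities (2^log2), the microarray reporting convention; 2^(difference of
log2 means) is selectable. Quantile normalization is provided as an optional
pre-step and off by default, since simulated matrices are already calibrated.
How the original analysis narrowed its DE set to a 200-gene shortlist is not
specified anywhere; `top_n_filter` implements a rank filter on the moderated
p among significant genes and documents itself as that choice.

## Enrichment

One-sided hypergeometric upper tail (Fisher's exact enriched side), terms
ranked by increasing p with ties broken by term id, uncorrected p-values
(the original screen used an uncorrected 0.05 cut). The universe is all
genes on the array, not the genome — the defensible default for array data.
Candidate selection takes significant DE genes that are members of a
top-25-term (p < alpha) or carry a relevance flag, ranked by |log2 fold|.

## qPCR quantification

Wells are averaged within (gene, arm, subject, plate) first; per-plate fold
= E^(−ΔCt) against the comparator arm's plate mean. No housekeeping gene is
assumed by default — the pooled control/vehicle is a fixed comparator — but
a reference-gene ΔΔCt mode exists for realism. Summaries aggregate on the
linear fold scale (the reporting convention), SEM over independent plate
replicates (wells are technical noise and are averaged away first; a single
plate has SEM 0 by convention and fails the ≥ 2-plate filter). The per-gene
cohort fold averages patients patient-first (each patient's plates first), so
unevenly replicated patients carry equal weight; whether the original
analysis pooled plates instead is unknowable from its description.

## Concordance and panel

"Match" is directional concordance of the patient-level qPCR fold and the
microarray cohort fold relative to 1.0 — the only reading consistent with
using qPCR to validate microarray direction. A fold of exactly 1.0 has no
direction and counts as a non-match (conservative; measure-zero under
noise). The technical replicate of the accuracy formula is a PCR plate, and
y (patients analyzed) is per-replicate, which is the only structure under
which the published 92.42 (61/66, six replicates) and 75.76 (25/33, three)
can coexist with 11 patients. Per-gene accuracy is rounded to 2 decimals and
the panel mean to 1 decimal, reproducing the published table and the 84.2%
headline exactly. The 70% threshold is inclusive (≥ 70).

The packaged per-replicate match counts are a *reconstruction*: the
published table prints only accuracies, so counts were reverse-engineered to
be consistent with 11 patients and reproduce every printed value under the
formula.

## Vitamin-D response

The treated-vs-vehicle t-test runs on replicate-level Ct means (log scale),
where the equal-variance assumption is most defensible; the original report
does not state its scale. Significance tiers are p < 0.005 and p < 0.0005.
Reversal compares the cell fold's log-sign against the patient-cohort qPCR
direction (a flag switches to microarray direction); folds of exactly 1 have
no direction to reverse. The 10 nM and 10⁻⁸ M dose notations are treated as
one condition; dose is metadata only.

## Pipeline and numerical choices

`run_pipeline` chains the stages, validating inter-stage sample/gene
contracts, and writes a manifest (config snapshot, seed, sha256 of every
output, timings, versions); digests are reproducible under a fixed seed
because no output embeds timestamps. In the default synthetic run, all
qPCR-tested candidates are flagged relevant (the real flag is a human
pre-selection that synthetic data cannot model), and when no treatment fold
map is configured the top four panel genes are treated with planted folds
opposite to their cohort direction — a reversal design mirroring the
original four-gene experiment. Plotting is out of scope; the pipeline emits
a long-format heatmap table (gene, sample, value, direction) instead.

Degenerate inputs: single-gene moderated-t input falls back to the ordinary
t with a warning; zero-variance genes follow the p = 1 / p = 0 convention;
plates missing a comparator are skipped with a logged warning and a gene
with no usable plate raises an insufficient-data error; empty candidate
lists and empty panels are valid outcomes and the report still renders.

## Problem sizes

Defaults throughout are the desk-scale study conditions: 29 samples, 2000
genes (200 planted), 2–6 plates × 3–6 wells, 6 treatment replicates,
0.15-cycle Ct noise. Recovery checks use 20 simulation seeds; the type-I
calibration uses 2000 null genes at one seed with a binomial tolerance band.
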