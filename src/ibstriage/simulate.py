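"""Seeded synthetic data: cohorts, microarray matrices, and qPCR Ct tables.

Every generator plants a known truth (group effects on the array, linear fold
changes in the Ct tables) so downstream estimators can be validated without
any external data.  The pooled non-IBS control is emulated by averaging the
simulated Ct values of eight control subjects on the Ct scale — an
approximation to the physical pooling of RNA.  Amplification efficiency
defaults to 100% (one cycle per doubling).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .config import InvalidConfigError, SimulationConfig

COHORT_COLUMNS = ["sample_id", "classification", "subtype", "sex", "age"]
CT_COLUMNS = ["gene", "arm", "subject_id", "plate", "well", "ct"]

# Cohort margins of the study population: controls 12F/6M; cases 8F/3M with
# subtypes 1 IBS-C, 4 IBS-D, 5 IBS-M, 1 unknown.
_CONTROL_SEX_COUNTS = {"F": 12, "M": 6}
_CASE_SEX_COUNTS = {"F": 8, "M": 3}
_CASE_SUBTYPE_COUNTS = {"IBS-C": 1, "IBS-D": 4, "IBS-M": 5, "unknown": 1}
_AGE_RANGE = (41, 60)


def _rng(seed: int, stream: str) -> np.random.Generator:
    """Independent, named stream derived from the master seed.

    crc32 (not hash()) keys the stream: it is stable across processes.
    """
    import zlib

    return np.random.default_rng(np.random.SeedSequence([int(seed), zlib.crc32(stream.encode())]))


def validate_cohort(cohort: pd.DataFrame) -> None:
    """Check CohortTable invariants; raise ``ValueError`` on violation."""
    missing = set(COHORT_COLUMNS) - set(cohort.columns)
    if missing:
        raise ValueError(f"cohort table missing columns: {sorted(missing)}")
    if cohort["sample_id"].duplicated().any():
        raise ValueError("sample_id values must be unique")
    if not set(cohort["classification"]) <= {"case", "control"}:
        raise ValueError("classification must be 'case' or 'control'")
    is_control = cohort["classification"] == "control"
    if not (cohort.loc[is_control, "subtype"] == "none").all():
        raise ValueError("controls must carry subtype 'none'")
    if (cohort.loc[~is_control, "subtype"] == "none").any():
        raise ValueError("cases must not carry subtype 'none'")
    if (cohort["age"] <= 0).any():
        raise ValueError("ages must be positive")


def _allocate(counts: Mapping[str, int], n: int) -> list[str]:
    """Allocate n items across categories by largest-remainder scaling of reference counts.

    With n equal to the reference total the reference counts are returned
    exactly, so the default cohort reproduces the study margins.
    """
    total = sum(counts.values())
    quotas = {k: n * v / total for k, v in counts.items()}
    alloc = {k: math.floor(q) for k, q in quotas.items()}
    short = n - sum(alloc.values())
    by_rem = sorted(counts, key=lambda k: (-(quotas[k] - alloc[k]), k))
    for k in by_rem[:short]:
        alloc[k] += 1
    out: list[str] = []
    for k in counts:  # preserve insertion order for determinism
        out.extend([k] * alloc[k])
    return out


def simulate_cohort(config: SimulationConfig) -> pd.DataFrame:
    """Generate a cohort table with the study's sex and subtype margins.

    Returns a DataFrame with columns sample_id, classification, subtype,
    sex, age.  With the default 11-case / 18-control config the margins equal
    the study population exactly (controls 12F/6M; cases 8F/3M; subtypes
    1 IBS-C, 4 IBS-D, 5 IBS-M, 1 unknown); other sizes are scaled by
    largest-remainder allocation.  Ages are drawn uniformly from the observed
    41-60 range.
    """
    if config.n_cases < 0 or config.n_controls < 0 or config.n_cases + config.n_controls == 0:
        raise InvalidConfigError("cohort must contain at least one sample")
    rng = _rng(config.seed, "cohort")
    rows = []
    sexes = _allocate(_CONTROL_SEX_COUNTS, config.n_controls)
    for i, sex in enumerate(sexes):
        rows.append(
            {
                "sample_id": f"CTRL-{i + 1:03d}",
                "classification": "control",
                "subtype": "none",
                "sex": sex,
                "age": int(rng.integers(_AGE_RANGE[0], _AGE_RANGE[1] + 1)),
            }
        )
    case_sexes = _allocate(_CASE_SEX_COUNTS, config.n_cases)
    case_subtypes = _allocate(_CASE_SUBTYPE_COUNTS, config.n_cases)
    for i, (sex, subtype) in enumerate(zip(case_sexes, case_subtypes)):
        rows.append(
            {
                "sample_id": f"CASE-{i + 1:03d}",
                "classification": "case",
                "subtype": subtype,
                "sex": sex,
                "age": int(rng.integers(_AGE_RANGE[0], _AGE_RANGE[1] + 1)),
            }
        )
    cohort = pd.DataFrame(rows, columns=COHORT_COLUMNS)
    validate_cohort(cohort)
    return cohort


@dataclass
class ExpressionMatrix:
    """Genes x samples log2 intensity matrix with an optional planted-truth sidecar.

    ``planted_truth`` maps gene id -> planted log2 case-vs-control effect for
    simulated matrices; it is absent for user-supplied data.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray  # shape (n_genes, n_samples), log2 intensities
    planted_truth: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"values shape {self.values.shape} inconsistent with "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values must be finite")
        unknown = set(self.planted_truth) - set(self.gene_ids)
        if unknown:
            raise ValueError(f"planted_truth refers to unknown genes: {sorted(unknown)[:5]}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    def to_tsv(self, path: str | Path, truth_path: str | Path | None = None) -> None:
        df = self.to_frame()
        df.index.name = "gene"
        df.to_csv(path, sep="\t")
        if truth_path is not None:
            Path(truth_path).write_text(json.dumps(self.planted_truth, indent=1, sort_keys=True))

    @classmethod
    def from_tsv(cls, path: str | Path, truth_path: str | Path | None = None) -> "ExpressionMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        truth = {}
        if truth_path is not None:
            truth = json.loads(Path(truth_path).read_text())
        return cls(list(df.index), list(df.columns), df.to_numpy(), truth)


def simulate_microarray(config: SimulationConfig, cohort: pd.DataFrame) -> ExpressionMatrix:
    """Simulate a log2 intensity matrix with planted case-vs-control effects.

    Model per gene g and sample s:
        log2 intensity = baseline_g + effect_g * [s is a case] + N(0, array_noise_sd)
    where effect_g is nonzero for ``n_de_genes`` genes chosen at random, with
    magnitude uniform in ``log2_effect_range`` and random sign (both induced
    and repressed genes are planted).
    """
    if len(cohort) == 0:
        raise InvalidConfigError("cohort must be non-empty")
    if config.n_de_genes > config.n_genes:
        raise InvalidConfigError("n_de_genes cannot exceed n_genes")
    validate_cohort(cohort)
    rng = _rng(config.seed, "microarray")
    n_genes, n_samples = config.n_genes, len(cohort)
    gene_ids = [f"G{i + 1:05d}" for i in range(n_genes)]
    baseline = rng.normal(8.0, 1.5, size=n_genes)
    de_idx = rng.choice(n_genes, size=config.n_de_genes, replace=False)
    lo, hi = config.log2_effect_range
    magnitudes = rng.uniform(lo, hi, size=config.n_de_genes)
    signs = rng.choice([-1.0, 1.0], size=config.n_de_genes)
    effects = np.zeros(n_genes)
    effects[de_idx] = magnitudes * signs
    is_case = (cohort["classification"] == "case").to_numpy(dtype=float)
    values = (
        baseline[:, None]
        + np.outer(effects, is_case)
        + rng.normal(0.0, config.array_noise_sd, size=(n_genes, n_samples))
    )
    truth = {gene_ids[i]: float(effects[i]) for i in de_idx}
    return ExpressionMatrix(gene_ids, list(cohort["sample_id"]), values, truth)


def validate_ct_table(ct: pd.DataFrame) -> None:
    """Check CtTable invariants; raise ``ValueError`` on violation."""
    missing = set(CT_COLUMNS) - set(ct.columns)
    if missing:
        raise ValueError(f"Ct table missing columns: {sorted(missing)}")
    if ((ct["ct"] <= 0) | (ct["ct"] >= 45)).any():
        raise ValueError("Ct values must lie strictly between 0 and 45 cycles")
    keys = ct[["gene", "arm", "subject_id", "plate", "well"]]
    if keys.duplicated().any():
        raise ValueError("(gene, arm, subject_id, plate, well) must be unique")


def simulate_qpcr(
    config: SimulationConfig,
    truth: Mapping[str, float],
    arms: tuple[str, str] = ("pooled_control", "case_patient"),
) -> pd.DataFrame:
    """Simulate a long-format Ct table with planted linear fold changes.

    For each gene the second arm's expected Ct sits ``log_E(fold)`` cycles
    below the first (comparator) arm's, where E is the amplification
    efficiency (log2 at the default 100%); per-well Gaussian noise of
    ``ct_noise_sd`` cycles is added on top.

    Two designs share this generator:

    * ``("pooled_control", "case_patient")`` — patients vs the pooled non-IBS
      aggregate.  The pooled arm's Ct per well is the mean of
      ``n_pooled_controls`` simulated control subjects' Ct values.  The number
      of plates per gene is drawn from ``plate_replicates`` and wells per
      (sample, plate) from ``well_replicates``.
    * ``("vehicle", "treated")`` — cell experiments with
      ``treatment_replicates`` independent replicates per arm, three wells
      each.
    """
    for gene, fold in truth.items():
        if fold <= 0:
            raise InvalidConfigError(f"planted fold for {gene} must be > 0, got {fold}")
    if len(arms) != 2 or arms[0] == arms[1]:
        raise InvalidConfigError("arms must be two distinct labels")
    rng = _rng(config.seed, f"qpcr:{arms[0]}|{arms[1]}")
    log_eff = math.log2(config.amplification_efficiency)
    noise = config.ct_noise_sd
    comparator, target = arms
    patient_design = target == "case_patient"
    rows: list[dict] = []
    for gene in truth:
        base_ct = float(rng.uniform(20.0, 30.0))
        shift = math.log2(truth[gene]) / log_eff  # cycles of depletion in the target arm
        n_plates = (
            int(rng.integers(config.plate_replicates[0], config.plate_replicates[1] + 1))
            if patient_design
            else config.treatment_replicates
        )
        for plate in range(1, n_plates + 1):
            n_wells = (
                int(rng.integers(config.well_replicates[0], config.well_replicates[1] + 1))
                if patient_design
                else 3
            )
            if patient_design:
                # pooled comparator: average of simulated control subjects per well
                for well in range(1, n_wells + 1):
                    pooled = rng.normal(base_ct, noise, size=config.n_pooled_controls).mean()
                    rows.append(
                        dict(gene=gene, arm=comparator, subject_id="pooled", plate=plate, well=well, ct=pooled)
                    )
                for p in range(1, config.n_cases + 1):
                    for well in range(1, n_wells + 1):
                        ct = rng.normal(base_ct - shift, noise)
                        rows.append(
                            dict(gene=gene, arm=target, subject_id=f"CASE-{p:03d}", plate=plate, well=well, ct=ct)
                        )
            else:
                # one replicate per plate and arm; subject_id names the replicate
                rep = f"rep-{plate:02d}"
                for well in range(1, n_wells + 1):
                    rows.append(
                        dict(gene=gene, arm=comparator, subject_id=rep, plate=plate, well=well, ct=rng.normal(base_ct, noise))
                    )
                for well in range(1, n_wells + 1):
                    rows.append(
                        dict(gene=gene, arm=target, subject_id=rep, plate=plate, well=well, ct=rng.normal(base_ct - shift, noise))
                    )
    ct_table = pd.DataFrame(rows, columns=CT_COLUMNS)
    if len(ct_table):
        ct_table["ct"] = ct_table["ct"].clip(0.01, 44.99)
        validate_ct_table(ct_table)
    return ct_table


def simulate_annotations(
    config: SimulationConfig,
    truth: Mapping[str, float],
    universe: Sequence[str],
    n_terms: int = 40,
    term_size_range: tuple[int, int] = (10, 50),
    n_enriched_terms: int = 5,
    enriched_fraction: float = 0.6,
) -> list[tuple[str, str, set[str]]]:
    """Build a toy gene-set collection with a few terms enriched in the planted genes.

    Returns (term_id, term_name, genes) triples in GMT order.  The first
    ``n_enriched_terms`` terms draw ``enriched_fraction`` of their members
    from the planted differentially expressed genes; the rest are uniform
    draws from the universe, giving a realistic null background.
    """
    rng = _rng(config.seed, "annotations")
    universe = list(universe)
    planted = [g for g in truth if g in set(universe)]
    terms = []
    for i in range(n_terms):
        size = int(rng.integers(term_size_range[0], term_size_range[1] + 1))
        if i < n_enriched_terms and planted:
            k = min(len(planted), max(1, int(round(size * enriched_fraction))))
            members = set(rng.choice(planted, size=k, replace=False))
            rest = [g for g in universe if g not in members]
            members |= set(rng.choice(rest, size=min(size - k, len(rest)), replace=False))
            name = f"toy pathway {i + 1} (planted-enriched)"
        else:
            members = set(rng.choice(universe, size=min(size, len(universe)), replace=False))
            name = f"toy pathway {i + 1}"
        terms.append((f"TOY:{i + 1:04d}", name, members))
    return terms
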