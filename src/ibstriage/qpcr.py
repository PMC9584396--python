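"""Relative quantification of qPCR Ct tables by the ddCt convention.

Wells are averaged within (gene, arm, subject, plate); the per-plate fold of
a target sample relative to the comparator arm (pooled control or vehicle) is
2 ** (-dCt) with dCt = mean Ct(target) - mean Ct(comparator), optionally each
first normalized to a reference gene.  Per-gene summaries aggregate folds on
the linear scale with the SEM taken over independent plate replicates, and a
gene must have at least ``min_plates`` (default 2) plates to pass the
replicate filter.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


class InsufficientDataError(ValueError):
    pass


def _well_means(ct: pd.DataFrame) -> pd.DataFrame:
    """Average Ct over wells within (gene, arm, subject_id, plate)."""
    return ct.groupby(["gene", "arm", "subject_id", "plate"], as_index=False)["ct"].mean()


def ddct_fold(
    ct: pd.DataFrame,
    target_arm: str,
    comparator_arm: str,
    use_reference_gene: bool = False,
    reference_gene: str | None = None,
    efficiency: float = 2.0,
) -> pd.DataFrame:
    """Per-(gene, subject, plate) linear fold changes relative to the comparator arm.

    Returns a DataFrame (gene, subject_id, plate, fold).  The comparator's Ct
    per (gene, plate) is the well mean over its subjects (a single pooled
    subject in the patient design, the vehicle replicate in the cell design).
    Plates missing a comparator measurement are skipped with a warning; a
    gene with no usable plate raises :class:`InsufficientDataError`.

    With ``use_reference_gene`` each arm's Ct is first differenced against
    the same subject/plate's Ct for ``reference_gene`` (the classic ddCt
    housekeeping normalization); the reference gene itself is then excluded
    from the output.
    """
    means = _well_means(ct)
    if use_reference_gene:
        if not reference_gene:
            raise ValueError("use_reference_gene requires reference_gene")
        ref = means[means["gene"] == reference_gene]
        if ref.empty:
            raise InsufficientDataError(f"reference gene {reference_gene!r} absent from Ct table")
        ref = ref.rename(columns={"ct": "ct_ref"})[["arm", "subject_id", "plate", "ct_ref"]]
        means = means[means["gene"] != reference_gene].merge(
            ref, on=["arm", "subject_id", "plate"], how="inner"
        )
        means["ct"] = means["ct"] - means["ct_ref"]

    target = means[means["arm"] == target_arm]
    comp = (
        means[means["arm"] == comparator_arm]
        .groupby(["gene", "plate"], as_index=False)["ct"]
        .mean()
        .rename(columns={"ct": "ct_comp"})
    )
    if target.empty:
        raise InsufficientDataError(f"no measurements for target arm {target_arm!r}")
    merged = target.merge(comp, on=["gene", "plate"], how="left")
    missing = merged["ct_comp"].isna()
    if missing.any():
        for _, row in merged[missing].iterrows():
            logger.warning(
                "skipping gene %s plate %s: no %s measurement", row["gene"], row["plate"], comparator_arm
            )
        merged = merged[~missing]
    if merged.empty:
        raise InsufficientDataError("no plate has both target and comparator measurements")
    dct = merged["ct"] - merged["ct_comp"]
    merged = merged.assign(fold=efficiency ** (-dct))
    return merged[["gene", "subject_id", "plate", "fold"]].reset_index(drop=True)


def summarize_gene(estimates: pd.DataFrame, min_plates: int = 2) -> pd.Series:
    """Summarize one gene's per-plate fold estimates.

    ``estimates`` holds (gene, subject_id, plate, fold) rows for a single
    gene.  Folds are first averaged over subjects within each plate; the
    summary is the arithmetic mean of the plate means, with
    SEM = sd(plate means) / sqrt(n_plates) (0 by convention for a single
    plate).  ``passes_replicate_filter`` requires at least ``min_plates``
    independent plates.
    """
    if estimates.empty:
        raise InsufficientDataError("no fold estimates supplied")
    genes = estimates["gene"].unique()
    if len(genes) != 1:
        raise ValueError(f"summarize_gene expects a single gene, got {list(genes)}")
    plate_means = estimates.groupby("plate")["fold"].mean()
    n_plates = len(plate_means)
    sem = float(plate_means.std(ddof=1) / np.sqrt(n_plates)) if n_plates > 1 else 0.0
    return pd.Series(
        {
            "gene": genes[0],
            "mean_fold": float(plate_means.mean()),
            "sem": sem,
            "n_plates": n_plates,
            "passes_replicate_filter": n_plates >= min_plates,
        }
    )


def summarize_all(estimates: pd.DataFrame, min_plates: int = 2) -> pd.DataFrame:
    """Per-gene fold summary table (gene, mean_fold, sem, n_plates, passes_replicate_filter)."""
    rows = [
        summarize_gene(sub, min_plates=min_plates)
        for _, sub in estimates.groupby("gene", sort=True)
    ]
    out = pd.DataFrame(rows).reset_index(drop=True)
    out["n_plates"] = out["n_plates"].astype(int)
    out["passes_replicate_filter"] = out["passes_replicate_filter"].astype(bool)
    return out


def per_patient_folds(estimates: pd.DataFrame) -> pd.DataFrame:
    """Per-(gene, subject) fold: the mean of that subject's per-plate folds."""
    return estimates.groupby(["gene", "subject_id"], as_index=False)["fold"].mean()


def cohort_fold(estimates: pd.DataFrame) -> pd.Series:
    """Per-gene cohort fold: patients' folds averaged patient-first.

    Each patient's plates are averaged before patients are averaged, so a
    patient run on six plates counts no more than one run on two.
    """
    per_patient = per_patient_folds(estimates)
    return per_patient.groupby("gene")["fold"].mean()
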