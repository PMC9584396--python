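"""1,25-dihydroxyvitamin-D (calcitriol) response of candidate genes in cell Ct data.

Each gene's treated-vs-vehicle fold change is estimated by ddCt on replicate
Ct measurements; significance comes from an equal-variance two-sample t-test
applied on the Ct (log) scale, where the equal-variance assumption is most
defensible, with the two reporting tiers p < 0.005 and p < 0.0005.  A gene
"reverses" when its treatment direction is opposite to its dysregulation
direction in the patient cohort (taken from the patient qPCR summary by
default).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import pandas as pd

from .de import student_t_test
from .qpcr import InsufficientDataError, _well_means

TIER_STRONG = "p<0.0005"
TIER_MODERATE = "p<0.005"
TIER_NS = "ns"


@dataclass(frozen=True)
class TreatmentResult:
    gene: str
    fold_1_25d: float
    p_value: float
    n_replicates: int
    significance_tier: str
    reversal: bool | None = None


def significance_tier(p: float) -> str:
    if p < 0.0005:
        return TIER_STRONG
    if p < 0.005:
        return TIER_MODERATE
    return TIER_NS


def treatment_fold_and_test(
    ct: pd.DataFrame,
    treated_arm: str = "treated",
    vehicle_arm: str = "vehicle",
    efficiency: float = 2.0,
) -> TreatmentResult:
    """Fold change and t-test for one gene's treated-vs-vehicle Ct slice.

    Wells are averaged within each replicate (subject/plate); the fold is
    E ** -(mean treated Ct - mean vehicle Ct) and the p-value a two-tailed
    pooled-variance t between the arms' replicate-level Ct means.  Requires
    at least two replicates per arm.
    """
    genes = ct["gene"].unique()
    if len(genes) != 1:
        raise ValueError(f"expected a single gene, got {list(genes)}")
    means = _well_means(ct)
    treated = means.loc[means["arm"] == treated_arm, "ct"].to_numpy()
    vehicle = means.loc[means["arm"] == vehicle_arm, "ct"].to_numpy()
    if len(treated) < 2 or len(vehicle) < 2:
        raise InsufficientDataError(
            f"gene {genes[0]}: need >= 2 replicates per arm, got "
            f"{len(treated)} treated / {len(vehicle)} vehicle"
        )
    dct = treated.mean() - vehicle.mean()
    fold = float(efficiency**-dct)
    p = student_t_test(treated, vehicle)
    return TreatmentResult(
        gene=str(genes[0]),
        fold_1_25d=fold,
        p_value=p,
        n_replicates=min(len(treated), len(vehicle)),
        significance_tier=significance_tier(p),
    )


def classify_reversal(cell_fold: float, patient_fold: float) -> bool:
    """True when treatment moves a gene opposite to its patient-cohort direction.

    Both folds are linear ratios; direction is the sign of the log fold.  A
    fold of exactly 1.0 on either side has no direction, so no reversal.
    """
    if cell_fold <= 0 or patient_fold <= 0:
        raise ValueError("fold changes must be strictly positive")
    if cell_fold == 1.0 or patient_fold == 1.0:
        return False
    return (math.log(cell_fold) > 0) != (math.log(patient_fold) > 0)


def analyze_treatment(
    ct: pd.DataFrame,
    patient_folds: Mapping[str, float],
    treated_arm: str = "treated",
    vehicle_arm: str = "vehicle",
    efficiency: float = 2.0,
) -> pd.DataFrame:
    """Per-gene treatment table: fold, p, tier, and reversal vs the patient direction.

    ``patient_folds`` maps gene -> cohort fold (the patient qPCR summary by
    default; pass microarray folds to flip the direction source).  Genes
    without a patient fold get reversal = NA.
    """
    rows = []
    for gene, sub in ct.groupby("gene", sort=True):
        res = treatment_fold_and_test(sub, treated_arm, vehicle_arm, efficiency)
        reversal = (
            classify_reversal(res.fold_1_25d, patient_folds[gene])
            if gene in patient_folds
            else pd.NA
        )
        rows.append(
            dict(
                gene=res.gene,
                fold_1_25d=res.fold_1_25d,
                p_value=res.p_value,
                n_replicates=res.n_replicates,
                significance_tier=res.significance_tier,
                reversal=reversal,
            )
        )
    return pd.DataFrame(
        rows,
        columns=["gene", "fold_1_25d", "p_value", "n_replicates", "significance_tier", "reversal"],
    )
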