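"""Directional concordance between patient qPCR folds and microarray folds.

The per-gene percent-accuracy statistic is

    %Accuracy = 100 * (sum over replicates of x_i / y_i) / R

where, within technical replicate i (a PCR plate), x_i counts the patients
whose qPCR fold change agrees in direction with the gene's microarray fold
change and y_i counts the patients analyzed on that plate (patients may be
absent from a plate, so y varies across replicates).  Per-gene accuracy is
rounded to 2 decimals and the panel mean to 1 decimal.  A panel gene must
reach the accuracy threshold (>= 70 by default), pass the >= 2-plate
replicate filter, and carry a pathophysiology-relevance flag.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd


class InsufficientDataError(ValueError):
    pass


@dataclass(frozen=True)
class ReplicateMatch:
    """Match counts for one technical replicate: x of y patients concordant."""

    gene: str
    replicate: int
    x: int
    y: int

    def __post_init__(self) -> None:
        if self.y < 1:
            raise ValueError("a replicate must analyze at least one patient")
        if not 0 <= self.x <= self.y:
            raise ValueError(f"need 0 <= x <= y, got x={self.x}, y={self.y}")


def patient_match(patient_fold: float, microarray_fold: float) -> bool:
    """True when the patient's qPCR fold agrees in direction with the array fold.

    Direction is relative to 1.0 (log-sign); a fold of exactly 1.0 on either
    side has no direction and counts as a non-match (conservative, and
    measure-zero under noise).
    """
    if patient_fold <= 0 or microarray_fold <= 0:
        raise ValueError("fold changes must be strictly positive")
    sp = math.copysign(1.0, math.log(patient_fold)) if patient_fold != 1.0 else 0.0
    sm = math.copysign(1.0, math.log(microarray_fold)) if microarray_fold != 1.0 else 0.0
    return sp != 0.0 and sp == sm


def percent_accuracy(replicates: Sequence[ReplicateMatch]) -> float:
    """Percent accuracy over technical replicates, rounded to 2 decimals."""
    if not replicates:
        raise InsufficientDataError("at least one replicate required")
    total = sum(r.x / r.y for r in replicates)
    return round(100.0 * total / len(replicates), 2)


def score_gene(
    per_replicate_folds: Mapping[int, Mapping[str, float]] | pd.DataFrame,
    microarray_fold: float,
    gene: str = "",
) -> tuple[list[ReplicateMatch], float]:
    """Score one gene: build per-replicate match counts, then percent accuracy.

    ``per_replicate_folds`` is either a mapping {replicate -> {patient ->
    fold}} or a per-plate estimate DataFrame (gene, subject_id, plate, fold)
    as produced by :func:`ibstriage.qpcr.ddct_fold`.
    """
    if isinstance(per_replicate_folds, pd.DataFrame) and not per_replicate_folds.empty:
        df = per_replicate_folds
        genes = df["gene"].unique()
        if len(genes) != 1:
            raise ValueError("score_gene expects estimates for a single gene")
        gene = gene or str(genes[0])
        per_replicate_folds = {
            int(plate): dict(zip(sub["subject_id"], sub["fold"]))
            for plate, sub in df.groupby("plate")
        }
    if not per_replicate_folds:
        raise InsufficientDataError("no replicates to score")
    matches = []
    for i, (rep, folds) in enumerate(sorted(per_replicate_folds.items()), start=1):
        if not folds:
            raise InsufficientDataError(f"replicate {rep} has no patient folds")
        x = sum(patient_match(f, microarray_fold) for f in folds.values())
        matches.append(ReplicateMatch(gene=gene, replicate=i, x=x, y=len(folds)))
    return matches, percent_accuracy(matches)


def score_all(
    estimates: pd.DataFrame, microarray_folds: Mapping[str, float]
) -> pd.DataFrame:
    """Score every gene present in both the estimates and the microarray folds.

    Returns (gene, replicates, percent_accuracy) with replicates packed as
    "x1/y1;x2/y2;..." strings in replicate order.
    """
    rows = []
    for gene, sub in estimates.groupby("gene", sort=True):
        if gene not in microarray_folds:
            continue
        matches, acc = score_gene(sub, microarray_folds[gene], gene=str(gene))
        packed = ";".join(f"{m.x}/{m.y}" for m in matches)
        rows.append(dict(gene=gene, replicates=packed, percent_accuracy=acc))
    return pd.DataFrame(rows, columns=["gene", "replicates", "percent_accuracy"])


def select_panel(
    scores: pd.DataFrame,
    summaries: pd.DataFrame,
    flags: Mapping[str, bool] | None = None,
    threshold: float = 70.0,
) -> tuple[pd.DataFrame, float]:
    """Apply the three panel criteria and report the panel's mean accuracy.

    A gene enters the panel iff percent_accuracy >= threshold (the
    "minimum 70 percent" bound is inclusive), it passed the >= 2-plate
    replicate filter, and its pathophysiology-relevance flag is set.  The
    returned mean accuracy is over panel members only, rounded to 1 decimal
    (nan for an empty panel).
    """
    flags = dict(flags or {})
    merged = scores.merge(
        summaries[["gene", "passes_replicate_filter"]], on="gene", how="left"
    )
    merged["passes_replicate_filter"] = merged["passes_replicate_filter"].fillna(False).astype(bool)
    merged["passes_accuracy"] = merged["percent_accuracy"] >= threshold
    merged["pathophysiology_relevant"] = (
        merged["gene"].map(lambda g: bool(flags.get(g, False))).astype(bool)
    )
    merged["in_panel"] = (
        merged["passes_accuracy"] & merged["passes_replicate_filter"] & merged["pathophysiology_relevant"]
    )
    panel = merged[merged["in_panel"]]
    mean_acc = round(float(panel["percent_accuracy"].mean()), 1) if len(panel) else float("nan")
    cols = [
        "gene",
        "percent_accuracy",
        "passes_accuracy",
        "passes_replicate_filter",
        "pathophysiology_relevant",
        "in_panel",
    ]
    return merged[cols].reset_index(drop=True), mean_acc
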