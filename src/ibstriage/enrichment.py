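"""Hypergeometric over-representation of a hit list against gene-set annotations.

The test is the one-sided hypergeometric upper tail (Fisher's exact test's
enriched side): with a universe of N genes of which K belong to a term and a
hit list of n genes of which k fall in the term, p = P(X >= k) for
X ~ Hypergeom(N, K, n).  The universe defaults to all genes on the array.
P-values are uncorrected; terms are ranked by increasing p, ties broken by
term id.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class AnnotationSet:
    """One gene set: identifier, human-readable name, member genes."""

    term_id: str
    term_name: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"annotation {self.term_id} has no genes")


def read_gmt(path: str | Path) -> list[AnnotationSet]:
    """Read a GMT file (tab-separated: term id, description, member genes...).

    Parsed directly so the description column survives as ``term_name``.
    """
    annotations = []
    seen: set[str] = set()
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line (needs id, description, >=1 gene): {line[:80]!r}")
        term_id, name, genes = parts[0], parts[1], [g for g in parts[2:] if g]
        if term_id in seen:
            raise ValueError(f"duplicate term id in GMT: {term_id}")
        seen.add(term_id)
        annotations.append(AnnotationSet(term_id, name, frozenset(genes)))
    return annotations


def write_gmt(annotations: Iterable[AnnotationSet | tuple], path: str | Path) -> None:
    lines = []
    for ann in annotations:
        if isinstance(ann, AnnotationSet):
            term_id, name, genes = ann.term_id, ann.term_name, ann.genes
        else:
            term_id, name, genes = ann
        lines.append("\t".join([term_id, name, *sorted(genes)]))
    Path(path).write_text("\n".join(lines) + "\n")


def hypergeometric_enrichment(
    de_genes: Iterable[str],
    annotations: Sequence[AnnotationSet],
    universe: Iterable[str],
) -> pd.DataFrame:
    """Score every term for over-representation of the DE list.

    Returns a DataFrame (term_id, term_name, k, K, n, N, p_value) sorted by
    increasing p_value, ties broken by term_id.  Each annotation is
    intersected with the universe before testing, so genes outside the
    universe never influence a p-value.
    """
    universe = set(universe)
    de = set(de_genes)
    if not universe:
        raise ValueError("universe must be non-empty")
    if not de:
        raise ValueError("DE gene list must be non-empty")
    if not de <= universe:
        raise ValueError(f"DE genes outside universe: {sorted(de - universe)[:5]}")
    N, n = len(universe), len(de)
    records = []
    for ann in annotations:
        members = ann.genes & universe
        K = len(members)
        k = len(members & de)
        # upper tail P(X >= k); sf(k-1) = P(X > k-1)
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if K else 1.0
        records.append(
            dict(term_id=ann.term_id, term_name=ann.term_name, k=k, K=K, n=n, N=N, p_value=min(p, 1.0))
        )
    out = pd.DataFrame(records, columns=["term_id", "term_name", "k", "K", "n", "N", "p_value"])
    return out.sort_values(["p_value", "term_id"], kind="mergesort").reset_index(drop=True)


def select_candidates(
    enrichment: pd.DataFrame,
    de_results: pd.DataFrame,
    annotations: Sequence[AnnotationSet],
    top_terms: int = 25,
    alpha: float = 0.05,
    flags: Mapping[str, bool] | None = None,
) -> list[str]:
    """Pick candidate genes for qPCR validation.

    A gene is a candidate when it is significant in the DE screen AND either
    belongs to one of the ``top_terms`` lowest-p enriched terms (those with
    p < alpha) or carries a pathophysiology-relevance flag.  The flag file is
    an explicit human-judgment input — relevance is never inferred.
    Candidates are returned ranked by decreasing |log2 fold change|.
    """
    flags = dict(flags or {})
    top = enrichment[enrichment["p_value"] < alpha].head(top_terms)
    term_members: set[str] = set()
    by_id = {a.term_id: a for a in annotations}
    for term_id in top["term_id"]:
        term_members |= set(by_id[term_id].genes)
    sig = de_results[de_results["significant"]]
    keep = sig[
        sig["gene"].isin(term_members) | sig["gene"].map(lambda g: bool(flags.get(g, False)))
    ]
    ranked = keep.reindex(keep["log2_fc"].abs().sort_values(ascending=False, kind="mergesort").index)
    return list(ranked["gene"])
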