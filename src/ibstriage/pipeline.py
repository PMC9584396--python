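"""End-to-end orchestration: simulate -> DE -> enrichment -> qPCR -> concordance -> 1,25D.

``run_pipeline`` executes the whole triage sequence on synthetic data (or on
user-supplied files for individual stages via the CLI), validates
inter-stage contracts, and emits a run manifest — config snapshot, seed,
sha256 digest of every stage output, stage timings, versions — plus a
numeric report whose every figure traces back to a manifest-listed file.
"""

from __future__ import annotations

import hashlib
import json
import time
from importlib import resources
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import __version__
from .concordance import score_all, select_panel
from .config import SimulationConfig, load_pipeline_config
from .de import run_de_screen, top_n_filter
from .enrichment import hypergeometric_enrichment, read_gmt, select_candidates, write_gmt
from .qpcr import cohort_fold, ddct_fold, summarize_all
from .simulate import (
    simulate_annotations,
    simulate_cohort,
    simulate_microarray,
    simulate_qpcr,
)
from .vitd import analyze_treatment


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def load_study_cohort() -> pd.DataFrame:
    """Packaged study-population cohort table (sample_id, classification, subtype, sex, age)."""
    with resources.files("ibstriage.data").joinpath("study_cohort.csv").open() as fh:
        return pd.read_csv(fh)


def load_published_panel() -> pd.DataFrame:
    """Packaged seven-gene biomarker panel: microarray fold, cohort qPCR fold, percent accuracy."""
    with resources.files("ibstriage.data").joinpath("published_panel.csv").open() as fh:
        return pd.read_csv(fh)


def load_panel_replicate_matches() -> pd.DataFrame:
    """Per-replicate match counts (gene, replicate, x, y) for the seven panel genes.

    The published table prints only per-gene accuracies; these counts are a
    reconstruction consistent with 11 patients per replicate that reproduces
    every printed accuracy exactly under the percent-accuracy formula.
    """
    with resources.files("ibstriage.data").joinpath("panel_replicate_matches.csv").open() as fh:
        return pd.read_csv(fh)


def export_heatmap_table(data: pd.DataFrame, path: str | Path | None = None) -> pd.DataFrame:
    """Flatten a matrix or per-gene summary into a plot-ready long table.

    Accepts either a wide genes x samples DataFrame (index = genes) or a
    per-gene summary with a ``mean_fold`` column.  Returns rows of
    (gene, sample, value, direction) where direction = sign(log2 value):
    +1 induced, -1 repressed, 0 unchanged.
    """
    if data.empty:
        raise ValueError("nothing to export")
    if "mean_fold" in data.columns:
        long = pd.DataFrame(
            {"gene": data["gene"], "sample": "cohort", "value": data["mean_fold"]}
        )
    else:
        long = (
            data.rename_axis(index="gene")
            .reset_index()
            .melt(id_vars="gene", var_name="sample", value_name="value")
        )
    long["direction"] = np.sign(np.log2(long["value"].astype(float))).astype(int)
    if path is not None:
        long.to_csv(path, sep="\t", index=False)
    return long


def run_pipeline(
    config: SimulationConfig | Mapping | str | Path,
    out_dir: str | Path,
    seed: int | None = None,
) -> tuple[dict, dict]:
    """Run every stage in order on synthetic data; return (manifest, report).

    ``config`` is a :class:`SimulationConfig`, a pipeline mapping with an
    optional ``simulation`` block plus stage options (``alpha``, ``rule``,
    ``top_n``, ``top_terms``, ``n_qpcr_genes``, ``accuracy_threshold``,
    ``gmt``, ``relevant_genes``), or a path to a YAML file of the same
    shape.  ``seed`` overrides the config seed.  A stage failure aborts with
    the failing stage named; outputs of completed stages are retained.
    """
    if isinstance(config, (str, Path)):
        config = load_pipeline_config(config)
    if isinstance(config, SimulationConfig):
        sim_config, options = config, {}
    else:
        options = {k: v for k, v in dict(config).items() if k != "simulation"}
        sim_config = SimulationConfig.from_dict(config.get("simulation", {}))
    if seed is not None:
        sim_config = SimulationConfig.from_dict({**sim_config.to_dict(), "seed": seed})

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": sim_config.to_dict(),
        "options": options,
        "seed": sim_config.seed,
        "versions": {"ibstriage": __version__, "numpy": np.__version__, "pandas": pd.__version__},
        "stages": {},
        "digests": {},
    }
    report: dict = {}

    def record(stage: str, t0: float, files: dict[str, Path]) -> None:
        manifest["stages"][stage] = {
            "seconds": round(time.perf_counter() - t0, 3),
            "outputs": {k: str(p) for k, p in files.items()},
        }
        for key, p in files.items():
            manifest["digests"][f"{stage}/{key}"] = _sha256(p)

    stage = "simulate"
    try:
        t0 = time.perf_counter()
        cohort = simulate_cohort(sim_config)
        matrix = simulate_microarray(sim_config, cohort)
        cohort_path = out / "cohort.csv"
        cohort.to_csv(cohort_path, index=False)
        matrix_path, truth_path = out / "expression.tsv", out / "planted_truth.json"
        matrix.to_tsv(matrix_path, truth_path)
        record(stage, t0, {"cohort": cohort_path, "matrix": matrix_path, "truth": truth_path})

        stage = "de"
        t0 = time.perf_counter()
        alpha = float(options.get("alpha", 0.05))
        de_results = run_de_screen(matrix, cohort, alpha=alpha, rule=options.get("rule", "any"))
        shortlist = top_n_filter(de_results, int(options.get("top_n", 200)))
        de_path = out / "de_results.tsv"
        de_results.to_csv(de_path, sep="\t", index=False)
        record(stage, t0, {"results": de_path})
        report["n_significant"] = int(de_results["significant"].sum())
        report["n_shortlist"] = int(len(shortlist))

        stage = "enrich"
        t0 = time.perf_counter()
        gmt_path = options.get("gmt")
        if gmt_path:
            annotations = read_gmt(gmt_path)
        else:
            triples = simulate_annotations(sim_config, matrix.planted_truth, matrix.gene_ids)
            gmt_path = out / "annotations.gmt"
            write_gmt(triples, gmt_path)
            annotations = read_gmt(gmt_path)
        de_genes = set(shortlist["gene"]) if len(shortlist) else set()
        if de_genes:
            enrichment = hypergeometric_enrichment(de_genes, annotations, matrix.gene_ids)
        else:
            enrichment = pd.DataFrame(columns=["term_id", "term_name", "k", "K", "n", "N", "p_value"])
        enrich_path = out / "enrichment.tsv"
        enrichment.to_csv(enrich_path, sep="\t", index=False)
        flags = {g: True for g in options.get("relevant_genes", [])}
        candidates = select_candidates(
            enrichment, de_results, annotations,
            top_terms=int(options.get("top_terms", 25)), alpha=alpha, flags=flags,
        ) if de_genes else []
        candidates = candidates[: int(options.get("n_qpcr_genes", 29))]
        cand_path = out / "candidates.tsv"
        pd.DataFrame({"gene": candidates}).to_csv(cand_path, sep="\t", index=False)
        record(stage, t0, {"gmt": Path(gmt_path), "enrichment": enrich_path, "candidates": cand_path})
        report["top_terms"] = enrichment.head(5)[["term_id", "p_value"]].to_dict("records")
        report["n_candidates"] = len(candidates)

        stage = "qpcr"
        t0 = time.perf_counter()
        truth_folds = {
            g: float(2.0 ** matrix.planted_truth.get(g, 0.0)) for g in candidates
        }
        if truth_folds:
            ct = simulate_qpcr(sim_config, truth_folds, arms=("pooled_control", "case_patient"))
            estimates = ddct_fold(ct, "case_patient", "pooled_control",
                                  efficiency=sim_config.amplification_efficiency)
            summaries = summarize_all(estimates)
        else:
            ct = pd.DataFrame(columns=["gene", "arm", "subject_id", "plate", "well", "ct"])
            estimates = pd.DataFrame(columns=["gene", "subject_id", "plate", "fold"])
            summaries = pd.DataFrame(columns=["gene", "mean_fold", "sem", "n_plates", "passes_replicate_filter"])
        ct_path, est_path, sum_path = out / "ct_patient.csv", out / "qpcr_estimates.tsv", out / "qpcr_summary.tsv"
        ct.to_csv(ct_path, index=False)
        estimates.to_csv(est_path, sep="\t", index=False)
        summaries.to_csv(sum_path, sep="\t", index=False)
        record(stage, t0, {"ct": ct_path, "estimates": est_path, "summary": sum_path})
        report["n_qpcr_pass_filter"] = int(summaries["passes_replicate_filter"].sum()) if len(summaries) else 0

        stage = "concordance"
        t0 = time.perf_counter()
        microarray_folds = dict(zip(de_results["gene"], de_results["fold_change"]))
        scores = score_all(estimates, microarray_folds) if len(estimates) else pd.DataFrame(
            columns=["gene", "replicates", "percent_accuracy"]
        )
        panel_flags = flags or {g: True for g in candidates}
        panel, mean_acc = select_panel(
            scores, summaries, flags=panel_flags,
            threshold=float(options.get("accuracy_threshold", 70.0)),
        )
        scores_path, panel_path = out / "concordance.tsv", out / "panel.tsv"
        scores.to_csv(scores_path, sep="\t", index=False)
        panel.to_csv(panel_path, sep="\t", index=False)
        record(stage, t0, {"scores": scores_path, "panel": panel_path})
        report["panel_genes"] = list(panel.loc[panel["in_panel"], "gene"])
        report["panel_mean_accuracy"] = mean_acc

        stage = "vitd"
        t0 = time.perf_counter()
        fold_map = dict(sim_config.treatment_fold_map)
        patient_dir = cohort_fold(estimates) if len(estimates) else pd.Series(dtype=float)
        if not fold_map and report["panel_genes"]:
            # default cell experiment: treat the top four panel genes, planting
            # folds opposite to each gene's cohort direction (a reversal design)
            for g in report["panel_genes"][:4]:
                fold_map[g] = 0.5 if patient_dir.get(g, 1.0) > 1.0 else 2.0
        if fold_map:
            cell_ct = simulate_qpcr(sim_config, fold_map, arms=("vehicle", "treated"))
            treatment = analyze_treatment(cell_ct, patient_dir.to_dict(),
                                          efficiency=sim_config.amplification_efficiency)
        else:
            cell_ct = pd.DataFrame(columns=["gene", "arm", "subject_id", "plate", "well", "ct"])
            treatment = pd.DataFrame(
                columns=["gene", "fold_1_25d", "p_value", "n_replicates", "significance_tier", "reversal"]
            )
        cell_path, treat_path = out / "ct_cells.csv", out / "treatment.tsv"
        cell_ct.to_csv(cell_path, index=False)
        treatment.to_csv(treat_path, sep="\t", index=False)
        record(stage, t0, {"ct": cell_path, "treatment": treat_path})
        report["n_reversals"] = int(treatment["reversal"].fillna(False).astype(bool).sum()) if len(treatment) else 0

        stage = "export"
        t0 = time.perf_counter()
        heatmap_path = out / "heatmap_long.tsv"
        if len(summaries):
            export_heatmap_table(summaries, heatmap_path)
        else:
            export_heatmap_table(matrix.to_frame().iloc[:50].pipe(lambda d: 2.0**d), heatmap_path)
        record(stage, t0, {"heatmap": heatmap_path})
    except Exception as exc:  # name the failing stage; keep partial outputs
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    report_path = out / "report.json"
    report_path.write_text(json.dumps(report, indent=1, sort_keys=True, default=str))
    return manifest, report
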