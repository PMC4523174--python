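"""Stage orchestration: classify -> correlate -> network, and IHC evaluation.

These functions are the programmatic face of the pipeline; the CLI wraps
them thinly.  All outputs are plain text (TSV/JSON/GraphML) written with
fixed float formatting, so reruns on the same inputs are byte-identical.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd

from . import correlation as corr
from . import ihc as ihc_mod
from .io import ExpressionMatrix, read_fpkm_matrix, tissue_means, write_fpkm_matrix
from .network import build_network, shared_tissue_counts
from .specificity import (
    ClassificationConfig,
    SpecificityResult,
    classify_all,
    results_to_frame,
    write_results,
)

logger = logging.getLogger("tissuespec")

__all__ = ["run_classification", "run_ihc_eval", "load_results"]


def run_classification(
    matrix: str | Path | ExpressionMatrix,
    out_dir: str | Path,
    cfg: ClassificationConfig,
    tissue_map: str | Path | dict | None = None,
    max_combo: int = 4,
) -> dict[str, Path]:
    """Classify a matrix and write per-gene results, census, correlation
    matrices and the co-enrichment network.  Returns the written paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if isinstance(matrix, ExpressionMatrix):
        m = matrix
    else:
        m = read_fpkm_matrix(matrix, tissue_map=tissue_map)
    logger.info(
        "classification thresholds: detection>%g FPKM, high>=%gx, enriched>=%gx, "
        "groups %s, all-high>=%g FPKM, target=%s",
        cfg.detection_limit, cfg.high_fold, cfg.enriched_fold,
        cfg.group_sizes, cfg.all_high_cutoff, cfg.target_tissue,
    )
    tm = tissue_means(m)
    paths = {}
    write_fpkm_matrix(tm, out_dir / "tissue_means.tsv")
    paths["tissue_means"] = out_dir / "tissue_means.tsv"

    results = classify_all(tm, cfg)
    paths.update(write_results(results, out_dir))

    reports, spear, pears = corr.pairwise_correlations(m)
    spear.to_csv(out_dir / "spearman_matrix.tsv", sep="\t", float_format="%.6g")
    pears.to_csv(out_dir / "pearson_matrix.tsv", sep="\t", float_format="%.6g")
    corr.reports_to_frame(reports).to_csv(
        out_dir / "correlations.tsv", sep="\t", index=False, float_format="%.6g"
    )
    paths["spearman"] = out_dir / "spearman_matrix.tsv"
    paths["pearson"] = out_dir / "pearson_matrix.tsv"
    paths["correlations"] = out_dir / "correlations.tsv"

    net = build_network(results, cfg.target_tissue, max_combo=max_combo)
    net.write_graphml(out_dir / "network.graphml")
    net.edge_list_frame().sort_values(["combo", "tissue"]).to_csv(
        out_dir / "network_edges.tsv", sep="\t", index=False
    )
    shared = shared_tissue_counts(results, cfg.target_tissue)
    with open(out_dir / "shared_tissue_counts.json", "w") as fh:
        json.dump(shared, fh, indent=2, sort_keys=True)
        fh.write("\n")
    paths["network"] = out_dir / "network.graphml"
    paths["network_edges"] = out_dir / "network_edges.tsv"
    paths["shared_counts"] = out_dir / "shared_tissue_counts.json"
    return paths


def load_results(path: str | Path) -> list[SpecificityResult]:
    """Read back a per-gene results TSV written by ``write_results``."""
    df = pd.read_csv(path, sep="\t", dtype={"group": str}, keep_default_na=False)
    return [
        SpecificityResult(
            gene_id=str(row["gene_id"]),
            category=str(row["category"]),
            score=float(row["score"]),
            group=frozenset(g for g in str(row["group"]).split(";") if g),
            n_detected_tissues=int(row["n_detected"]),
        )
        for _, row in df.iterrows()
    ]


def run_ihc_eval(
    cohort: str | Path | list,
    out_dir: str | Path,
    compartment: str | None = None,
    collapse: str = "max",
) -> dict[str, Path]:
    """Evaluate a marker cohort: breakdown table, 2x2 and statistics block.

    Cohorts with only one histology class present yield NaN sentinels in
    the statistics (logged as a warning), not a failure.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    records = (
        cohort if isinstance(cohort, list) else ihc_mod.read_cohort(cohort)
    )
    compartments = (
        [compartment]
        if compartment
        else sorted({r.compartment for r in records})
    )
    paths: dict[str, Path] = {}
    for comp in compartments:
        breakdown = ihc_mod.breakdown_table(records, compartment=comp,
                                            collapse=collapse)
        table = ihc_mod.contingency(records, compartment=comp, collapse=collapse)
        stats = ihc_mod.diagnostic_stats(table)
        if any(
            v != v for v in (stats.chi_square, stats.sensitivity, stats.specificity)
        ):
            logger.warning(
                "compartment %s: some statistics undefined (empty class or margin)",
                comp,
            )
        breakdown.to_csv(out_dir / f"{comp}_breakdown.tsv", sep="\t",
                         index_label="status")
        pd.DataFrame(
            table.as_array().astype(int),
            index=["negative", "positive"],
            columns=["benign", "tumor_metastasis"],
        ).to_csv(out_dir / f"{comp}_2x2.tsv", sep="\t", index_label="status")
        with open(out_dir / f"{comp}_stats.json", "w") as fh:
            json.dump(
                {k: (None if v != v else round(v, 6))
                 for k, v in stats.to_dict().items()},
                fh, indent=2, sort_keys=True,
            )
            fh.write("\n")
        paths[f"{comp}_breakdown"] = out_dir / f"{comp}_breakdown.tsv"
        paths[f"{comp}_2x2"] = out_dir / f"{comp}_2x2.tsv"
        paths[f"{comp}_stats"] = out_dir / f"{comp}_stats.json"
    return paths
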