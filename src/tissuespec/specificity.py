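"""Tissue-specificity classification of per-tissue mean FPKM profiles.

Every gene is placed in exactly one category relative to a designated
target tissue (here typically prostate):

``not_detected``
    no tissue mean above the detection limit (1 FPKM).
``highly_enriched``
    target mean at least 50-fold the maximum of all other tissues.
``moderately_enriched``
    target mean at least 5-fold the maximum of all other tissues.
``group_enriched``
    the mean over a group of 2-7 tissues containing the target is at
    least 5-fold the maximum of every excluded tissue, all group members
    detected.
``expressed_all_high`` / ``expressed_all_low``
    detected in every tissue, with all tissue means at/above, resp. at
    least one below, 10 FPKM ("house-keeping" expression).
``enhanced``
    target mean at least 5-fold the average mean over all tissues
    (target included).
``mixed``
    detected somewhere but in none of the categories above.

The tissue-specific score of a gene is its target-tissue mean divided by
the maximum mean among all other tissues; scores >= 50 correspond to the
highly enriched tier, scores in [5, 50) to the moderately enriched tier.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .io import TissueMeanMatrix

__all__ = [
    "CATEGORIES",
    "MAJOR_GROUPS",
    "ClassificationConfig",
    "SpecificityResult",
    "tissue_specific_score",
    "find_enriched_group",
    "classify_gene",
    "classify_all",
    "census",
    "results_to_frame",
    "write_results",
]

CATEGORIES = (
    "not_detected",
    "highly_enriched",
    "moderately_enriched",
    "group_enriched",
    "expressed_all_high",
    "expressed_all_low",
    "enhanced",
    "mixed",
)

#: category -> major group of the four-way census
MAJOR_GROUPS = {
    "not_detected": "not_detected",
    "mixed": "mixed",
    "expressed_all_low": "expressed_in_all",
    "expressed_all_high": "expressed_in_all",
    "highly_enriched": "elevated",
    "moderately_enriched": "elevated",
    "group_enriched": "elevated",
    "enhanced": "elevated",
}


@dataclass(frozen=True)
class ClassificationConfig:
    """Thresholds of the specificity classification.

    Parameters
    ----------
    target_tissue
        Tissue the classification is relative to.
    detection_limit
        FPKM above which (strictly) a gene counts as detected; 1 FPKM is
        roughly one mRNA molecule per cell.
    high_fold, enriched_fold
        Fold thresholds of the highly / moderately enriched tiers (and of
        the group and enhanced criteria, which reuse ``enriched_fold``).
    group_sizes
        Inclusive (min, max) group size of the group-enrichment search,
        counting the target tissue.
    all_high_cutoff
        FPKM splitting expressed-in-all genes into the low/high bands.
    """

    target_tissue: str
    detection_limit: float = 1.0
    high_fold: float = 50.0
    enriched_fold: float = 5.0
    group_sizes: tuple[int, int] = (2, 7)
    all_high_cutoff: float = 10.0

    def __post_init__(self) -> None:
        if not self.detection_limit > 0:
            raise ValueError("detection_limit must be > 0")
        if not (self.high_fold > self.enriched_fold > 1):
            raise ValueError("need high_fold > enriched_fold > 1")
        lo, hi = self.group_sizes
        if not (2 <= lo <= hi):
            raise ValueError("group_sizes must be an increasing range with min >= 2")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ClassificationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "group_sizes" in raw:
            raw["group_sizes"] = tuple(raw["group_sizes"])
        return cls(**raw)


@dataclass
class SpecificityResult:
    """Classification outcome for one gene."""

    gene_id: str
    category: str
    score: float
    group: frozenset[str] = frozenset()
    n_detected_tissues: int = 0


def _as_series(row, tissues=None) -> pd.Series:
    if isinstance(row, pd.Series):
        s = row.astype(float)
    else:
        if tissues is None:
            raise ValueError("tissue labels required for array input")
        s = pd.Series(np.asarray(row, dtype=float), index=list(tissues))
    if (s < 0).any() or not np.isfinite(s.to_numpy()).all():
        raise ValueError("tissue means must be finite and non-negative")
    return s


def tissue_specific_score(row: pd.Series, target: str) -> float:
    """Target-tissue mean FPKM divided by the maximum mean of all others.

    Returns ``inf`` when no other tissue expresses the gene at all but the
    target does, and 0 when the gene is absent everywhere.

    >>> tissue_specific_score(pd.Series({"prostate": 4700.79, "lung": 5.76}),
    ...                       "prostate")
    816.1093750000...
    """
    s = _as_series(row)
    if target not in s.index:
        raise KeyError(f"unknown target tissue {target!r}")
    if len(s) < 2:
        raise ValueError("need at least 2 tissues")
    t = s[target]
    max_other = s.drop(target).max()
    if max_other == 0:
        return float("inf") if t > 0 else 0.0
    return float(t / max_other)


def find_enriched_group(row: pd.Series, cfg: ClassificationConfig) -> frozenset[str] | None:
    """Search for the smallest enriched tissue group containing the target.

    For each group size k in ``cfg.group_sizes`` the candidate group is the
    target plus the k-1 highest-expressing other tissues (ties broken by
    tissue label, so output is deterministic).  A candidate is accepted when
    its mean FPKM is at least ``enriched_fold`` times the maximum FPKM among
    the excluded tissues and every member is detected.  Top-k candidates are
    optimal for this criterion: they simultaneously maximise the group mean
    and minimise the excluded maximum, so the greedy search agrees with
    exhaustive subset enumeration.

    Returns the accepted group with smallest k, or None.
    """
    s = _as_series(row)
    target = cfg.target_tissue
    if target not in s.index:
        raise KeyError(f"unknown target tissue {target!r}")
    others = s.drop(target)
    # sort descending by value, ascending by label on ties
    order = sorted(others.index, key=lambda t: (-others[t], t))
    lo, hi = cfg.group_sizes
    hi = min(hi, len(s) - 1)  # leave at least one excluded tissue
    for k in range(lo, hi + 1):
        members = [target] + order[: k - 1]
        group_vals = s[members]
        if (group_vals <= cfg.detection_limit).any():
            continue
        excluded_max = others[order[k - 1:]].max()
        if group_vals.mean() >= cfg.enriched_fold * excluded_max:
            return frozenset(members)
    return None


def classify_gene(
    row: pd.Series, cfg: ClassificationConfig, gene_id: str = ""
) -> SpecificityResult:
    """Assign the single specificity category of one gene.

    ``row`` is the per-tissue mean FPKM vector (index = tissue labels).
    The precedence chain runs enrichment tiers first, then the group
    search, then expressed-in-all, then enhanced, then mixed, so the
    categories are mutually exclusive and exhaustive.
    """
    s = _as_series(row)
    target = cfg.target_tissue
    if target not in s.index:
        raise KeyError(f"unknown target tissue {target!r}")
    detected = s > cfg.detection_limit
    n_det = int(detected.sum())
    score = tissue_specific_score(s, target)

    def result(cat: str, group: frozenset[str] = frozenset()) -> SpecificityResult:
        return SpecificityResult(gene_id, cat, score, group, n_det)

    if n_det == 0:
        return result("not_detected")
    t = s[target]
    max_other = s.drop(target).max()
    target_det = bool(detected[target])
    if target_det and t >= cfg.high_fold * max_other:
        return result("highly_enriched")
    if target_det and t >= cfg.enriched_fold * max_other:
        return result("moderately_enriched")
    group = find_enriched_group(s, cfg)
    if group is not None:
        return result("group_enriched", group)
    if detected.all():
        if s.min() >= cfg.all_high_cutoff:
            return result("expressed_all_high")
        return result("expressed_all_low")
    if target_det and t >= cfg.enriched_fold * s.mean():
        return result("enhanced")
    return result("mixed")


def classify_all(
    tm: TissueMeanMatrix, cfg: ClassificationConfig
) -> list[SpecificityResult]:
    """Classify every gene of a tissue-mean matrix."""
    return [
        classify_gene(tm.values.loc[g], cfg, gene_id=g) for g in tm.values.index
    ]


def census(results: list[SpecificityResult]) -> dict:
    """Category counts/fractions plus the four-way major-group rollup.

    The four major groups are: not detected, mixed, expressed in all
    tissues (house-keeping), and elevated in the target tissue (highly +
    moderately + group enriched + enhanced).
    """
    n = len(results)
    counts = {c: 0 for c in CATEGORIES}
    for r in results:
        counts[r.category] += 1
    major = {g: 0 for g in ("not_detected", "mixed", "expressed_in_all", "elevated")}
    for c, k in counts.items():
        major[MAJOR_GROUPS[c]] += k
    fractions = {c: (k / n if n else 0.0) for c, k in counts.items()}
    return {
        "n_genes": n,
        "counts": counts,
        "fractions": fractions,
        "major_counts": major,
        "major_fractions": {g: (k / n if n else 0.0) for g, k in major.items()},
    }


def results_to_frame(results: list[SpecificityResult]) -> pd.DataFrame:
    """Tabulate results (group as semicolon-joined sorted labels)."""
    return pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in results],
            "category": [r.category for r in results],
            "score": [r.score for r in results],
            "group": [";".join(sorted(r.group)) for r in results],
            "n_detected": [r.n_detected_tissues for r in results],
        }
    ).set_index("gene_id")


def write_results(
    results: list[SpecificityResult], out_dir: str | Path, prefix: str = "specificity"
) -> dict[str, Path]:
    """Write per-gene TSV plus census TSV/JSON; returns the paths written."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "results": out_dir / f"{prefix}_results.tsv",
        "census_tsv": out_dir / f"{prefix}_census.tsv",
        "census_json": out_dir / f"{prefix}_census.json",
    }
    results_to_frame(results).to_csv(paths["results"], sep="\t", float_format="%.6g")
    cen = census(results)
    pd.DataFrame(
        {
            "category": list(cen["counts"]),
            "count": list(cen["counts"].values()),
            "fraction": ["%.6g" % f for f in cen["fractions"].values()],
        }
    ).to_csv(paths["census_tsv"], sep="\t", index=False)
    with open(paths["census_json"], "w") as fh:
        json.dump(cen, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths
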