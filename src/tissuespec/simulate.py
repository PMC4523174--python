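"""Synthetic expression matrices and IHC cohorts with planted ground truth.

The matrix generator emulates a 27-tissue FPKM compendium with a handful
of samples per tissue, a detection limit of 1 FPKM and a dynamic range of
about 10^4.  Each planted gene is constructed so that its *expected*
tissue means satisfy its category's defining inequality with a margin
strictly inside the thresholds (e.g. highly enriched genes planted at
>= 70-fold where the classifier requires 50-fold), so zero-noise
classification recovers the planted label exactly and moderate
multiplicative noise rarely flips it.  Sample-level values multiply the
planted tissue mean by 2**N(0, noise_sd): log-normal measurement noise on
the log2 scale.

The cohort generator draws one latent 0-3 staining score per case from a
per-histology-class categorical distribution and emits ``replicate_cores``
identical core rows per case; replicate cores share the case's score, so
the planted per-class positivity (P(score >= 2)) is also the per-case
truth after max-collapse.  Default class counts and score probabilities
emulate a four-cohort prostate TMA study (156 benign, 162 tumor across
Gleason grades 2-5, 15 metastases) with a strongly benign-specific
membranous marker.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ExpressionMatrix
from .specificity import CATEGORIES, ClassificationConfig

__all__ = ["MatrixSpec", "CohortSpec", "generate_matrix", "generate_cohort", "TISSUES_27"]

#: prostate plus 26 other human tissue labels
TISSUES_27 = (
    "prostate",
    "adipose", "adrenal_gland", "appendix", "bone_marrow", "brain", "colon",
    "duodenum", "endometrium", "esophagus", "gallbladder", "heart", "kidney",
    "liver", "lung", "lymph_node", "ovary", "pancreas", "placenta",
    "salivary_gland", "skeletal_muscle", "skin", "small_intestine", "spleen",
    "stomach", "testis", "thyroid",
)

DEFAULT_GENES_PER_CATEGORY = {
    # mirrors, at desk scale, a genome where ~30% of genes are undetected,
    # ~23% mixed, ~46% expressed in all tissues and ~1% elevated in the target
    "not_detected": 30,
    "mixed": 23,
    "expressed_all_low": 36,
    "expressed_all_high": 10,
    "highly_enriched": 2,
    "moderately_enriched": 2,
    "group_enriched": 2,
    "enhanced": 2,
}


@dataclass
class MatrixSpec:
    """Recipe for a planted-category expression matrix.

    Fold margins sit strictly inside the classification thresholds
    (highly >= 70x vs the 50x cutoff, moderately 7-35x inside [5, 50),
    group and enhanced at >= ~7x vs the 5x cutoff) so that planted labels
    are unambiguous.
    """

    n_tissues: int = 27
    samples_per_tissue: int = 4
    genes_per_category: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_GENES_PER_CATEGORY)
    )
    noise_sd: float = 0.2  # sd of log2 multiplicative sample noise
    highly_fold_range: tuple[float, float] = (70.0, 700.0)
    moderate_fold_range: tuple[float, float] = (7.0, 35.0)
    group_fold: float = 7.0
    baseline_log10_range: tuple[float, float] = (1.5, 3.5)  # specific-gene level
    group_size_range: tuple[int, int] = (2, 7)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tissues < 10:
            raise ValueError("need at least 10 tissues")
        unknown = set(self.genes_per_category) - set(CATEGORIES)
        if unknown:
            raise ValueError(f"unknown categories: {sorted(unknown)}")
        if any(v < 0 for v in self.genes_per_category.values()):
            raise ValueError("gene counts must be >= 0")
        cfg = ClassificationConfig(target_tissue="x")
        lo, hi = self.moderate_fold_range
        if not (cfg.enriched_fold < lo <= hi < cfg.high_fold):
            raise ValueError(
                "moderate fold margins must lie strictly inside "
                f"({cfg.enriched_fold}, {cfg.high_fold})"
            )
        if self.highly_fold_range[0] < cfg.high_fold:
            raise ValueError("highly fold margin must be >= the 50-fold cutoff")
        if self.group_fold <= cfg.enriched_fold:
            raise ValueError("group fold margin must exceed the 5-fold cutoff")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def _tissue_labels(n: int) -> list[str]:
    if n <= len(TISSUES_27):
        return list(TISSUES_27[:n])
    extra = [f"tissue_{i:02d}" for i in range(n - len(TISSUES_27))]
    return list(TISSUES_27) + extra


def _plant_means(spec: MatrixSpec, category: str, rng: np.random.Generator,
                 tissues: list[str]) -> tuple[np.ndarray, frozenset[str]]:
    """Expected per-tissue means for one gene of a given category."""
    n = len(tissues)
    means = np.zeros(n)
    group: frozenset[str] = frozenset()
    lo10, hi10 = spec.baseline_log10_range

    if category == "not_detected":
        means[:] = rng.uniform(0.0, 0.5, size=n)
    elif category == "highly_enriched":
        t = 10 ** rng.uniform(lo10 + 0.5, hi10 + 0.5)
        fold = rng.uniform(*spec.highly_fold_range)
        means[1:] = rng.uniform(0.0, t / fold, size=n - 1)
        means[rng.integers(1, n)] = t / fold
        means[0] = t
    elif category == "moderately_enriched":
        t = 10 ** rng.uniform(lo10, hi10)
        fold = rng.uniform(*spec.moderate_fold_range)
        means[1:] = rng.uniform(0.0, t / fold, size=n - 1)
        means[rng.integers(1, n)] = t / fold
        means[0] = t
    elif category == "group_enriched":
        k = int(rng.integers(spec.group_size_range[0], spec.group_size_range[1] + 1))
        others = rng.choice(np.arange(1, n), size=k - 1, replace=False)
        level = 10 ** rng.uniform(1.0, 2.5)
        member_idx = np.concatenate([[0], others])
        # members within 2x of each other: no single tissue dominates 5-fold
        means[member_idx] = level * rng.uniform(0.7, 1.4, size=k)
        rest = np.setdiff1d(np.arange(n), member_idx)
        means[rest] = rng.uniform(0.0, means[member_idx].mean() / spec.group_fold,
                                  size=rest.size)
        group = frozenset(tissues[i] for i in member_idx)
    elif category == "expressed_all_low":
        means[:] = rng.uniform(3.0, 9.0, size=n)
    elif category == "expressed_all_high":
        means[:] = rng.uniform(15.0, 60.0, size=n)
    elif category == "enhanced":
        t = rng.uniform(40.0, 80.0)
        means[0] = t
        secondary = rng.choice(np.arange(1, n), size=7, replace=False)
        means[secondary] = t * rng.uniform(0.28, 0.42, size=7)
        rest = np.setdiff1d(np.arange(1, n), secondary)
        means[rest] = rng.uniform(0.0, 0.5, size=rest.size)
    elif category == "mixed":
        if rng.random() < 0.5:
            # target expressed alongside >= 14 tissues at comparable levels
            n_expr = int(rng.integers(14, min(26, n - 1) + 1))
            others = rng.choice(np.arange(1, n), size=n_expr - 1, replace=False)
            idx = np.concatenate([[0], others])
            means[idx] = rng.uniform(4.0, 8.0, size=n_expr)
        else:
            # target silent, a few other tissues expressed
            n_expr = int(rng.integers(2, 11))
            others = rng.choice(np.arange(1, n), size=n_expr, replace=False)
            means[others] = rng.uniform(3.0, 30.0, size=n_expr)
            means[0] = rng.uniform(0.0, 0.5)
    else:  # pragma: no cover
        raise ValueError(f"unknown category {category!r}")
    return means, group


def generate_matrix(spec: MatrixSpec) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Generate a planted expression matrix and its truth table.

    Returns the matrix (target tissue is the first label, ``prostate`` for
    27-tissue specs) and a truth DataFrame indexed by gene id with columns
    ``category`` and ``group`` (semicolon-joined member labels, empty for
    non-group genes).  Deterministic for a given spec (seed included).
    """
    rng = np.random.default_rng(spec.seed)
    tissues = _tissue_labels(spec.n_tissues)
    rows, truth_rows, gene_ids = [], [], []
    i = 0
    for category in CATEGORIES:
        for _ in range(spec.genes_per_category.get(category, 0)):
            means, group = _plant_means(spec, category, rng, tissues)
            noise = rng.normal(0.0, spec.noise_sd,
                               size=(spec.n_tissues, spec.samples_per_tissue))
            samples = means[:, None] * np.exp2(noise)
            rows.append(samples.reshape(-1))
            gene_ids.append(f"g{i:04d}")
            truth_rows.append({"category": category, "group": ";".join(sorted(group))})
            i += 1
    sample_ids = [
        f"{t}.{j + 1}" for t in tissues for j in range(spec.samples_per_tissue)
    ]
    values = pd.DataFrame(
        np.array(rows).reshape(len(gene_ids), -1) if rows else
        np.empty((0, len(sample_ids))),
        index=pd.Index(gene_ids, name="gene_id"),
        columns=sample_ids,
    )
    tissue_of_sample = {s: s.rsplit(".", 1)[0] for s in sample_ids}
    truth = pd.DataFrame(truth_rows, index=pd.Index(gene_ids, name="gene_id"),
                         columns=["category", "group"])
    return ExpressionMatrix(values=values, tissue_of_sample=tissue_of_sample), truth


# --- IHC cohorts -----------------------------------------------------------

def _split(pos: float, neg: float | None = None) -> list[float]:
    """Even low/high split of a positivity rate into score probabilities."""
    neg = 1.0 - pos if neg is None else neg
    return [neg / 2, neg / 2, pos / 2, pos / 2]


DEFAULT_CLASS_COUNTS = {
    "benign": 156, "GG2": 3, "GG3": 76, "GG4": 62, "GG5": 21, "metastasis": 15,
}

#: per-class P(score = 0..3); positivity = P(2) + P(3)
DEFAULT_SCORE_PROBS = {
    "benign": _split(0.814),
    "GG2": _split(0.0),
    "GG3": _split(0.224),
    "GG4": _split(0.113),
    "GG5": _split(0.095),
    "metastasis": _split(0.20),
}


@dataclass
class CohortSpec:
    """Recipe for a synthetic IHC cohort with known per-class positivity."""

    class_counts: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_COUNTS)
    )
    score_probs: dict[str, list[float]] = field(
        default_factory=lambda: {k: list(v) for k, v in DEFAULT_SCORE_PROBS.items()}
    )
    replicate_cores: int = 2
    compartment: str = "membranous"
    seed: int = 0

    def __post_init__(self) -> None:
        from .ihc import HISTOLOGY_CLASSES

        for cls, n in self.class_counts.items():
            if cls not in HISTOLOGY_CLASSES:
                raise ValueError(f"unknown histology class {cls!r}")
            if n < 0:
                raise ValueError("class counts must be >= 0")
        for cls, p in self.score_probs.items():
            if len(p) != 4 or any(x < 0 for x in p) or abs(sum(p) - 1.0) > 1e-9:
                raise ValueError(
                    f"score probabilities for {cls!r} must be 4 values summing to 1"
                )
        if self.replicate_cores < 1:
            raise ValueError("replicate_cores must be >= 1")


def generate_cohort(spec: CohortSpec):
    """Generate IHC core records plus the planted per-class positivity.

    Returns (records, truth) where truth maps each histology class to its
    planted P(positive) = P(score in {2, 3}).  One latent score is drawn
    per case; all replicate cores of the case carry that score.
    """
    from .ihc import IHCRecord

    rng = np.random.default_rng(spec.seed)
    records: list[IHCRecord] = []
    truth: dict[str, float] = {}
    case_no = 0
    for cls in sorted(spec.class_counts):
        n = spec.class_counts[cls]
        if n == 0:
            continue
        probs = spec.score_probs[cls]
        truth[cls] = probs[2] + probs[3]
        scores = rng.choice(4, size=n, p=probs)
        for s in scores:
            case_no += 1
            cid = f"case{case_no:05d}"
            for _ in range(spec.replicate_cores):
                records.append(
                    IHCRecord(case_id=cid, histology=cls, score=int(s),
                              compartment=spec.compartment)
                )
    return records, truth
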