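"""Diagnostic evaluation of IHC-scored tissue biomarkers.

A cohort is a table of tissue-core records: case id, histology class
(benign, Gleason grade 2-5, or metastasis), staining compartment (e.g.
membranous, cytoplasmic) and an intensity score on the 0-3 scale
(0 = no reactivity, 1 = faint, 2 = moderate, 3 = strong reactivity in
more than 30% of epithelial cells).  Scores are dichotomized at 2
(0/1 = low = marker negative, 2/3 = high = marker positive), replicate
cores of a case are collapsed (maximum score by default, the usual TMA
convention), and cases are cross-tabulated as marker status x histology
(benign vs tumor-plus-metastasis).

The 2x2 statistics use the standard closed forms with NO continuity
correction:

    chi2 = n (ad - bc)^2 / (r1 r2 c1 c2)          Pearson chi-square, df=1
    G    = 2 sum O ln(O/E)                        likelihood-ratio statistic
    phi  = (ad - bc) / sqrt(r1 r2 c1 c2)          and n * phi^2 == chi2

With rows ordered negative -> positive and columns benign -> tumor, a
marker of *benign* tissue yields a negative phi.  For binary x binary
data the Spearman coefficient equals phi, so it is reported identically.

The condition being detected is the *benign* gland: sensitivity is the
positive fraction among benign cases, specificity the negative fraction
among tumor cases, and the single-threshold ROC AUC is their average.
Statistics that are undefined (a zero margin, an empty class) are
returned as NaN sentinels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "HISTOLOGY_CLASSES",
    "TUMOR_CLASSES",
    "IHCRecord",
    "ContingencyTable2x2",
    "DiagnosticStats",
    "dichotomize",
    "collapse_cases",
    "contingency",
    "breakdown_table",
    "chi_square",
    "g_test",
    "phi_correlation",
    "sens_spec",
    "binary_auc",
    "ordinal_auc",
    "diagnostic_stats",
    "cross_tabulate",
    "read_cohort",
]

HISTOLOGY_CLASSES = ("benign", "GG2", "GG3", "GG4", "GG5", "metastasis")
TUMOR_CLASSES = ("GG2", "GG3", "GG4", "GG5", "metastasis")

UNDEFINED = float("nan")


@dataclass(frozen=True)
class IHCRecord:
    """One scored tissue core."""

    case_id: str
    histology: str
    score: int
    compartment: str = "cytoplasmic"

    def __post_init__(self) -> None:
        if self.histology not in HISTOLOGY_CLASSES:
            raise ValueError(
                f"case {self.case_id!r}: unknown histology {self.histology!r} "
                f"(expected one of {HISTOLOGY_CLASSES})"
            )
        if self.score not in (0, 1, 2, 3):
            raise ValueError(
                f"case {self.case_id!r}: score {self.score!r} outside 0-3"
            )


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Marker status x histology counts.

    Layout: rows negative/positive, columns benign/tumor:

        a = negative & benign    b = negative & tumor
        c = positive & benign    d = positive & tumor
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for v in (self.a, self.b, self.c, self.d):
            if v < 0 or int(v) != v:
                raise ValueError("contingency counts must be non-negative integers")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def row_totals(self) -> tuple[int, int]:
        return (self.a + self.b, self.c + self.d)

    @property
    def col_totals(self) -> tuple[int, int]:
        return (self.a + self.c, self.b + self.d)

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)


@dataclass(frozen=True)
class DiagnosticStats:
    """Full statistics block for one 2x2 marker table."""

    chi_square: float
    p_value: float
    g_statistic: float
    pearson_r: float
    spearman_rho: float
    sensitivity: float
    specificity: float
    auc: float

    def to_dict(self) -> dict[str, float]:
        return {
            "chi_square": self.chi_square,
            "p_value": self.p_value,
            "g_statistic": self.g_statistic,
            "pearson_r": self.pearson_r,
            "spearman_rho": self.spearman_rho,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "auc": self.auc,
        }


def dichotomize(score: int) -> str:
    """Map an IHC score to marker status: 0/1 -> 'low', 2/3 -> 'high'."""
    if score not in (0, 1, 2, 3):
        raise ValueError(f"IHC score {score!r} outside 0-3")
    return "high" if score >= 2 else "low"


def collapse_cases(
    records: list[IHCRecord],
    compartment: str | None = None,
    collapse: str = "max",
) -> pd.DataFrame:
    """Collapse replicate cores to one row per case.

    Returns a DataFrame indexed by case_id with columns ``histology`` and
    ``score``.  ``collapse`` is 'max' (default TMA convention: a case is
    positive if any core is) or 'mean' (rounded to nearest integer score).
    """
    rows = [
        r for r in records if compartment is None or r.compartment == compartment
    ]
    if not rows:
        return pd.DataFrame(columns=["histology", "score"])
    df = pd.DataFrame(
        {
            "case_id": [r.case_id for r in rows],
            "histology": [r.histology for r in rows],
            "score": [r.score for r in rows],
        }
    )
    hist = df.groupby("case_id")["histology"].agg(
        lambda h: h.iloc[0]
    )
    conflicting = df.groupby("case_id")["histology"].nunique()
    if (conflicting > 1).any():
        bad = conflicting[conflicting > 1].index[0]
        raise ValueError(f"case {bad!r} has conflicting histology labels")
    if collapse == "max":
        score = df.groupby("case_id")["score"].max()
    elif collapse == "mean":
        score = df.groupby("case_id")["score"].mean().round().astype(int)
    else:
        raise ValueError(f"unknown collapse rule {collapse!r}")
    return pd.DataFrame({"histology": hist, "score": score})


def _is_tumor(histology: pd.Series) -> pd.Series:
    return histology.isin(TUMOR_CLASSES)


def contingency(
    records: list[IHCRecord],
    compartment: str | None = None,
    collapse: str = "max",
) -> ContingencyTable2x2:
    """Marker status x (benign vs tumor+metastasis) counts, per case."""
    cases = collapse_cases(records, compartment=compartment, collapse=collapse)
    if cases.empty:
        return ContingencyTable2x2(0, 0, 0, 0)
    positive = cases["score"].map(dichotomize) == "high"
    tumor = _is_tumor(cases["histology"])
    return ContingencyTable2x2(
        a=int((~positive & ~tumor).sum()),
        b=int((~positive & tumor).sum()),
        c=int((positive & ~tumor).sum()),
        d=int((positive & tumor).sum()),
    )


def breakdown_table(
    records: list[IHCRecord],
    compartment: str | None = None,
    collapse: str = "max",
) -> pd.DataFrame:
    """Negative/positive counts per full histology class (benign..metastasis)."""
    cases = collapse_cases(records, compartment=compartment, collapse=collapse)
    out = pd.DataFrame(
        0, index=["negative", "positive"], columns=list(HISTOLOGY_CLASSES)
    )
    if cases.empty:
        return out
    status = cases["score"].map(dichotomize).map(
        {"low": "negative", "high": "positive"}
    )
    for (st, h), k in (
        pd.crosstab(status, cases["histology"]).stack().items()
    ):
        out.loc[st, h] = int(k)
    return out


def _margins_ok(t: ContingencyTable2x2) -> bool:
    return all(m > 0 for m in (*t.row_totals, *t.col_totals))


def chi_square(t: ContingencyTable2x2) -> tuple[float, float]:
    """Pearson chi-square (df=1, no continuity correction) and its p-value."""
    if t.n == 0 or not _margins_ok(t):
        return UNDEFINED, UNDEFINED
    r1, r2 = t.row_totals
    c1, c2 = t.col_totals
    stat = t.n * (t.a * t.d - t.b * t.c) ** 2 / (r1 * r2 * c1 * c2)
    return float(stat), float(stats.chi2.sf(stat, df=1))


def g_test(t: ContingencyTable2x2) -> float:
    """Likelihood-ratio statistic 2*sum O*ln(O/E); empty cells contribute 0."""
    if t.n == 0 or not _margins_ok(t):
        return UNDEFINED
    obs = t.as_array()
    rows = obs.sum(axis=1, keepdims=True)
    cols = obs.sum(axis=0, keepdims=True)
    expected = rows * cols / t.n
    mask = obs > 0
    return float(2.0 * (obs[mask] * np.log(obs[mask] / expected[mask])).sum())


def phi_correlation(t: ContingencyTable2x2) -> tuple[float, float]:
    """Phi coefficient (= Pearson r of the two binary variables).

    For binary data the Spearman coefficient equals phi, so the pair
    (pearson_r, spearman_rho) is returned with identical values.
    """
    if not _margins_ok(t):
        return UNDEFINED, UNDEFINED
    r1, r2 = t.row_totals
    c1, c2 = t.col_totals
    phi = (t.a * t.d - t.b * t.c) / math.sqrt(r1 * r2 * c1 * c2)
    return float(phi), float(phi)


def sens_spec(t: ContingencyTable2x2) -> tuple[float, float]:
    """Sensitivity and specificity for detecting the benign gland.

    sensitivity = positive & benign / all benign;
    specificity = negative & tumor / all tumor.
    """
    benign_total = t.a + t.c
    tumor_total = t.b + t.d
    sens = t.c / benign_total if benign_total else UNDEFINED
    spec = t.b / tumor_total if tumor_total else UNDEFINED
    return float(sens), float(spec)


def binary_auc(t: ContingencyTable2x2) -> float:
    """Trapezoidal ROC AUC of a single-threshold binary test: (sens+spec)/2."""
    sens, spec = sens_spec(t)
    if math.isnan(sens) or math.isnan(spec):
        return UNDEFINED
    return (sens + spec) / 2.0


def ordinal_auc(scores, is_condition) -> float:
    """Mann-Whitney AUC of ordinal scores with tie correction.

    ``is_condition`` flags the class the score is expected to be high in
    (here benign cases).  Returns P(score_cond > score_other) +
    0.5 * P(equal), computed from mid-ranks; equals the trapezoidal area
    under the full ROC curve of the 0-3 score.
    """
    scores = np.asarray(scores, dtype=float)
    cond = np.asarray(is_condition, dtype=bool)
    n1 = int(cond.sum())
    n0 = int((~cond).sum())
    if n1 == 0 or n0 == 0:
        return UNDEFINED
    ranks = stats.rankdata(scores)
    u = ranks[cond].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def diagnostic_stats(t: ContingencyTable2x2) -> DiagnosticStats:
    """All 2x2 statistics of a marker table in one record."""
    chi, p = chi_square(t)
    r, rho = phi_correlation(t)
    sens, spec = sens_spec(t)
    return DiagnosticStats(
        chi_square=chi,
        p_value=p,
        g_statistic=g_test(t),
        pearson_r=r,
        spearman_rho=rho,
        sensitivity=sens,
        specificity=spec,
        auc=binary_auc(t),
    )


def cross_tabulate(
    status_a, status_b
) -> tuple[ContingencyTable2x2, DiagnosticStats]:
    """2x2 of marker A status x marker B status on the same cases.

    Inputs are aligned boolean sequences (True = positive).  Rows follow A
    (negative, positive), columns follow B.
    """
    a_pos = np.asarray(status_a, dtype=bool)
    b_pos = np.asarray(status_b, dtype=bool)
    if a_pos.shape != b_pos.shape:
        raise ValueError("marker status vectors must be aligned")
    t = ContingencyTable2x2(
        a=int((~a_pos & ~b_pos).sum()),
        b=int((~a_pos & b_pos).sum()),
        c=int((a_pos & ~b_pos).sum()),
        d=int((a_pos & b_pos).sum()),
    )
    return t, diagnostic_stats(t)


def read_cohort(path) -> list[IHCRecord]:
    """Read a cohort TSV with columns case_id, histology, compartment, score."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"case_id", "histology", "compartment", "score"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"cohort file {path}: missing columns {sorted(missing)}")
    records = []
    for i, row in df.iterrows():
        try:
            score = int(row["score"])
        except (TypeError, ValueError):
            raise ValueError(
                f"cohort file {path}, row {i + 2}: non-integer score {row['score']!r}"
            ) from None
        try:
            records.append(
                IHCRecord(
                    case_id=str(row["case_id"]),
                    histology=str(row["histology"]),
                    score=score,
                    compartment=str(row["compartment"]),
                )
            )
        except ValueError as exc:
            raise ValueError(f"cohort file {path}, row {i + 2}: {exc}") from None
    return records
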