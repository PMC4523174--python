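"""Pairwise sample/tissue correlation on log-transformed expression.

Expression values are transformed as log2(FPKM + 1) (a pseudo-count of 1
keeps zeros finite and maps them to 0).  Pearson coefficients are computed
on the transformed values, Spearman coefficients on their mid-ranks (ties
averaged).  All genes are included, zeros too — no detection filter is
applied, matching genome-wide scatterplot practice.

A zero-variance column (e.g. a sample with a constant profile) has no
defined correlation; such pairs are reported as NaN sentinels rather than
failing or contaminating the rest of the matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import ExpressionMatrix, TissueMeanMatrix

__all__ = ["CorrelationReport", "log_transform", "pairwise_correlations"]


@dataclass(frozen=True)
class CorrelationReport:
    """Spearman/Pearson coefficients for one pair of samples or tissues."""

    pair: tuple[str, str]
    spearman: float
    pearson: float
    n_genes: int


def log_transform(values):
    """Elementwise log2(value + 1); input must be non-negative."""
    arr = np.asarray(values, dtype=float)
    if (arr < 0).any():
        raise ValueError("negative expression value in log transform")
    out = np.log2(arr + 1.0)
    if isinstance(values, pd.DataFrame):
        return pd.DataFrame(out, index=values.index, columns=values.columns)
    if isinstance(values, pd.Series):
        return pd.Series(out, index=values.index)
    return out


def _corr_matrix(log_df: pd.DataFrame, rank: bool) -> pd.DataFrame:
    data = log_df.rank(axis=0, method="average") if rank else log_df
    x = data.to_numpy()
    constant = x.max(axis=0) - x.min(axis=0) == 0  # zero-variance columns
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.corrcoef(x, rowvar=False)
    c = np.atleast_2d(c)
    c[constant, :] = np.nan
    c[:, constant] = np.nan
    np.fill_diagonal(c, 1.0)
    return pd.DataFrame(c, index=log_df.columns, columns=log_df.columns)


def pairwise_correlations(
    m: ExpressionMatrix | TissueMeanMatrix,
) -> tuple[list[CorrelationReport], pd.DataFrame, pd.DataFrame]:
    """All pairwise Spearman and Pearson coefficients between columns.

    Returns (reports for each unordered pair, spearman matrix, pearson
    matrix).  Matrices are symmetric with unit diagonal; undefined
    coefficients (zero-variance columns) appear as NaN.
    """
    df = m.values
    if len(df.index) < 3:
        raise ValueError("need at least 3 genes for correlation analysis")
    log_df = log_transform(df)
    spear = _corr_matrix(log_df, rank=True)
    pears = _corr_matrix(log_df, rank=False)
    cols = list(df.columns)
    reports = [
        CorrelationReport(
            pair=(a, b),
            spearman=float(spear.loc[a, b]),
            pearson=float(pears.loc[a, b]),
            n_genes=len(df.index),
        )
        for i, a in enumerate(cols)
        for b in cols[i + 1:]
    ]
    return reports, spear, pears


def reports_to_frame(reports: list[CorrelationReport]) -> pd.DataFrame:
    """Long-format table (pair, spearman, pearson, n_genes)."""
    return pd.DataFrame(
        {
            "id_a": [r.pair[0] for r in reports],
            "id_b": [r.pair[1] for r in reports],
            "spearman": [r.spearman for r in reports],
            "pearson": [r.pearson for r in reports],
            "n_genes": [r.n_genes for r in reports],
        }
    )
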