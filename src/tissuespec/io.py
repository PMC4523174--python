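"""Reading, writing and replicate-collapsing of FPKM expression matrices.

An expression matrix is genes x samples, with every sample assigned to
exactly one tissue and typically several samples per tissue.  Values are
FPKM (fragments per kilobase of exon model per million mapped reads) and
must be finite and non-negative; missing measurements are not allowed and
have to be encoded as 0 upstream.

Two on-disk conventions are supported for the sample -> tissue mapping:

* header encoding: sample columns named ``<tissue>.<replicate>`` (e.g.
  ``prostate.1``, ``prostate.2``); the tissue is everything before the
  last dot, or the whole name if there is no dot;
* sidecar file: a two-column TSV ``sample<TAB>tissue`` passed explicitly.

Tissue labels are case-sensitive and stripped of surrounding whitespace.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "TissueMeanMatrix",
    "MatrixParseError",
    "read_fpkm_matrix",
    "write_fpkm_matrix",
    "read_tissue_map",
    "tissue_means",
]


class MatrixParseError(ValueError):
    """Raised when an expression-matrix file violates the format contract."""


def _check_values(values: np.ndarray, gene_ids, sample_ids) -> None:
    bad = ~np.isfinite(values)
    if bad.any():
        g, s = np.argwhere(bad)[0]
        raise MatrixParseError(
            f"non-finite value at gene {gene_ids[g]!r}, sample {sample_ids[s]!r}"
        )
    neg = values < 0
    if neg.any():
        g, s = np.argwhere(neg)[0]
        raise MatrixParseError(
            f"negative FPKM {values[g, s]!r} at gene {gene_ids[g]!r}, "
            f"sample {sample_ids[s]!r}"
        )


@dataclass
class ExpressionMatrix:
    """Genes x samples FPKM matrix with a sample -> tissue assignment.

    Parameters
    ----------
    values
        DataFrame of non-negative FPKM values, index = gene ids,
        columns = sample ids.
    tissue_of_sample
        Mapping from each sample id to its tissue label.
    """

    values: pd.DataFrame
    tissue_of_sample: dict[str, str]

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)
        if self.values.index.has_duplicates:
            dup = self.values.index[self.values.index.duplicated()][0]
            raise MatrixParseError(f"duplicate gene id {dup!r}")
        if self.values.columns.has_duplicates:
            dup = self.values.columns[self.values.columns.duplicated()][0]
            raise MatrixParseError(f"duplicate sample id {dup!r}")
        self.tissue_of_sample = {
            str(s): str(t).strip() for s, t in self.tissue_of_sample.items()
        }
        missing = [s for s in self.values.columns if s not in self.tissue_of_sample]
        if missing:
            raise MatrixParseError(f"samples without tissue assignment: {missing}")
        _check_values(
            self.values.to_numpy(), list(self.values.index), list(self.values.columns)
        )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def tissues(self) -> list[str]:
        """Distinct tissue labels, sorted."""
        return sorted(set(self.tissue_of_sample[s] for s in self.values.columns))


@dataclass
class TissueMeanMatrix:
    """Genes x tissues matrix of per-tissue mean FPKM (one column per tissue)."""

    values: pd.DataFrame  # index = gene ids, columns = tissue labels (sorted)

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)
        _check_values(
            self.values.to_numpy(), list(self.values.index), list(self.values.columns)
        )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def tissue_ids(self) -> list[str]:
        return list(self.values.columns)


def _tissue_from_header(name: str) -> str:
    base, _, tail = name.rpartition(".")
    return (base if base else name).strip()


def read_tissue_map(path: str | Path) -> dict[str, str]:
    """Read a two-column ``sample<TAB>tissue`` sidecar file (no header)."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    if df.shape[1] != 2:
        raise MatrixParseError(
            f"tissue map {path}: expected 2 columns, found {df.shape[1]}"
        )
    return {str(s).strip(): str(t).strip() for s, t in zip(df[0], df[1])}


def read_fpkm_matrix(
    path: str | Path, tissue_map: dict[str, str] | str | Path | None = None
) -> ExpressionMatrix:
    """Read a tab-separated FPKM matrix.

    First column holds gene ids, the remaining columns one sample each.
    ``tissue_map`` may be a dict, a path to a sidecar TSV, or None, in
    which case tissues are derived from column names (``tissue.replicate``).

    Raises
    ------
    MatrixParseError
        On malformed rows, negative or non-numeric values, or duplicate
        gene/sample ids; the message names the offending row/column.
    """
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise MatrixParseError(f"cannot parse {path}: {exc}") from exc
    df.index = df.index.astype(str)
    df.columns = [str(c) for c in df.columns]
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = df.index[bad.to_numpy().nonzero()[0][0]]
            raise MatrixParseError(
                f"non-numeric value at gene {row!r}, sample {col!r}"
            )
        df[col] = coerced
    if df.isna().any().any():
        gene = df.index[df.isna().any(axis=1)][0]
        raise MatrixParseError(f"missing value in row for gene {gene!r}")

    if tissue_map is None:
        tmap = {c: _tissue_from_header(c) for c in df.columns}
    elif isinstance(tissue_map, (str, Path)):
        tmap = read_tissue_map(tissue_map)
    else:
        tmap = dict(tissue_map)
    return ExpressionMatrix(values=df, tissue_of_sample=tmap)


def write_fpkm_matrix(m: ExpressionMatrix | TissueMeanMatrix, path: str | Path) -> None:
    """Write a matrix as TSV with ``%.6g`` precision (round-trip stable)."""
    m.values.to_csv(path, sep="\t", float_format="%.6g", index_label="gene_id")


def tissue_means(m: ExpressionMatrix) -> TissueMeanMatrix:
    """Collapse sample replicates to the arithmetic per-tissue mean FPKM.

    The average FPKM over a tissue's samples estimates that tissue's total
    expression level.  Columns are ordered by sorted tissue label, so the
    result is invariant to the sample order of the input.
    """
    tissues = pd.Series(
        [m.tissue_of_sample[s] for s in m.values.columns], index=m.values.columns
    )
    means = m.values.T.groupby(tissues).mean().T
    means = means[sorted(means.columns)]
    return TissueMeanMatrix(values=means)
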