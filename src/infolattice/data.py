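"""Labelled real-valued data matrices (samples x variables) and their I/O.

The canonical input is a delimited text table whose first row holds variable
labels and first column holds sample labels.  A transpose flag switches
between the two analyses a measurement table supports: rows-as-samples
(e.g. cells x genes, gene modules as the object of study) and its transpose
(genes x cells, cell types as the object of study).
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd


class DataMatrix:
    """An ``m x n`` real measurement matrix with sample and variable labels.

    Requires ``m >= 2`` samples (a single observation supports no entropy
    estimate) and at least one variable; all values must be finite.
    """

    def __init__(
        self,
        values: np.ndarray,
        sample_labels: Sequence[str] | None = None,
        variable_labels: Sequence[str] | None = None,
        transposed: bool = False,
    ) -> None:
        values = np.asarray(values, dtype=float)
        if values.ndim != 2:
            raise ValueError(f"expected a 2-D matrix, got shape {values.shape}")
        m, n = values.shape
        if m < 2:
            raise ValueError(f"need at least 2 samples, got {m}")
        if n < 1:
            raise ValueError("need at least 1 variable")
        if not np.isfinite(values).all():
            bad = int((~np.isfinite(values)).sum())
            raise ValueError(f"matrix contains {bad} non-finite entries")
        if sample_labels is None:
            sample_labels = [f"s{i}" for i in range(m)]
        if variable_labels is None:
            variable_labels = [f"v{j}" for j in range(n)]
        sample_labels = [str(x) for x in sample_labels]
        variable_labels = [str(x) for x in variable_labels]
        if len(sample_labels) != m:
            raise ValueError("sample_labels length mismatch")
        if len(variable_labels) != n:
            raise ValueError("variable_labels length mismatch")
        for name, labels in (("sample", sample_labels), ("variable", variable_labels)):
            if len(set(labels)) != len(labels):
                raise ValueError(f"duplicate {name} labels")
        self.values = values
        self.sample_labels = list(sample_labels)
        self.variable_labels = list(variable_labels)
        #: whether this matrix is the transpose of its source file
        self.transposed = bool(transposed)

    # -- shape ---------------------------------------------------------------

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_variables(self) -> int:
        return self.values.shape[1]

    def __repr__(self) -> str:
        return (
            f"DataMatrix(m={self.n_samples}, n={self.n_variables}, "
            f"transposed={self.transposed})"
        )

    def transpose(self) -> "DataMatrix":
        """Swap samples and variables (matrix D -> D^T analysis)."""
        return DataMatrix(
            self.values.T,
            sample_labels=self.variable_labels,
            variable_labels=self.sample_labels,
            transposed=not self.transposed,
        )

    # -- conversions ---------------------------------------------------------

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, transpose: bool = False) -> "DataMatrix":
        try:
            values = df.to_numpy(dtype=float)
        except (TypeError, ValueError) as exc:
            raise ValueError(f"non-numeric cells in table: {exc}") from exc
        dm = cls(
            values,
            sample_labels=[str(i) for i in df.index],
            variable_labels=[str(c) for c in df.columns],
        )
        return dm.transpose() if transpose else dm

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.sample_labels, columns=self.variable_labels
        )


def _sep_for(path: Path, sep: str | None) -> str:
    if sep is not None:
        return sep
    return "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","


def read_matrix(
    path: str | Path, transpose: bool = False, sep: str | None = None
) -> DataMatrix:
    """Read a delimited table (first row/column are labels) into a DataMatrix.

    ``transpose=True`` analyses the transpose of the file: rows of the file
    become variables.  The separator defaults to tab for ``.tsv/.tab/.txt``
    and comma otherwise.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=_sep_for(path, sep), index_col=0)
    if df.shape[1] == 0:
        raise ValueError(f"{path}: no data columns found")
    if df.isna().any().any():
        raise ValueError(
            f"{path}: missing values present; impute or drop before loading"
        )
    try:
        return DataMatrix.from_dataframe(df, transpose=transpose)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from exc


def write_matrix(matrix: DataMatrix, path: str | Path, sep: str | None = None) -> None:
    """Write a DataMatrix back to delimited text (round-trips with read_matrix)."""
    path = Path(path)
    matrix.to_dataframe().to_csv(path, sep=_sep_for(path, sep))
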