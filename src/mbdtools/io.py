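"""Reading and writing sample-by-variable expression matrices.

Format: delimited text (CSV, or TSV by extension/``sep``), first row =
variable names, first column = sample identifiers, optional final column
named ``label`` carrying a class identifier per sample.  All other cells
must be numeric and present.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["ExpressionMatrix", "read_matrix", "write_matrix"]

LABEL_COLUMN = "label"


@dataclass
class ExpressionMatrix:
    """n×d numeric matrix: rows are samples, columns are variables (genes).

    ``labels`` is optional; when present it holds one class identifier per
    sample (a labeled matrix in the classification sense).
    """

    values: np.ndarray
    sample_ids: list[str] = field(default=None)  # type: ignore[assignment]
    variable_ids: list[str] = field(default=None)  # type: ignore[assignment]
    labels: np.ndarray | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("invalid matrix: values must be 2-D")
        n, d = self.values.shape
        if self.sample_ids is None:
            self.sample_ids = [f"s{i + 1}" for i in range(n)]
        if self.variable_ids is None:
            self.variable_ids = [f"g{j + 1}" for j in range(d)]
        if len(self.sample_ids) != n or len(self.variable_ids) != d:
            raise ValueError("sample_ids/variable_ids lengths must match the matrix shape")
        if len(set(self.sample_ids)) != n:
            raise ValueError("duplicate sample ids")
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if len(self.labels) != n:
                raise ValueError("labels length must match the number of samples")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def d(self) -> int:
        return self.values.shape[1]

    def subset(self, rows) -> "ExpressionMatrix":
        rows = np.asarray(rows)
        return ExpressionMatrix(
            values=self.values[rows],
            sample_ids=[self.sample_ids[i] for i in rows],
            variable_ids=list(self.variable_ids),
            labels=None if self.labels is None else self.labels[rows],
        )

    def by_class(self) -> dict:
        if self.labels is None:
            raise ValueError("matrix has no labels")
        _, first = np.unique(self.labels, return_index=True)
        classes = self.labels[np.sort(first)]
        return {g: self.subset(np.flatnonzero(self.labels == g)) for g in classes}

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, index=self.sample_ids, columns=self.variable_ids)
        if self.labels is not None:
            df[LABEL_COLUMN] = self.labels
        return df

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "ExpressionMatrix":
        labels = None
        if LABEL_COLUMN in df.columns:
            labels = df[LABEL_COLUMN].to_numpy()
            df = df.drop(columns=[LABEL_COLUMN])
        bad = df.columns[[not pd.api.types.is_numeric_dtype(t) for t in df.dtypes]]
        for col in bad:
            for sid, val in df[col].items():
                try:
                    float(val)
                except (TypeError, ValueError):
                    raise ValueError(
                        f"non-numeric cell at row {sid!r}, column {col!r}: {val!r}"
                    ) from None
        if df.isna().any().any():
            r, c = np.argwhere(df.isna().to_numpy())[0]
            raise ValueError(f"missing cell at row {df.index[r]!r}, column {df.columns[c]!r}")
        return cls(
            values=df.to_numpy(dtype=float),
            sample_ids=[str(i) for i in df.index],
            variable_ids=[str(c) for c in df.columns],
            labels=labels,
        )


def _sep_for(path: Path, sep: str | None) -> str:
    if sep is not None:
        return sep
    return "\t" if path.suffix.lower() in (".tsv", ".tab", ".txt") else ","


def read_matrix(path, sep: str | None = None) -> ExpressionMatrix:
    """Read a CSV/TSV expression matrix (see module docstring for the layout)."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path, sep), index_col=0, float_precision="round_trip")
    return ExpressionMatrix.from_dataframe(df)


def write_matrix(x: ExpressionMatrix, path, sep: str | None = None) -> Path:
    """Write a matrix; round-trips finite doubles exactly (repr precision)."""
    path = Path(path)
    x.to_dataframe().to_csv(
        path, sep=_sep_for(path, sep), index_label="sample_id", float_format="%.17g"
    )
    return path
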