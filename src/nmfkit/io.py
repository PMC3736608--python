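"""Delimited-text I/O for expression matrices and label vectors.

Matrices are stored features-by-samples: feature IDs in the first column,
sample IDs in the header row, NaN (empty or ``NA``) for missing cells.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .factorizations import DataMatrix

__all__ = ["read_matrix", "write_matrix", "read_labels", "write_labels"]


def read_matrix(path: str | Path, sep: str | None = None) -> pd.DataFrame:
    """Read a feature-by-sample matrix (TSV by default, CSV by extension)."""
    if sep is None:
        sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0)
    return df.astype(float)


def write_matrix(df: pd.DataFrame | np.ndarray, path: str | Path,
                 sep: str | None = None) -> None:
    if sep is None:
        sep = "," if str(path).endswith(".csv") else "\t"
    if not isinstance(df, pd.DataFrame):
        arr = np.asarray(df)
        df = pd.DataFrame(
            arr,
            index=[f"f{i+1}" for i in range(arr.shape[0])],
            columns=[f"s{j+1}" for j in range(arr.shape[1])],
        )
    df.to_csv(path, sep=sep)


def as_data_matrix_frame(df: pd.DataFrame) -> DataMatrix:
    """DataMatrix view of a features-by-samples frame."""
    return DataMatrix.from_array(df.to_numpy(dtype=float))


def read_labels(path: str | Path) -> pd.Series:
    """Read a two-column (sample_id TAB class) label file."""
    df = pd.read_csv(path, sep="\t", header=None, names=["sample", "label"])
    return df.set_index("sample")["label"]


def write_labels(labels: pd.Series | dict, path: str | Path) -> None:
    s = pd.Series(labels)
    s.to_csv(path, sep="\t", header=False)
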