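"""Normalization, sparsity and gene-list utilities."""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
from numpy.typing import ArrayLike, NDArray

__all__ = [
    "normalize_mean0_std1",
    "matrix_sparsity",
    "write_gene_list",
    "read_gene_list",
]


def normalize_mean0_std1(
    X: ArrayLike, axis: Literal["features", "samples"] = "features"
) -> NDArray[np.float64]:
    """Standardize each feature row (or sample column) to mean 0, std 1.

    Uses the sample standard deviation (denominator length - 1).  A constant
    vector cannot be standardized; it is set to zeros with a warning.
    """
    X = np.asarray(X, dtype=float)
    if axis == "features":
        ax = 1
    elif axis == "samples":
        ax = 0
    else:
        raise ValueError(f"axis must be 'features' or 'samples', got {axis!r}")
    mu = X.mean(axis=ax, keepdims=True)
    sd = X.std(axis=ax, ddof=1, keepdims=True)
    constant = sd <= 0
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant vector(s) set to zeros during "
            "standardization"
        )
    sd = np.where(constant, 1.0, sd)
    out = (X - mu) / sd
    return np.where(np.broadcast_to(constant, out.shape), 0.0, out)


def matrix_sparsity(M: ArrayLike, zero_tol: float = 0.0) -> float:
    """Fraction of entries with |entry| <= zero_tol.

    With the default exact-zero tolerance, active-set factorizations (which
    produce true zeros) report their sparsity directly; multiplicative-rule
    outputs only approach zero, so pass a small positive ``zero_tol`` for
    them.
    """
    if zero_tol < 0:
        raise ValueError("zero_tol must be >= 0")
    M = np.asarray(M, dtype=float)
    if M.size == 0:
        raise ValueError("matrix is empty")
    return float((np.abs(M) <= zero_tol).mean())


def write_gene_list(
    names: Sequence[str],
    path: str | Path,
    scores: Sequence[float] | None = None,
) -> None:
    """Write one feature name per line, optionally with a tab-separated score."""
    if len(names) == 0:
        raise ValueError("gene list is empty")
    if scores is not None and len(scores) != len(names):
        raise ValueError("scores length must match names")
    with open(path, "w", encoding="utf-8") as fh:
        for i, name in enumerate(names):
            if scores is not None:
                fh.write(f"{name}\t{scores[i]:.6g}\n")
            else:
                fh.write(f"{name}\n")


def read_gene_list(path: str | Path) -> tuple[list[str], list[float] | None]:
    """Round-trip reader for :func:`write_gene_list`."""
    names: list[str] = []
    scores: list[float] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            names.append(parts[0])
            if len(parts) > 1:
                scores.append(float(parts[1]))
    return names, (scores if scores else None)
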