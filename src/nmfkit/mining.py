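"""NMF-based mining: clustering, rank selection, biclustering, feature
extraction and factor-specific feature selection.

Clustering reads each sample's dominant coefficient: sample i joins the
cluster of the basis vector with the largest entry in column y_i.  Rank
selection repeats the factorization from random restarts, accumulates a
consensus matrix C (how often two samples co-cluster) and picks the rank
whose consensus is most nearly binary, measured by the dispersion
coefficient rho = (1/n^2) sum_ij 4 (C_ij - 1/2)^2.  A bicluster pairs each
factor's dominant samples (argmax columns) with its heavily-loaded features
(basis weight above mean + z * std of that column).  Feature extraction
learns A on training data and projects unknowns by NNLS; the entropy score
ranks features by how factor-specific their basis row is.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any, Callable, Literal

import numpy as np
from numpy.typing import ArrayLike, NDArray

from .factorizations import (
    DataMatrix,
    FactorizationResult,
    FitOptions,
    VSMFConfig,
    as_data_matrix,
    convex_nmf,
    nmf_multiplicative,
    nmf_nnls,
    orth_nmf,
    seminmf,
    sparse_nmf,
    vsmf,
)
from .kernels import KernelSpec, compute_kernel_matrix, kernel_seminmf
from .solvers import QPProblem, solve_nnls, solve_nnqp

__all__ = [
    "ClusterResult",
    "ConsensusSummary",
    "Bicluster",
    "FeatureSpace",
    "EntropySelection",
    "assign_clusters",
    "choose_best_k",
    "bicluster",
    "extract_features_train",
    "extract_features_test",
    "select_features_entropy",
    "FACTORIZATION_METHODS",
]


# registry used by extract_features_train and the examples
FACTORIZATION_METHODS: dict[str, Callable[..., FactorizationResult]] = {
    "nmf": nmf_nnls,
    "nmf-mult": nmf_multiplicative,
    "seminmf": seminmf,
    "sparse": sparse_nmf,
    "vsmf": vsmf,
    "convex": convex_nmf,
    "orth": orth_nmf,
}


@dataclass
class ClusterResult:
    """Hard cluster assignment read off a coefficient matrix (labels 1..k)."""

    labels: NDArray[np.int_]
    Y: NDArray[np.float64]
    k: int


@dataclass
class ConsensusSummary:
    """Consensus matrix over restarts and its dispersion coefficient."""

    C: NDArray[np.float64]
    dispersion: float
    runs: int
    k: int


@dataclass
class Bicluster:
    """One factor's associated feature set and sample set (0-based indices)."""

    factor_index: int
    row_members: NDArray[np.int_]
    col_members: NDArray[np.int_]


@dataclass
class FeatureSpace:
    """NMF feature space: basis A learned on training data, coefficients of
    training and (after projection) unknown samples."""

    A: NDArray[np.float64] | None
    Y_tr: NDArray[np.float64]
    k: int
    method: str
    kernel: KernelSpec | None = None
    X_tr: NDArray[np.float64] | None = None
    pseudo: NDArray[np.float64] | None = None
    Y_uk: NDArray[np.float64] | None = None
    S: NDArray[np.float64] | None = None


@dataclass
class EntropySelection:
    """Entropy-based factor-specificity scores and per-factor selections."""

    p: NDArray[np.float64]
    score: NDArray[np.float64]
    selected: dict[int, NDArray[np.int_]] = field(default_factory=dict)
    threshold: float = 0.0
    excluded_rows: NDArray[np.int_] = field(default_factory=lambda: np.array([], int))


def assign_clusters(Y: ArrayLike) -> ClusterResult:
    """Cluster each sample by its largest coefficient (ties -> lowest row).

    The label of sample i is the 1-based index of the argmax row of y_i.
    """
    Y = np.asarray(Y, dtype=float)
    if Y.min() < 0:
        raise ValueError("coefficient matrix must be non-negative")
    zero_cols = ~Y.any(axis=0)
    if zero_cols.any():
        warnings.warn(
            f"{int(zero_cols.sum())} all-zero coefficient column(s) assigned "
            "to cluster 1"
        )
    labels = Y.argmax(axis=0) + 1  # argmax takes the lowest index on ties
    return ClusterResult(labels=labels.astype(int), Y=Y, k=Y.shape[0])


def dispersion_coefficient(C: ArrayLike) -> float:
    """rho = (1/n^2) sum_ij 4 (C_ij - 1/2)^2; 1 iff C is binary."""
    C = np.asarray(C, dtype=float)
    n = C.shape[0]
    return float(np.sum(4.0 * (C - 0.5) ** 2) / n**2)


def choose_best_k(
    data: DataMatrix | ArrayLike,
    k_range: list[int],
    runs: int = 20,
    opts: FitOptions | None = None,
    method: str = "nmf",
) -> tuple[int, dict[int, ConsensusSummary]]:
    """Pick the rank whose consensus clustering is most stable.

    For each candidate k, run ``runs`` factorizations from different seeds,
    count how often each sample pair lands in the same argmax cluster
    (consensus matrix C), and score stability by the dispersion coefficient.
    The best k maximizes dispersion; ties go to the larger k (merging
    well-separated clusters is always stable, so small k would otherwise win
    degenerately).
    """
    if not k_range:
        raise ValueError("k_range is empty")
    data = as_data_matrix(data)
    opts = opts or FitOptions()
    if runs < 10:
        warnings.warn("fewer than 10 consensus runs gives an unstable dispersion")
    fit = FACTORIZATION_METHODS[method]
    n = data.shape[1]
    summaries: dict[int, ConsensusSummary] = {}
    for k in k_range:
        C = np.zeros((n, n))
        for r in range(runs):
            run_opts = FitOptions(
                max_iter=opts.max_iter, tol=opts.tol, seed=opts.seed + r * 9973
            )
            labels = assign_clusters(fit(data, k, opts=run_opts).Y).labels
            C += (labels[:, None] == labels[None, :]).astype(float)
        C /= runs
        summaries[k] = ConsensusSummary(
            C=C, dispersion=dispersion_coefficient(C), runs=runs, k=k
        )
    best_k = max(k_range, key=lambda k: (summaries[k].dispersion, k))
    return best_k, summaries


def bicluster(
    data: DataMatrix | ArrayLike,
    k: int,
    row_z: float = 1.0,
    opts: FitOptions | None = None,
    method: str = "nmf",
) -> tuple[list[Bicluster], FactorizationResult]:
    """Simultaneously group features and samples through one factorization.

    Factor q's samples are those whose coefficient argmax is q (a partition);
    its features are those with basis weight A_iq >= mean + row_z * std of
    column q.
    """
    data = as_data_matrix(data)
    if data.sign_mode != "non-negative":
        raise ValueError("biclustering requires non-negative data")
    res = FACTORIZATION_METHODS[method](data, k, opts=opts or FitOptions())
    labels = assign_clusters(res.Y).labels
    out: list[Bicluster] = []
    for q in range(k):
        col = res.A[:, q]
        thr = col.mean() + row_z * col.std()
        rows = np.flatnonzero(col >= thr)
        cols = np.flatnonzero(labels == q + 1)
        if rows.size == 0 or cols.size == 0:
            warnings.warn(f"bicluster {q + 1} is empty")
        out.append(Bicluster(factor_index=q + 1, row_members=rows, col_members=cols))
    return out, res


def extract_features_train(
    data: DataMatrix | ArrayLike,
    k: int,
    method: str = "nmf",
    opts: FitOptions | None = None,
    kernel: KernelSpec | None = None,
    cfg: VSMFConfig | None = None,
) -> FeatureSpace:
    """Learn the k-dimensional NMF feature space X = A Y_tr from training data.

    With a kernel spec, the basis lives implicitly in feature space and only
    coefficients plus the pseudo-inverse needed for projection are stored.
    """
    data = as_data_matrix(data)
    opts = opts or FitOptions()
    X = data.X
    if kernel is not None:
        K = compute_kernel_matrix(X, X, kernel)
        kf = kernel_seminmf(K, k, "nnls", 0.0, opts)
        return FeatureSpace(
            A=None, Y_tr=kf.Y, k=k, method="kernel-seminmf",
            kernel=kernel, X_tr=X, pseudo=kf.pseudo,
        )
    if method not in FACTORIZATION_METHODS:
        raise ValueError(
            f"unknown method {method!r}; supported: "
            f"{sorted(FACTORIZATION_METHODS)}"
        )
    fit = FACTORIZATION_METHODS[method]
    if method in ("sparse", "vsmf"):
        res = fit(data, k, cfg or VSMFConfig(), opts=opts)
    else:
        res = fit(data, k, opts=opts)
    return FeatureSpace(A=res.A, Y_tr=res.Y, k=k, method=method, X_tr=X)


def extract_features_test(space: FeatureSpace, S: ArrayLike) -> NDArray[np.float64]:
    """Project unknown samples S into the learned space: S = A Y_uk, Y_uk >= 0.

    Linear spaces solve NNLS against the stored basis; kernel spaces use
    K(X_tr, S) inner products only.
    """
    S = np.asarray(S, dtype=float)
    if space.kernel is not None:
        if S.shape[0] != space.X_tr.shape[0]:
            raise ValueError("feature dimension of S does not match training data")
        K_ts = compute_kernel_matrix(space.X_tr, S, space.kernel)
        P = space.pseudo
        K_tr = compute_kernel_matrix(space.X_tr, space.X_tr, space.kernel)
        H = P.T @ K_tr @ P
        G = -(P.T @ K_ts)
        Y_uk = solve_nnqp(QPProblem(0.5 * (H + H.T), G), check_psd=False).Z
    else:
        if S.shape[0] != space.A.shape[0]:
            raise ValueError(
                f"S has {S.shape[0]} features but the space was learned on "
                f"{space.A.shape[0]}"
            )
        Y_uk = solve_nnls(space.A, S).Z
    space.Y_uk = Y_uk
    space.S = S
    return Y_uk


def select_features_entropy(
    A: ArrayLike, threshold_sd: float = 2.0
) -> EntropySelection:
    """Score each feature by how factor-specific its basis row is.

    Row weights p(i, q) = A_iq / sum_q A_iq give a per-feature distribution
    over factors; the score 1 + (1/log2 k) sum_q p log2 p is 1 for a one-hot
    row (fully factor-specific) and 0 for a uniform row.  Features scoring
    above mean + threshold_sd * std are selected and assigned to their argmax
    factor.
    """
    A = np.asarray(A, dtype=float)
    if A.ndim != 2 or A.shape[1] < 2:
        raise ValueError("entropy selection needs a basis with k >= 2 factors")
    if A.min() < 0:
        raise ValueError("basis must be non-negative")
    m, k = A.shape
    rowsum = A.sum(axis=1)
    excluded = np.flatnonzero(rowsum <= 0)
    safe = np.where(rowsum > 0, rowsum, 1.0)
    p = A / safe[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log2(p), 0.0)
    score = 1.0 + plogp.sum(axis=1) / np.log2(k)
    score[excluded] = np.nan

    valid = ~np.isnan(score)
    thr = float(np.mean(score[valid]) + threshold_sd * np.std(score[valid]))
    chosen = np.flatnonzero(valid & (score > thr))
    sel: dict[int, NDArray[np.int_]] = {q: [] for q in range(1, k + 1)}
    for i in chosen:
        sel[int(A[i].argmax()) + 1].append(i)
    selected = {q: np.asarray(v, dtype=int) for q, v in sel.items()}
    return EntropySelection(
        p=p, score=score, selected=selected, threshold=thr, excluded_rows=excluded
    )
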