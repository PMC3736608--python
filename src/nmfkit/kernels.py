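"""Kernelized factorizations operating on inner products only.

Semi-NMF's alternating updates need the data matrix X only through the Gram
matrix X'X: the least-squares basis update A = X Y-dagger gives
A'A = (Y-dagger)' X'X Y-dagger  and  A'X = (Y-dagger)' X'X, so replacing X'X
with any kernel matrix K(X, X) kernelizes the factorization without ever
materializing the (possibly infinite-dimensional) basis.  The same holds for
convex NMF, whose multiplicative updates use only the positive/negative split
of X'X, and a non-negative kernel matrix (e.g. RBF) can itself be factorized
by standard NMF.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from numpy.typing import ArrayLike, NDArray

from .factorizations import (
    FactorizationResult,
    FitOptions,
    _EPS,
    _convex_init,
    _kernel_convex_iterate,
    nmf_nnls,
)
from .solvers import QPProblem, solve_nnqp

__all__ = [
    "KernelSpec",
    "KernelFactorization",
    "compute_kernel_matrix",
    "kernel_seminmf",
    "kernel_convex_nmf",
    "kernel_nmf_decompose",
]


@dataclass
class KernelSpec:
    """Kernel function and parameters.

    ``sigma`` is the RBF width in feature-space units (default: median
    pairwise distance of the data it is first applied to); ``degree`` and
    ``coef0`` parameterize the polynomial kernel (u'v + coef0)^degree.
    """

    name: Literal["linear", "rbf", "polynomial", "precomputed"] = "linear"
    sigma: float | None = None
    degree: int = 2
    coef0: float = 1.0

    def __post_init__(self) -> None:
        if self.name == "rbf" and self.sigma is not None and self.sigma <= 0:
            raise ValueError("rbf sigma must be positive")
        if self.name == "polynomial" and (
            self.degree < 1 or int(self.degree) != self.degree
        ):
            raise ValueError("polynomial degree must be an integer >= 1")


@dataclass
class KernelFactorization:
    """Kernel semi-NMF state: coefficients plus everything needed to project.

    ``pseudo`` is Y-dagger = Y'(YY')^-1; with it and the training Gram matrix
    any new sample can be represented through kernel evaluations only.
    """

    Y: NDArray[np.float64]
    gram_train: NDArray[np.float64]
    pseudo: NDArray[np.float64]
    spec: KernelSpec
    objective_trace: NDArray[np.float64]
    iterations: int
    converged: bool

    @property
    def k(self) -> int:
        return self.Y.shape[0]

    @property
    def objective(self) -> float:
        return float(self.objective_trace[-1])


def _median_sigma(A: NDArray[np.float64], B: NDArray[np.float64]) -> float:
    d2 = _sqdist(A, B)
    med = float(np.sqrt(np.median(d2[d2 > 0]))) if (d2 > 0).any() else 1.0
    return med if med > 0 else 1.0


def _sqdist(A: NDArray[np.float64], B: NDArray[np.float64]) -> NDArray[np.float64]:
    aa = (A**2).sum(axis=0)[:, None]
    bb = (B**2).sum(axis=0)[None, :]
    return np.maximum(aa + bb - 2 * (A.T @ B), 0.0)


def compute_kernel_matrix(
    A: ArrayLike, B: ArrayLike, spec: KernelSpec
) -> NDArray[np.float64]:
    """Pairwise kernel matrix K(a_i, b_j) between the columns of A and B."""
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if A.shape[0] != B.shape[0]:
        raise ValueError(
            f"feature dimensions differ: A has {A.shape[0]}, B has {B.shape[0]}"
        )
    if spec.name == "linear":
        return A.T @ B
    if spec.name == "rbf":
        sigma = spec.sigma if spec.sigma is not None else _median_sigma(A, B)
        return np.exp(-_sqdist(A, B) / (2 * sigma**2))
    if spec.name == "polynomial":
        return (A.T @ B + spec.coef0) ** spec.degree
    raise ValueError(f"cannot compute a '{spec.name}' kernel from data")


def _check_gram(K: NDArray[np.float64], repair: bool = True) -> NDArray[np.float64]:
    K = np.asarray(K, dtype=float)
    scale = max(1.0, float(np.abs(K).max(initial=0.0)))
    if np.abs(K - K.T).max(initial=0.0) > 1e-8 * scale:
        raise ValueError("kernel matrix must be symmetric (within 1e-8)")
    K = 0.5 * (K + K.T)
    eigs, vecs = np.linalg.eigh(K)
    lam_max = max(eigs[-1], 0.0)
    if eigs[0] < -1e-8 * max(lam_max, 1.0):
        raise ValueError(
            f"kernel matrix is not PSD (min eigenvalue {eigs[0]:.3e}); "
            "add diagonal jitter or fix the kernel"
        )
    if repair and eigs[0] < 0:
        eigs = np.maximum(eigs, 0.0)
        K = (vecs * eigs) @ vecs.T
    return K


def _pseudo_from_Y(Y: NDArray[np.float64]) -> NDArray[np.float64]:
    YYt = Y @ Y.T
    ridge = 1e-10 * max(np.trace(YYt), 1e-30)
    return Y.T @ np.linalg.inv(YYt + ridge * np.eye(Y.shape[0]))


def kernel_seminmf(
    K: ArrayLike,
    k: int,
    algo: Literal["mult", "nnls"] = "nnls",
    lambda_sparse: float = 0.0,
    opts: FitOptions | None = None,
) -> KernelFactorization:
    """Kernel semi-NMF: factor samples in feature space given only K(X, X).

    Per iteration the implicit basis A = phi(X) Y-dagger yields
    H = A'A = (Y-dagger)' K Y-dagger and A'phi(X) = (Y-dagger)' K; the Y
    update is exact NNQP (``algo="nnls"``, with an optional l1 weight
    ``lambda_sparse``) or the square-rooted multiplicative semi-NMF rule.
    """
    if lambda_sparse < 0:
        raise ValueError("lambda_sparse must be >= 0")
    opts = opts or FitOptions()
    K = _check_gram(K)
    n = K.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"need 1 <= k <= n = {n}, got k={k}")

    def objective(Y):
        P = _pseudo_from_Y(Y)
        AtA = P.T @ K @ P
        AtX = P.T @ K
        fit = 0.5 * float(np.trace(K) - 2 * np.sum(AtX * Y) + np.sum((AtA @ Y) * Y))
        return fit + lambda_sparse * float(np.abs(Y).sum())

    if opts.init == "provided":
        Y = np.array(opts.Y0, dtype=float)
    else:
        Y = np.random.default_rng(opts.seed).random((k, n))

    trace = [objective(Y)]
    converged = False
    for it in range(1, opts.max_iter + 1):
        P = _pseudo_from_Y(Y)
        AtA = P.T @ K @ P
        AtX = P.T @ K
        if algo == "nnls":
            Y = solve_nnqp(
                QPProblem(AtA, lambda_sparse - AtX), check_psd=False
            ).Z
        else:
            AtX_p, AtX_n = np.maximum(AtX, 0), np.maximum(-AtX, 0)
            AtA_p, AtA_n = np.maximum(AtA, 0), np.maximum(-AtA, 0)
            Y = Y * np.sqrt(
                (AtX_p + AtA_n @ Y) / np.maximum(AtX_n + AtA_p @ Y, _EPS)
            )
        f = objective(Y)
        trace.append(f)
        if abs(trace[-2] - f) <= opts.tol * max(abs(trace[-2]), 1e-12):
            converged = True
            break
    return KernelFactorization(
        Y=Y,
        gram_train=K,
        pseudo=_pseudo_from_Y(Y),
        spec=KernelSpec("precomputed"),
        objective_trace=np.asarray(trace),
        iterations=it,
        converged=converged,
    )


def kernel_convex_nmf(
    K: ArrayLike, k: int, opts: FitOptions | None = None
) -> tuple[NDArray[np.float64], NDArray[np.float64]]:
    """Kernel convex NMF: implicit basis phi(X) W with W, Y >= 0.

    Runs the positive/negative-split multiplicative updates on K alone;
    returns (W, Y) with W columns summing to one.
    """
    opts = opts or FitOptions()
    K = _check_gram(K)
    n = K.shape[0]
    if k > n:
        raise ValueError(f"need k <= n = {n}, got k={k}")
    W0, G0 = _convex_init(None, K, k, opts.seed, opts)
    W, G, _, _, _ = _kernel_convex_iterate(K, W0, G0, opts)
    return W, G.T


def kernel_nmf_decompose(
    K: ArrayLike, k: int, opts: FitOptions | None = None
) -> FactorizationResult:
    """Factorize a non-negative kernel matrix itself: K = A Y, A, Y >= 0."""
    K = np.asarray(K, dtype=float)
    scale = max(1.0, float(np.abs(K).max(initial=0.0)))
    if np.abs(K - K.T).max(initial=0.0) > 1e-8 * scale:
        raise ValueError("kernel matrix must be symmetric")
    if K.min() < 0:
        raise ValueError(
            "kernel matrix has negative entries; use kernel_seminmf instead"
        )
    return nmf_nnls(K, k, opts or FitOptions())
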