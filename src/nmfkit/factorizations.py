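"""Linear NMF variants as alternating block-coordinate optimizers.

All variants factor an m-features x n-samples matrix ``X`` as ``X = A Y + E``
with inner dimension ``k``: ``A`` (m x k) holds the basis vectors
("metasamples" for expression data) and ``Y`` (k x n) the per-sample mixing
coefficients.  The variants differ in which factors are sign-constrained and
which penalties are added:

================  =========================  =================================
variant           constraint                 objective added to (1/2)||X-AY||^2
================  =========================  =================================
standard NMF      A, Y >= 0                  --
semi-NMF          Y >= 0 only                --
sparse NMF        A, Y >= 0, ||a_i||_2 = 1   lambda * sum_i ||y_i||_1
VSMF              switchable per factor      elastic-net on both factors
convex NMF        A = X W, W, Y >= 0         --  (basis = convex data combos)
ortho NMF         A, S, Y >= 0               --  (A'A ~ I, YY' ~ I, X = ASY)
weighted NMF      A, Y >= 0                  residual masked at missing cells
================  =========================  =================================

Two optimization families are provided: multiplicative update rules
(monotone, approach zeros asymptotically) and exact alternating
NNLS/NNQP/l1-QP steps via :mod:`nmfkit.solvers` (stationary-point
convergence, exact zeros).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any, Callable, Literal

import numpy as np
from numpy.typing import ArrayLike, NDArray

from .solvers import solve_l1qp, solve_nnls_gram, solve_nnqp, QPProblem

__all__ = [
    "DataMatrix",
    "FactorizationResult",
    "VSMFConfig",
    "FitOptions",
    "nmf_multiplicative",
    "nmf_nnls",
    "seminmf",
    "sparse_nmf",
    "vsmf",
    "convex_nmf",
    "orth_nmf",
    "weighted_nmf",
]

_EPS = 1e-9  # multiplicative-rule denominator guard


# ---------------------------------------------------------------------------
# containers


@dataclass
class DataMatrix:
    """A feature-by-sample matrix with missingness mask and sign mode.

    ``X`` keeps NaN at missing cells; ``mask`` is 1 where observed.
    ``sign_mode`` is ``"non-negative"`` when all observed entries are >= 0,
    else ``"mixed"``.
    """

    X: NDArray[np.float64]
    mask: NDArray[np.float64]
    sign_mode: Literal["non-negative", "mixed"]

    @classmethod
    def from_array(cls, X: ArrayLike) -> "DataMatrix":
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be a 2-D feature-by-sample matrix")
        mask = (~np.isnan(X)).astype(float)
        observed = X[mask.astype(bool)]
        sign = "non-negative" if observed.size == 0 or observed.min() >= 0 else "mixed"
        return cls(X=X, mask=mask, sign_mode=sign)

    @property
    def shape(self) -> tuple[int, int]:
        return self.X.shape

    @property
    def has_missing(self) -> bool:
        return bool((self.mask == 0).any())

    def filled(self, value: float = 0.0) -> NDArray[np.float64]:
        """X with missing cells replaced by ``value``."""
        return np.where(self.mask.astype(bool), self.X, value)


def as_data_matrix(data: "DataMatrix | ArrayLike") -> DataMatrix:
    return data if isinstance(data, DataMatrix) else DataMatrix.from_array(data)


@dataclass
class FactorizationResult:
    """Output of any factorization: factors, objective trace, convergence."""

    A: NDArray[np.float64]
    Y: NDArray[np.float64]
    k: int
    objective_trace: NDArray[np.float64]
    iterations: int
    converged: bool
    extra: dict[str, Any] = field(default_factory=dict)

    def residual(self, X: ArrayLike) -> NDArray[np.float64]:
        """E = X - A Y (convex NMF stores A = X W already)."""
        return np.asarray(X, dtype=float) - self.A @ self.Y

    @property
    def objective(self) -> float:
        return float(self.objective_trace[-1])


@dataclass
class VSMFConfig:
    """Penalty weights and sign switches of the versatile sparse factorization.

    ``alpha1``/``alpha2`` are the l1/l2 weights on basis columns,
    ``lambda1``/``lambda2`` the l1/l2 weights on coefficient columns;
    ``t1``/``t2`` turn non-negativity of A/Y on (True) or off.  ``eta`` and
    ``lambda_sparse`` parameterize the classic sparse-NMF objective
    (eta/2 ||A||_F^2 + lambda/2 sum_i ||y_i||_1^2); ``squared_l1`` selects
    the squared-l1 coefficient penalty (the model as published) versus a
    plain l1 sum.
    """

    alpha1: float = 0.0
    alpha2: float = 0.0
    lambda1: float = 0.0
    lambda2: float = 0.0
    t1: bool = True
    t2: bool = True
    eta: float = 0.0
    lambda_sparse: float = 0.0
    squared_l1: bool = True

    def __post_init__(self) -> None:
        for name in ("alpha1", "alpha2", "lambda1", "lambda2", "eta", "lambda_sparse"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v}")


@dataclass
class FitOptions:
    """Iteration control shared by all variants."""

    max_iter: int = 500
    tol: float = 1e-6
    seed: int = 0
    init: Literal["random", "provided", "kmeans"] = "random"
    A0: NDArray[np.float64] | None = None
    Y0: NDArray[np.float64] | None = None
    n_restarts: int = 1

    def __post_init__(self) -> None:
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.tol <= 0:
            raise ValueError("tol must be positive")


# ---------------------------------------------------------------------------
# shared machinery


def _init_factors(
    X: NDArray[np.float64], k: int, opts: FitOptions, seed: int
) -> tuple[NDArray[np.float64], NDArray[np.float64]]:
    m, n = X.shape
    if opts.init == "provided":
        if opts.Y0 is None:
            raise ValueError("init='provided' requires Y0 (and usually A0)")
        A0 = np.array(opts.A0, dtype=float) if opts.A0 is not None else None
        Y0 = np.array(opts.Y0, dtype=float)
        if A0 is None:
            A0 = np.zeros((m, k))
        return A0, Y0
    rng = np.random.default_rng(seed)
    scale = np.sqrt(np.nanmean(np.abs(X)) / k + _EPS)
    return rng.random((m, k)) * scale, rng.random((k, n)) * scale


def _check_k(k: int, m: int, n: int, *, strict: bool = False) -> None:
    upper = min(m, n)
    if k < 1 or (strict and k >= upper) or k > upper:
        raise ValueError(f"k must satisfy 1 <= k <= min(m, n) = {upper}, got {k}")


def _require_nonneg(data: DataMatrix, variant: str) -> None:
    if data.sign_mode != "non-negative":
        raise ValueError(
            f"{variant} requires non-negative data; "
            "use seminmf/vsmf for mixed-sign matrices"
        )


def _reinit_dead_columns(
    A: NDArray[np.float64],
    X: NDArray[np.float64],
    Y: NDArray[np.float64],
) -> NDArray[np.float64]:
    """Replace all-zero basis columns with the residual's largest-norm column."""
    dead = np.flatnonzero(np.linalg.norm(A, axis=0) < 1e-12)
    if dead.size:
        R = X - A @ Y
        j = int(np.argmax(np.linalg.norm(R, axis=0)))
        for q in dead:
            A[:, q] = np.abs(R[:, j]) + _EPS
    return A


def _run_alternating(
    objective: Callable[[NDArray, NDArray], float],
    update: Callable[[NDArray, NDArray], tuple[NDArray, NDArray]],
    A: NDArray[np.float64],
    Y: NDArray[np.float64],
    opts: FitOptions,
) -> tuple[NDArray, NDArray, NDArray, int, bool]:
    trace = [objective(A, Y)]
    converged = False
    for it in range(1, opts.max_iter + 1):
        A, Y = update(A, Y)
        f = objective(A, Y)
        trace.append(f)
        if abs(trace[-2] - f) <= opts.tol * max(abs(trace[-2]), 1e-12):
            converged = True
            break
    return A, Y, np.asarray(trace), it, converged


def _with_restarts(fit_once: Callable[[int], FactorizationResult], opts: FitOptions):
    best: FactorizationResult | None = None
    for r in range(opts.n_restarts):
        res = fit_once(opts.seed + r)
        if best is None or res.objective < best.objective:
            best = res
    return best


def _frob_obj(X: NDArray[np.float64]) -> Callable[[NDArray, NDArray], float]:
    return lambda A, Y: 0.5 * float(np.sum((X - A @ Y) ** 2))


# ---------------------------------------------------------------------------
# standard NMF


def nmf_multiplicative(
    data: DataMatrix | ArrayLike, k: int, opts: FitOptions | None = None
) -> FactorizationResult:
    """Standard NMF by the classic multiplicative update rules.

    A <- A * (X Y') / (A Y Y'), Y <- Y * (A'X) / (A'A Y); the objective
    (1/2)||X - AY||_F^2 is non-increasing under these rules.
    """
    data = as_data_matrix(data)
    _require_nonneg(data, "nmf_multiplicative")
    opts = opts or FitOptions()
    X = data.X
    _check_k(k, *X.shape)

    def update(A, Y):
        A = A * (X @ Y.T) / np.maximum(A @ (Y @ Y.T), _EPS)
        Y = Y * (A.T @ X) / np.maximum((A.T @ A) @ Y, _EPS)
        return A, Y

    def fit_once(seed):
        A, Y = _init_factors(X, k, opts, seed)
        A, Y, trace, its, conv = _run_alternating(_frob_obj(X), update, A, Y, opts)
        return FactorizationResult(A, Y, k, trace, its, conv)

    return _with_restarts(fit_once, opts)


def nmf_nnls(
    data: DataMatrix | ArrayLike, k: int, opts: FitOptions | None = None
) -> FactorizationResult:
    """Standard NMF by alternating exact NNLS (active set).

    Each half step solves its non-negative least-squares subproblem to
    optimality, so the objective never increases and the iteration converges
    to a stationary point; zeros in the factors are exact.
    """
    data = as_data_matrix(data)
    _require_nonneg(data, "nmf_nnls")
    opts = opts or FitOptions()
    X = data.X
    _check_k(k, *X.shape)

    def update(A, Y):
        # Y-step first, matching the sparse variant's step order so that the
        # lambda = 0 sparse model follows the same trajectory up to rescaling
        Y = solve_nnls_gram(A.T @ A, A.T @ X).Z
        A = solve_nnls_gram(Y @ Y.T, Y @ X.T).Z.T
        A = _reinit_dead_columns(A, X, Y)
        return A, Y

    def fit_once(seed):
        A, Y = _init_factors(X, k, opts, seed)
        A, Y, trace, its, conv = _run_alternating(_frob_obj(X), update, A, Y, opts)
        return FactorizationResult(A, Y, k, trace, its, conv)

    return _with_restarts(fit_once, opts)


# ---------------------------------------------------------------------------
# semi-NMF


def _pseudo_inverse_rows(Y: NDArray[np.float64]) -> NDArray[np.float64]:
    """Y-dagger = Y' (Y Y')^-1 with a small ridge when Y Y' is near singular."""
    YYt = Y @ Y.T
    ridge = 1e-10 * max(np.trace(YYt), 1e-30)
    return Y.T @ np.linalg.inv(YYt + ridge * np.eye(Y.shape[0]))


def seminmf(
    data: DataMatrix | ArrayLike,
    k: int,
    algo: Literal["mult", "nnls"] = "nnls",
    opts: FitOptions | None = None,
) -> FactorizationResult:
    """Semi-NMF: X may be mixed sign, A unconstrained, Y >= 0.

    The A update is the exact least-squares solution A = X Y-dagger; the Y
    update is either exact NNLS or the square-rooted multiplicative rule
    using positive/negative part splitting.
    """
    data = as_data_matrix(data)
    opts = opts or FitOptions()
    X = data.X
    m, n = X.shape
    if k >= n:
        raise ValueError(f"semi-NMF needs k < n (Y-dagger undefined); got k={k}, n={n}")
    _check_k(k, m, n)

    def update(A, Y):
        A = X @ _pseudo_inverse_rows(Y)
        if algo == "nnls":
            Y = solve_nnls_gram(A.T @ A, A.T @ X).Z
        else:
            AtX = A.T @ X
            AtA = A.T @ A
            AtX_p, AtX_n = np.maximum(AtX, 0), np.maximum(-AtX, 0)
            AtA_p, AtA_n = np.maximum(AtA, 0), np.maximum(-AtA, 0)
            Y = Y * np.sqrt((AtX_p + AtA_n @ Y) / np.maximum(AtX_n + AtA_p @ Y, _EPS))
        return A, Y

    def fit_once(seed):
        if opts.init == "kmeans":
            # cluster-indicator start (the usual semi-NMF recipe): semi-NMF
            # factors are only identifiable up to a non-negative mixing of Y,
            # and the indicator init steers the optimizer to the sparse
            # cluster-structured optimum
            from scipy.cluster.vq import kmeans2

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                _, lab = kmeans2(X.T, k, seed=seed, minit="++")
            Y = np.zeros((k, n))
            Y[lab, np.arange(n)] = 1.0
        else:
            _, Y = _init_factors(X, k, opts, seed)
        A = X @ _pseudo_inverse_rows(Y)  # A is determined by Y from the start
        A, Y, trace, its, conv = _run_alternating(_frob_obj(X), update, A, Y, opts)
        return FactorizationResult(A, Y, k, trace, its, conv)

    return _with_restarts(fit_once, opts)


# ---------------------------------------------------------------------------
# sparse NMF


def sparse_nmf(
    data: DataMatrix | ArrayLike,
    k: int,
    cfg: VSMFConfig | None = None,
    variant: Literal["kim_park", "unit_norm"] = "unit_norm",
    semi: bool = False,
    opts: FitOptions | None = None,
) -> FactorizationResult:
    """Sparse NMF with an l1 penalty on the coefficient columns.

    ``unit_norm`` (the recommended model): minimize
    (1/2)||X - AY||_F^2 + lambda * sum_i ||y_i||_1 with A, Y >= 0 and unit-l2
    basis columns; three alternating steps per iteration (Y by NNQP with
    H = A'A and g_i = lambda - A'x_i; A by NNLS, or unconstrained least
    squares when ``semi``; then column normalization of A).

    ``kim_park`` (the classic model): minimize
    (1/2)||X - AY||_F^2 + eta/2 ||A||_F^2 + lambda/2 sum_i ||y_i||_1^2,
    all non-negative; the squared l1 term adds lambda * 11' to the Y-step
    Hessian (set ``cfg.squared_l1 = False`` for a plain l1 sum).
    """
    data = as_data_matrix(data)
    cfg = cfg or VSMFConfig()
    opts = opts or FitOptions()
    lam = cfg.lambda_sparse
    X = data.X
    m, n = X.shape
    _check_k(k, m, n)
    if variant == "kim_park":
        if semi:
            raise ValueError("kim_park variant has no semi (mixed-sign) form")
        _require_nonneg(data, "sparse_nmf(kim_park)")
    elif not semi:
        _require_nonneg(data, "sparse_nmf")

    ones = np.ones((k, k))

    if variant == "unit_norm":

        def objective(A, Y):
            return 0.5 * float(np.sum((X - A @ Y) ** 2)) + lam * float(
                np.abs(Y).sum()
            )

        def update(A, Y):
            Y = solve_nnqp(
                QPProblem(A.T @ A, lam - A.T @ X), check_psd=False
            ).Z
            if semi:
                A = X @ _pseudo_inverse_rows(Y)
            else:
                A = solve_nnls_gram(Y @ Y.T, Y @ X.T).Z.T
                A = _reinit_dead_columns(A, X, Y)
            A = A / np.maximum(np.linalg.norm(A, axis=0), 1e-12)
            return A, Y

    else:  # kim_park

        def objective(A, Y):
            l1 = np.abs(Y).sum(axis=0)
            pen = 0.5 * lam * float((l1**2).sum()) if cfg.squared_l1 else lam * float(
                l1.sum()
            )
            return (
                0.5 * float(np.sum((X - A @ Y) ** 2))
                + 0.5 * cfg.eta * float(np.sum(A**2))
                + pen
            )

        def update(A, Y):
            if cfg.squared_l1:
                H = A.T @ A + lam * ones
                G = -(A.T @ X)
            else:
                H = A.T @ A
                G = lam - A.T @ X
            Y = solve_nnqp(QPProblem(H, G), check_psd=False).Z
            A = solve_nnqp(
                QPProblem(Y @ Y.T + cfg.eta * np.eye(k), -(Y @ X.T)), check_psd=False
            ).Z.T
            A = _reinit_dead_columns(A, X, Y)
            return A, Y

    def fit_once(seed):
        A, Y = _init_factors(X, k, opts, seed)
        if variant == "unit_norm":
            A = A / np.maximum(np.linalg.norm(A, axis=0), 1e-12)
        A, Y, trace, its, conv = _run_alternating(objective, update, A, Y, opts)
        return FactorizationResult(A, Y, k, trace, its, conv)

    return _with_restarts(fit_once, opts)


# ---------------------------------------------------------------------------
# versatile sparse matrix factorization


def _vsmf_objective(
    X: NDArray[np.float64], cfg: VSMFConfig
) -> Callable[[NDArray, NDArray], float]:
    def f(A, Y):
        return (
            0.5 * float(np.sum((X - A @ Y) ** 2))
            + 0.5 * cfg.alpha2 * float(np.sum(A**2))
            + cfg.alpha1 * float(np.abs(A).sum())
            + 0.5 * cfg.lambda2 * float(np.sum(Y**2))
            + cfg.lambda1 * float(np.abs(Y).sum())
        )

    return f


def vsmf(
    data: DataMatrix | ArrayLike,
    k: int,
    cfg: VSMFConfig | None = None,
    algo: Literal["mult", "active_set"] = "active_set",
    opts: FitOptions | None = None,
) -> FactorizationResult:
    """Versatile sparse matrix factorization: elastic-net penalties on both
    factors with switchable non-negativity.

    minimize (1/2)||X - AY||_F^2
             + sum_i (alpha2/2 ||a_i||_2^2 + alpha1 ||a_i||_1)
             + sum_i (lambda2/2 ||y_i||_2^2 + lambda1 ||y_i||_1)
    with A >= 0 iff t1, Y >= 0 iff t2.

    ``algo="mult"`` (requires t1 = t2 = 1 and non-negative X) applies
    A <- A * (X Y') / (A Y Y' + alpha2 A + alpha1) and
    Y <- Y * (A'X) / (A'A Y + lambda2 Y + lambda1).
    ``algo="active_set"`` updates non-negative blocks by NNQP and sign-free
    blocks by l1-regularized QP, so any (t1, t2) combination is supported.
    """
    data = as_data_matrix(data)
    cfg = cfg or VSMFConfig()
    opts = opts or FitOptions()
    X = data.X
    m, n = X.shape
    _check_k(k, m, n)
    if algo == "mult":
        if not (cfg.t1 and cfg.t2):
            raise ValueError(
                "multiplicative VSMF requires t1 = t2 = 1; "
                "use algo='active_set' for sign-free factors"
            )
        _require_nonneg(data, "vsmf(mult)")
    elif cfg.t1 and cfg.t2:
        _require_nonneg(data, "vsmf with t1 = t2 = 1")

    objective = _vsmf_objective(X, cfg)

    if algo == "mult":

        def update(A, Y):
            A = A * (X @ Y.T) / np.maximum(A @ (Y @ Y.T) + cfg.alpha2 * A + cfg.alpha1, _EPS)
            Y = Y * (A.T @ X) / np.maximum((A.T @ A) @ Y + cfg.lambda2 * Y + cfg.lambda1, _EPS)
            return A, Y

    else:

        def update(A, Y):
            H_A = Y @ Y.T + cfg.alpha2 * np.eye(k)
            if cfg.t1:
                A = solve_nnqp(
                    QPProblem(H_A, cfg.alpha1 - Y @ X.T), check_psd=False
                ).Z.T
                A = _reinit_dead_columns(A, X, Y)
            else:
                A = solve_l1qp(H_A, -(Y @ X.T), cfg.alpha1).T
            H_Y = A.T @ A + cfg.lambda2 * np.eye(k)
            if cfg.t2:
                Y = solve_nnqp(
                    QPProblem(H_Y, cfg.lambda1 - A.T @ X), check_psd=False
                ).Z
            else:
                Y = solve_l1qp(H_Y, -(A.T @ X), cfg.lambda1)
            return A, Y

    def fit_once(seed):
        A, Y = _init_factors(X, k, opts, seed)
        A, Y, trace, its, conv = _run_alternating(objective, update, A, Y, opts)
        return FactorizationResult(A, Y, k, trace, its, conv)

    return _with_restarts(fit_once, opts)


# ---------------------------------------------------------------------------
# convex NMF


def convex_nmf(
    data: DataMatrix | ArrayLike, k: int, opts: FitOptions | None = None
) -> FactorizationResult:
    """Convex NMF: X = X W Y + E with W, Y >= 0 and W columns summing to one.

    Basis vectors A = X W are convex combinations of data points, hence close
    to cluster centroids.  The square-rooted multiplicative updates operate on
    the positive/negative split of X'X only, so the kernel version shares the
    exact same iteration.  Initialization clusters the samples (seeded k-means)
    and smooths the indicator, following the original recipe.
    """
    data = as_data_matrix(data)
    opts = opts or FitOptions()
    X = data.X
    m, n = X.shape
    if k > n:
        raise ValueError(f"convex NMF needs k <= n, got k={k}, n={n}")
    K = X.T @ X

    def fit_once(seed):
        W0, G0 = _convex_init(X.T, K, k, seed, opts)
        W, G, trace, its, conv = _kernel_convex_iterate(K, W0, G0, opts)
        A = X @ W
        return FactorizationResult(
            A, G.T, k, trace, its, conv, extra={"W": W}
        )

    return _with_restarts(fit_once, opts)


def _convex_init(
    points: NDArray[np.float64] | None,
    K: NDArray[np.float64],
    k: int,
    seed: int,
    opts: FitOptions,
) -> tuple[NDArray[np.float64], NDArray[np.float64]]:
    """Smoothed cluster-indicator init (W n x k, G n x k = Y')."""
    n = K.shape[0]
    if opts.init == "provided":
        if opts.A0 is None or opts.Y0 is None:
            raise ValueError("provided init for convex NMF needs A0 = W and Y0")
        return np.array(opts.A0, dtype=float), np.array(opts.Y0, dtype=float).T
    from scipy.cluster.vq import kmeans2

    rng = np.random.default_rng(seed)
    if points is None:
        # kernel-only caller: cluster on rows of K (sample similarity profiles)
        points = K
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # empty-cluster warnings on tiny data
        _, labels = kmeans2(points, k, seed=rng, minit="++")
    G = np.zeros((n, k))
    G[np.arange(n), labels] = 1.0
    counts = np.maximum(G.sum(axis=0), 1.0)
    G = G + 0.2
    W = (G / counts) .copy()
    W = W / W.sum(axis=0)
    return W, G


def _kernel_convex_iterate(
    K: NDArray[np.float64],
    W: NDArray[np.float64],
    G: NDArray[np.float64],
    opts: FitOptions,
) -> tuple[NDArray, NDArray, NDArray, int, bool]:
    """Shared convex-NMF iteration on a Gram matrix K = X'X (or kernel)."""
    Kp, Kn = np.maximum(K, 0), np.maximum(-K, 0)

    def objective(W, G):
        # ||X - X W G'||_F^2 expressed through K only
        KW = K @ W
        return 0.5 * float(
            np.trace(K)
            - 2 * np.sum(KW * G)
            + np.sum((G @ (W.T @ KW)) * G)
        )

    trace = [objective(W, G)]
    converged = False
    for it in range(1, opts.max_iter + 1):
        GtG = G.T @ G
        G = G * np.sqrt(
            (Kp @ W + G @ (W.T @ Kn @ W)) / np.maximum(Kn @ W + G @ (W.T @ Kp @ W), _EPS)
        )
        W = W * np.sqrt(
            (Kp @ G + Kn @ W @ GtG) / np.maximum(Kn @ G + Kp @ W @ GtG, _EPS)
        )
        # normalize W columns to sum one, compensating G to keep X W G' fixed
        s = np.maximum(W.sum(axis=0), 1e-12)
        W = W / s
        G = G * s
        f = objective(W, G)
        trace.append(f)
        if abs(trace[-2] - f) <= opts.tol * max(abs(trace[-2]), 1e-12):
            converged = True
            break
    return W, G, np.asarray(trace), it, converged


# ---------------------------------------------------------------------------
# orthogonal NMF


def orth_nmf(
    data: DataMatrix | ArrayLike, k: int, opts: FitOptions | None = None
) -> FactorizationResult:
    """Orthogonal tri-factor NMF: X = A S Y + E, all factors >= 0.

    Square-rooted multiplicative updates push A'A and YY' toward identity
    (orthogonality is soft); S absorbs the magnitude of X.  The achieved
    deviations ||A'A - I||_F and ||YY' - I||_F are reported in ``extra``.
    """
    data = as_data_matrix(data)
    _require_nonneg(data, "orth_nmf")
    opts = opts or FitOptions()
    X = data.X
    m, n = X.shape
    _check_k(k, m, n)

    def objective(A, SY):
        S, Y = SY
        return 0.5 * float(np.sum((X - A @ S @ Y) ** 2))

    def fit_once(seed):
        rng = np.random.default_rng(seed)
        if opts.init == "provided":
            A = np.array(opts.A0, dtype=float)
            Y = np.array(opts.Y0, dtype=float)
        else:
            # near-orthonormal start keeps the square-root rules monotone
            A = rng.random((m, k))
            A /= np.linalg.norm(A, axis=0)
            Y = rng.random((k, n))
            Y /= np.linalg.norm(Y, axis=1)[:, None]
        S = A.T @ X @ Y.T  # scale absorbed by the middle factor from the start

        trace = [objective(A, (S, Y))]
        converged = False
        for it in range(1, opts.max_iter + 1):
            XYS = X @ Y.T @ S.T
            A = A * np.sqrt(XYS / np.maximum(A @ (A.T @ XYS), _EPS))
            SAX = S.T @ (A.T @ X)
            Y = Y * np.sqrt(SAX / np.maximum((SAX @ Y.T) @ Y, _EPS))
            AXY = A.T @ X @ Y.T
            S = S * np.sqrt(AXY / np.maximum((A.T @ A) @ S @ (Y @ Y.T), _EPS))
            f = objective(A, (S, Y))
            trace.append(f)
            if abs(trace[-2] - f) <= opts.tol * max(abs(trace[-2]), 1e-12):
                converged = True
                break
        extra = {
            "S": S,
            "orth_dev_A": float(np.linalg.norm(A.T @ A - np.eye(k))),
            "orth_dev_Y": float(np.linalg.norm(Y @ Y.T - np.eye(k))),
        }
        return FactorizationResult(
            A, S @ Y, k, np.asarray(trace), it, converged, extra=extra
        )

    return _with_restarts(fit_once, opts)


# ---------------------------------------------------------------------------
# weighted NMF (missing values)


def weighted_nmf(
    data: DataMatrix | ArrayLike, k: int, opts: FitOptions | None = None
) -> FactorizationResult:
    """Weighted NMF: missing cells get zero weight and never influence the fit.

    minimize (1/2)||M * (X - AY)||_F^2 with M the observed-cell indicator;
    multiplicative rules A <- A * ((M*X) Y') / ((M*(AY)) Y') and
    Y <- Y * (A'(M*X)) / (A'(M*(AY))).  ``extra["X_imputed"]`` holds the
    completed matrix A Y.
    """
    data = as_data_matrix(data)
    _require_nonneg(data, "weighted_nmf")
    opts = opts or FitOptions()
    M = data.mask
    X = data.filled(0.0)
    m, n = X.shape
    _check_k(k, m, n)
    if (M.sum(axis=0) == 0).any() or (M.sum(axis=1) == 0).any():
        warnings.warn(
            "a fully-missing row or column leaves its factor unconstrained"
        )
    MX = M * X

    def objective(A, Y):
        return 0.5 * float(np.sum((M * (X - A @ Y)) ** 2))

    def update(A, Y):
        A = A * (MX @ Y.T) / np.maximum((M * (A @ Y)) @ Y.T, _EPS)
        Y = Y * (A.T @ MX) / np.maximum(A.T @ (M * (A @ Y)), _EPS)
        return A, Y

    def fit_once(seed):
        A, Y = _init_factors(X, k, opts, seed)
        A, Y, trace, its, conv = _run_alternating(objective, update, A, Y, opts)
        return FactorizationResult(
            A, Y, k, trace, its, conv, extra={"X_imputed": A @ Y}
        )

    return _with_restarts(fit_once, opts)
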