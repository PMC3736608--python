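"""Non-negative quadratic programming solvers.

Every factorization and the NNLS classifier in this package reduce their
inner steps to one problem: minimize, independently for each column ``z_i``
of a matrix ``Z``,

    (1/2) z_i' H z_i + g_i' z_i   subject to  z_i >= 0,

with a shared symmetric positive-semidefinite Hessian ``H``.  Non-negative
least squares (min ||B - AZ||_F over Z >= 0) is the special case
H = A'A, g_i = -A'b_i, and an l1-penalized sign-free quadratic program is
handled by the standard positive/negative split z = u - v.

The solver is a Lawson--Hanson style active-set method: exact (it terminates
at a KKT point, producing exact zeros rather than small positive values) and
deterministic.  Columns are solved in sequence with the previous column's
passive set used as a warm start.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from numpy.typing import ArrayLike, NDArray


__all__ = [
    "QPProblem",
    "QPSolution",
    "NNQPNumericalWarning",
    "solve_nnqp",
    "solve_nnls",
    "solve_nnls_gram",
    "solve_l1qp",
]


class NNQPNumericalWarning(UserWarning):
    """Active-set iteration limit reached; the returned column may be inexact."""


@dataclass
class QPProblem:
    """One NNQP instance: Hessian ``H`` (p x p, PSD) and linear terms ``G`` (p x q).

    The optional per-column offsets ``c`` do not affect the argmin and are kept
    only so that objective values can be reported on the caller's scale.
    """

    H: NDArray[np.float64]
    G: NDArray[np.float64]
    c: NDArray[np.float64] | None = None

    def __post_init__(self) -> None:
        self.H = np.asarray(self.H, dtype=float)
        self.G = np.asarray(self.G, dtype=float)
        if self.G.ndim == 1:
            self.G = self.G[:, None]
        if self.H.ndim != 2 or self.H.shape[0] != self.H.shape[1]:
            raise ValueError(f"H must be square, got shape {self.H.shape}")
        scale = max(1.0, float(np.abs(self.H).max(initial=0.0)))
        if np.abs(self.H - self.H.T).max(initial=0.0) > 1e-10 * scale:
            raise ValueError("H must be symmetric (within 1e-10 relative)")
        if self.G.shape[0] != self.H.shape[0]:
            raise ValueError(
                f"G has {self.G.shape[0]} rows but H is {self.H.shape[0]}-dimensional"
            )


@dataclass
class QPSolution:
    """Column-wise NNQP solution with its KKT certificate.

    ``kkt_residual`` is the worst violation, over all columns and coordinates,
    of dual feasibility (gradient >= 0 on the zero set) and complementarity
    (z * gradient = 0).
    """

    Z: NDArray[np.float64]
    kkt_residual: float
    iterations: list[int] = field(default_factory=list)

    @property
    def x(self) -> NDArray[np.float64]:
        """The solution as a flat vector (single-column problems)."""
        return self.Z[:, 0]


def _check_psd(H: NDArray[np.float64]) -> None:
    eigs = np.linalg.eigvalsh(H)
    lam_max = max(eigs[-1], 0.0)
    if eigs[0] < -1e-8 * max(1.0, lam_max):
        raise ValueError(
            f"H is not positive semidefinite: smallest eigenvalue {eigs[0]:.3e}"
        )


def _nnqp_column(
    H: NDArray[np.float64],
    g: NDArray[np.float64],
    tol: float,
    max_outer: int,
    passive_init: NDArray[np.bool_] | None,
) -> tuple[NDArray[np.float64], int, NDArray[np.bool_]]:
    """Lawson--Hanson active set for a single column; returns (z, iters, passive)."""
    p = g.shape[0]
    passive = np.zeros(p, dtype=bool)
    z = np.zeros(p)
    iters = 0

    if passive_init is not None and passive_init.any():
        # warm start: try the previous column's free set; keep it only if the
        # unconstrained solution on that set is strictly feasible
        try:
            s = np.linalg.solve(H[np.ix_(passive_init, passive_init)], -g[passive_init])
        except np.linalg.LinAlgError:
            s = None
        if s is not None and np.all(s > 0):
            passive = passive_init.copy()
            z[passive] = s

    grad = H @ z + g
    while True:
        candidates = ~passive
        if not candidates.any():
            break
        w = -grad[candidates]
        if w.max() <= tol:
            break
        if iters >= max_outer:
            warnings.warn(
                f"active-set iteration limit ({max_outer}) reached; "
                "returning current iterate",
                NNQPNumericalWarning,
                stacklevel=3,
            )
            break
        iters += 1
        j = np.flatnonzero(candidates)[int(np.argmax(w))]
        passive[j] = True
        # inner loop: restore primal feasibility on the passive set
        while True:
            idx = np.flatnonzero(passive)
            s = np.linalg.solve(H[np.ix_(idx, idx)], -g[idx])
            if np.all(s > 0):
                z[:] = 0.0
                z[idx] = s
                break
            zp = z[idx]
            neg = s <= 0
            with np.errstate(divide="ignore", invalid="ignore"):
                ratios = zp[neg] / (zp[neg] - s[neg])
            alpha = float(np.nanmin(ratios)) if ratios.size else 0.0
            z[idx] = zp + alpha * (s - zp)
            drop = idx[z[idx] <= 1e-14]
            z[drop] = 0.0
            passive[drop] = False
            if not passive.any():
                break
        grad = H @ z + g
    if passive.any():
        # one step of iterative refinement tightens the KKT certificate on
        # ill-conditioned Hessians
        idx = np.flatnonzero(passive)
        Hp = H[np.ix_(idx, idx)]
        r = -g[idx] - Hp @ z[idx]
        s = z[idx] + np.linalg.solve(Hp, r)
        if np.all(s > 0):
            z[idx] = s
    return z, iters, passive


def solve_nnqp(
    problem: QPProblem,
    tol: float = 1e-8,
    *,
    check_psd: bool = True,
    warm_start: bool = True,
    max_iter: int | None = None,
) -> QPSolution:
    """Solve min (1/2) z'Hz + g'z s.t. z >= 0, columnwise over the columns of G.

    Parameters
    ----------
    problem
        The Hessian/linear-term bundle.  ``H`` must be symmetric PSD.
    tol
        KKT tolerance: dual feasibility and complementarity are enforced to
        within ``tol``.
    check_psd
        Skip the eigenvalue check when the caller constructed H as a Gram
        matrix (PSD by construction).
    warm_start
        Seed each column's passive set from the previous column.
    max_iter
        Cap on active-set additions per column; default ``max(3p, 30)``.

    Returns
    -------
    QPSolution
        Exact-zero solution columns with KKT certificate.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    H, G = problem.H, problem.G
    p, q = G.shape
    if check_psd:
        _check_psd(H)
    # ridge keeps rank-deficient Hessians solvable without materially moving optima
    ridge = 1e-12 * np.trace(H) / max(p, 1)
    Hr = H + ridge * np.eye(p) if ridge > 0 else H.copy()
    if max_iter is None:
        max_iter = max(3 * p, 30)

    Z = np.zeros((p, q))
    iterations: list[int] = []
    passive: NDArray[np.bool_] | None = None
    for i in range(q):
        z, it, pas = _nnqp_column(
            Hr, G[:, i], tol, max_iter, passive if warm_start else None
        )
        Z[:, i] = z
        iterations.append(it)
        passive = pas

    grad = Hr @ Z + G
    dual_viol = np.where(Z <= 0, np.maximum(0.0, -grad), 0.0)
    comp_viol = np.abs(Z * grad)
    kkt = float(max(dual_viol.max(initial=0.0), comp_viol.max(initial=0.0)))
    return QPSolution(Z=Z, kkt_residual=kkt, iterations=iterations)


def solve_nnls(
    A: ArrayLike,
    B: ArrayLike,
    tol: float = 1e-8,
) -> QPSolution:
    """Non-negative least squares: min (1/2)||B - AZ||_F^2 over Z >= 0.

    Delegates to :func:`solve_nnqp` with H = A'A and g_i = -A'b_i.  Callers
    that only have inner products (kernel methods) should use
    :func:`solve_nnls_gram` directly.
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if B.ndim == 1:
        B = B[:, None]
    if A.shape[0] != B.shape[0]:
        raise ValueError(
            f"A has {A.shape[0]} rows but B has {B.shape[0]}; dimensions must match"
        )
    if A.shape[1] > A.shape[0] or np.linalg.matrix_rank(A) < min(A.shape):
        warnings.warn("A is rank deficient; NNLS solution may not be unique")
    return solve_nnls_gram(A.T @ A, A.T @ B, tol)


def solve_nnls_gram(
    AtA: ArrayLike,
    AtB: ArrayLike,
    tol: float = 1e-8,
) -> QPSolution:
    """NNLS from precomputed Gram matrices: H = A'A (PSD), linear terms -A'B."""
    AtA = np.asarray(AtA, dtype=float)
    AtB = np.asarray(AtB, dtype=float)
    if AtB.ndim == 1:
        AtB = AtB[:, None]
    # symmetrize away roundoff: the Gram construction guarantees PSD
    AtA = 0.5 * (AtA + AtA.T)
    return solve_nnqp(QPProblem(H=AtA, G=-AtB), tol, check_psd=False)


def solve_l1qp(
    H: ArrayLike,
    g: ArrayLike,
    lambda1: float,
    tol: float = 1e-8,
) -> NDArray[np.float64]:
    """l1-regularized QP: min (1/2) z'Hz + g'z + lambda1*||z||_1 over sign-free z.

    Solved by splitting z = u - v with u, v >= 0, giving an NNQP on the doubled
    system [[H, -H], [-H, H]] with linear terms [g + lambda1; -g + lambda1].
    """
    if lambda1 < 0:
        raise ValueError("lambda1 must be non-negative")
    H = np.asarray(H, dtype=float)
    g = np.asarray(g, dtype=float)
    single = g.ndim == 1
    G = g[:, None] if single else g
    p = H.shape[0]
    H2 = np.block([[H, -H], [-H, H]])
    G2 = np.vstack([G + lambda1, -G + lambda1])
    sol = solve_nnqp(QPProblem(H=H2, G=G2), tol, check_psd=False)
    Z = sol.Z[:p] - sol.Z[p:]
    return Z[:, 0] if single else Z
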