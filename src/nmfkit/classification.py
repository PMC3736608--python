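"""NNLS sparse-representation classifier with missing-value-aware kernels.

The classifier needs no training beyond storing the data: the training
samples themselves are the basis, and an unknown sample s is expressed as a
sparse non-negative combination s = X_tr y, y >= 0 (optionally with an l1
weight).  The class is read from y either as the class whose training
samples reconstruct s with the smallest residual (the sparse-representation
convention) or as the class with the largest total coefficient.  Because the
NNQP step touches the data only through inner products, the classifier
kernelizes directly, and missing values are handled without imputation: each
pairwise inner product is computed on the features observed in both samples,
after rescaling both restrictions to unit l2 norm.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from numpy.typing import ArrayLike, NDArray
from sklearn.model_selection import KFold, StratifiedKFold

from .kernels import KernelSpec, compute_kernel_matrix
from .solvers import QPProblem, solve_nnqp

__all__ = [
    "ClassifierModel",
    "CVResult",
    "missing_aware_gram",
    "change_class_labels",
    "nnls_fit",
    "nnls_predict",
    "knn1_predict",
    "cross_validate",
    "missingness_experiment",
    "noise_experiment",
]


def change_class_labels(labels: ArrayLike) -> tuple[NDArray[np.int_], list]:
    """Map arbitrary class labels to 0..C-1; returns (codes, class list)."""
    labels = np.asarray(labels)
    classes = sorted(set(labels.tolist()))
    lookup = {c: i for i, c in enumerate(classes)}
    return np.array([lookup[v] for v in labels.tolist()]), classes


def missing_aware_gram(X1: ArrayLike, X2: ArrayLike) -> NDArray[np.float64]:
    """Pairwise inner products on common observed features, unit-normalized.

    Entry (i, j) is <x_i / ||x_i||, x_j / ||x_j||> where both columns are
    restricted to the features observed in both and the norms are taken on
    that restriction.  No values are imputed.  A pair of columns with no
    common observed feature is an error.
    """
    X1 = np.asarray(X1, dtype=float)
    X2 = np.asarray(X2, dtype=float)
    if X1.shape[0] != X2.shape[0]:
        raise ValueError("feature dimensions differ")
    O1, O2 = ~np.isnan(X1), ~np.isnan(X2)
    Z1, Z2 = np.where(O1, X1, 0.0), np.where(O2, X2, 0.0)
    common = O1.astype(float).T @ O2.astype(float)
    if (common == 0).any():
        i, j = np.argwhere(common == 0)[0]
        raise ValueError(
            f"columns {i} (left) and {j} (right) have disjoint observed "
            "features; no inner product is defined"
        )
    S = Z1.T @ Z2
    N1 = np.sqrt((Z1**2).T @ O2.astype(float))
    N2 = np.sqrt(O1.astype(float).T @ (Z2**2))
    denom = N1 * N2
    out = np.divide(S, denom, out=np.zeros_like(S), where=denom > 0)
    return out


@dataclass
class ClassifierModel:
    """Stored training state of the NNLS classifier."""

    X_tr: NDArray[np.float64]
    labels: NDArray[np.int_]
    classes: list
    spec: KernelSpec
    lambda_sparse: float
    decision_rule: Literal["min_class_residual", "max_class_coefficient"]
    gram: NDArray[np.float64]


@dataclass
class CVResult:
    """Fold-level accuracies of repeated stratified k-fold cross-validation."""

    fold_accuracies: NDArray[np.float64]
    mean_accuracy: float
    std_accuracy: float
    config: dict = field(default_factory=dict)


def nnls_fit(
    X_tr: ArrayLike,
    labels: ArrayLike,
    spec: KernelSpec | None = None,
    lambda_sparse: float = 0.0,
    decision_rule: Literal[
        "min_class_residual", "max_class_coefficient"
    ] = "min_class_residual",
) -> ClassifierModel:
    """Store the training samples as the classifier basis and precompute the
    training Gram matrix (missing-aware for incomplete linear data)."""
    X_tr = np.asarray(X_tr, dtype=float)
    codes, classes = change_class_labels(labels)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    if codes.shape[0] != X_tr.shape[1]:
        raise ValueError("labels length must equal the number of training samples")
    spec = spec or KernelSpec("linear")
    has_nan = bool(np.isnan(X_tr).any())
    if spec.name == "linear":
        gram = missing_aware_gram(X_tr, X_tr)
        if has_nan:
            # pairwise-support inner products need not form a PSD matrix;
            # project onto the PSD cone so the NNQP step stays well posed
            gram = 0.5 * (gram + gram.T)
            eigs, vecs = np.linalg.eigh(gram)
            if eigs[0] < 0:
                gram = (vecs * np.maximum(eigs, 0.0)) @ vecs.T
    else:
        if has_nan:
            raise ValueError(
                "kernel NNLS requires complete data; the missing-aware path "
                "is linear only"
            )
        gram = compute_kernel_matrix(X_tr, X_tr, spec)
    return ClassifierModel(
        X_tr=X_tr,
        labels=codes,
        classes=classes,
        spec=spec,
        lambda_sparse=lambda_sparse,
        decision_rule=decision_rule,
        gram=0.5 * (gram + gram.T),
    )


def nnls_predict(
    model: ClassifierModel, S: ArrayLike
) -> tuple[NDArray, NDArray[np.float64]]:
    """Predict class labels of unknown samples S.

    Each column s gets coefficients y >= 0 minimizing
    (1/2)||s - X_tr y||^2 + lambda ||y||_1, computed from inner products only.
    ``min_class_residual`` picks the class whose samples alone reconstruct s
    best; ``max_class_coefficient`` picks the class with the largest total
    coefficient.  Ties go to the lowest class id.
    """
    S = np.asarray(S, dtype=float)
    if S.ndim == 1:
        S = S[:, None]
    if S.shape[0] != model.X_tr.shape[0]:
        raise ValueError("feature dimension of S does not match training data")
    if model.spec.name == "linear":
        cross = missing_aware_gram(model.X_tr, S)
        self_ip = np.ones(S.shape[1])  # unit normalization
    else:
        cross = compute_kernel_matrix(model.X_tr, S, model.spec)
        self_ip = np.diag(compute_kernel_matrix(S, S, model.spec)).copy()
    H = model.gram
    sol = solve_nnqp(QPProblem(H, model.lambda_sparse - cross), check_psd=False)
    Y = sol.Z

    C = len(model.classes)
    n_unk = S.shape[1]
    pred = np.empty(n_unk, dtype=int)
    for j in range(n_unk):
        y = Y[:, j]
        if model.decision_rule == "max_class_coefficient":
            scores = np.array(
                [y[model.labels == c].sum() for c in range(C)]
            )
            pred[j] = int(np.argmax(scores))  # argmax: lowest id wins ties
        else:
            resid = np.empty(C)
            for c in range(C):
                yc = np.where(model.labels == c, y, 0.0)
                # ||s - X yc||^2 from inner products
                resid[c] = (
                    self_ip[j] - 2 * yc @ cross[:, j] + yc @ H @ yc
                )
            pred[j] = int(np.argmin(resid))
    labels = np.array([model.classes[p] for p in pred])
    return labels, Y


def knn1_predict(
    X_tr: ArrayLike, labels: ArrayLike, S: ArrayLike
) -> NDArray:
    """1-nearest-neighbour baseline (Euclidean), used in robustness comparisons."""
    X_tr = np.asarray(X_tr, dtype=float)
    S = np.asarray(S, dtype=float)
    labels = np.asarray(labels)
    d2 = (
        (S**2).sum(axis=0)[None, :]
        + (X_tr**2).sum(axis=0)[:, None]
        - 2 * X_tr.T @ S
    )
    return labels[np.argmin(d2, axis=0)]


def cross_validate(
    X: ArrayLike,
    labels: ArrayLike,
    folds: int = 4,
    runs: int = 20,
    spec: KernelSpec | None = None,
    lambda_sparse: float = 0.0,
    decision_rule: str = "min_class_residual",
    seed: int = 0,
) -> CVResult:
    """Repeated stratified k-fold cross-validation of the NNLS classifier.

    Each run uses a distinct derived seed; all fold accuracies are returned
    (``runs * folds`` values).  Classes smaller than the fold count degrade
    to plain k-fold with a warning.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    n = X.shape[1]
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if n < folds:
        raise ValueError("need at least as many samples as folds")
    _, counts = np.unique(labels, return_counts=True)
    stratified = counts.min() >= folds
    if not stratified:
        warnings.warn(
            "a class has fewer members than folds; using plain k-fold"
        )
    accs = []
    for run in range(runs):
        run_seed = seed + run
        splitter = (
            StratifiedKFold(folds, shuffle=True, random_state=run_seed)
            if stratified
            else KFold(folds, shuffle=True, random_state=run_seed)
        )
        for tr_idx, te_idx in splitter.split(X.T, labels):
            model = nnls_fit(
                X[:, tr_idx], labels[tr_idx], spec, lambda_sparse, decision_rule
            )
            pred, _ = nnls_predict(model, X[:, te_idx])
            accs.append(float(np.mean(pred == labels[te_idx])))
    accs = np.asarray(accs)
    return CVResult(
        fold_accuracies=accs,
        mean_accuracy=float(accs.mean()),
        std_accuracy=float(accs.std()),
        config={"folds": folds, "runs": runs, "seed": seed},
    )


def apply_missingness(
    X: ArrayLike, rate: float, seed: int
) -> NDArray[np.float64]:
    """Mask exactly round(rate * m * n) entries uniformly at random with NaN."""
    if not 0 <= rate < 1:
        raise ValueError("rate must be in [0, 1)")
    X = np.array(X, dtype=float)
    m, n = X.shape
    n_missing = int(round(rate * m * n))
    idx = np.random.default_rng(seed).choice(m * n, size=n_missing, replace=False)
    X.flat[idx] = np.nan
    return X


def missingness_experiment(
    X: ArrayLike,
    labels: ArrayLike,
    rates: list[float],
    strategies: tuple[str, ...] = ("ignore", "zero_impute"),
    folds: int = 4,
    runs: int = 1,
    n_seeds: int = 20,
    seed: int = 0,
) -> dict[tuple[float, str], tuple[float, float]]:
    """Accuracy of the NNLS classifier under random missingness.

    For each rate, mask entries uniformly at random (``n_seeds`` independent
    masks) and cross-validate with each strategy: ``ignore`` uses the
    missing-aware inner products; ``zero_impute`` replaces NaN with 0 first.
    Returns {(rate, strategy): (mean accuracy, std over masks)}.
    """
    X = np.asarray(X, dtype=float)
    out: dict[tuple[float, str], tuple[float, float]] = {}
    for rate in rates:
        if rate >= 1:
            raise ValueError("rate must be < 1")
        per_strategy: dict[str, list[float]] = {s: [] for s in strategies}
        for s_i in range(n_seeds):
            Xm = apply_missingness(X, rate, seed + 1000 * s_i)
            for strat in strategies:
                Xs = np.nan_to_num(Xm, nan=0.0) if strat == "zero_impute" else Xm
                cv = cross_validate(
                    Xs, labels, folds=folds, runs=runs, seed=seed + s_i
                )
                per_strategy[strat].append(cv.mean_accuracy)
        for strat, vals in per_strategy.items():
            vals = np.asarray(vals)
            out[(rate, strat)] = (float(vals.mean()), float(vals.std()))
    return out


def noise_experiment(
    X: ArrayLike,
    labels: ArrayLike,
    variances: list[float],
    folds: int = 4,
    runs: int = 1,
    n_seeds: int = 20,
    seed: int = 0,
    include_knn: bool = True,
) -> dict[tuple[float, str], tuple[float, float]]:
    """Accuracy under additive Gaussian noise of increasing variance.

    Reports the NNLS classifier and (optionally) a 1-nearest-neighbour
    baseline at each noise level, averaged over ``n_seeds`` noise draws.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    out: dict[tuple[float, str], tuple[float, float]] = {}
    for var in variances:
        nnls_accs, knn_accs = [], []
        for s_i in range(n_seeds):
            rng = np.random.default_rng(seed + 7919 * s_i)
            Xn = X + rng.normal(0, np.sqrt(var), X.shape) if var > 0 else X.copy()
            cv = cross_validate(Xn, labels, folds=folds, runs=runs, seed=seed + s_i)
            nnls_accs.append(cv.mean_accuracy)
            if include_knn:
                splitter = StratifiedKFold(folds, shuffle=True, random_state=seed + s_i)
                fold_acc = []
                for tr, te in splitter.split(Xn.T, labels):
                    pred = knn1_predict(Xn[:, tr], labels[tr], Xn[:, te])
                    fold_acc.append(float(np.mean(pred == labels[te])))
                knn_accs.append(float(np.mean(fold_acc)))
        out[(var, "nnls")] = (
            float(np.mean(nnls_accs)), float(np.std(nnls_accs))
        )
        if include_knn:
            out[(var, "knn1")] = (
                float(np.mean(knn_accs)), float(np.std(knn_accs))
            )
    return out
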