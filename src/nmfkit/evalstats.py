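"""Statistical comparison of classifiers.

Three tools: (i) the smallest training-set size at which a classifier's
accuracy is significantly better than chance, judged by a label-permutation
test; (ii) an inverse-power-law learning curve e(n) = a n^(-alpha) + b
fitted to error rates so performance can be extrapolated to larger data;
(iii) the Friedman rank test over a classifiers-by-datasets accuracy table
with the post-hoc Nemenyi test and its critical-difference (CD) diagram:
two classifiers differ significantly when their mean ranks are more than
CD = q_alpha sqrt(k(k+1)/(6N)) apart, with q_alpha the studentized-range
quantile at infinite degrees of freedom divided by sqrt 2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.typing import ArrayLike, NDArray
from scipy import stats
from scipy.optimize import curve_fit

from .classification import nnls_fit, nnls_predict

__all__ = [
    "LearningCurve",
    "ComparisonTable",
    "minimum_significant_size",
    "fit_learning_curve",
    "friedman_test",
    "nemenyi_cd",
    "cd_groups",
    "render_cd_diagram",
]


@dataclass
class LearningCurve:
    """Fitted inverse power law e(n) = a n^(-alpha) + b."""

    a: float
    alpha: float
    b: float
    sizes: NDArray[np.float64]
    errors: NDArray[np.float64]
    rss: float

    def __call__(self, n: ArrayLike) -> NDArray[np.float64]:
        return self.a * np.asarray(n, dtype=float) ** (-self.alpha) + self.b


@dataclass
class ComparisonTable:
    """Friedman test over a k-classifiers x N-datasets accuracy table."""

    accuracies: NDArray[np.float64]
    ranks: NDArray[np.float64]
    mean_ranks: NDArray[np.float64]
    chi2_F: float
    p_value: float
    iman_davenport_F: float
    iman_davenport_p: float
    CD: float = np.nan
    alpha: float = 0.05
    names: list[str] | None = None


def _evaluate_subsample(X, labels, train_idx, test_idx):
    model = nnls_fit(X[:, train_idx], labels[train_idx])
    pred, _ = nnls_predict(model, X[:, test_idx])
    return float(np.mean(pred == labels[test_idx]))


def _mean_accuracy_at_size(X, labels, size, reps, rng):
    """Mean held-out accuracy over `reps` random train subsets of `size`."""
    n = X.shape[1]
    classes = np.unique(labels)
    accs = []
    for _ in range(reps):
        # sample a training set containing at least one sample per class
        while True:
            tr = rng.choice(n, size=size, replace=False)
            if all((labels[tr] == c).any() for c in classes):
                break
        te = np.setdiff1d(np.arange(n), tr)
        accs.append(_evaluate_subsample(X, labels, tr, te))
    return float(np.mean(accs))


def minimum_significant_size(
    X: ArrayLike,
    labels: ArrayLike,
    candidate_sizes: list[int],
    alpha: float = 0.05,
    reps: int = 10,
    n_permutations: int = 200,
    seed: int = 0,
) -> tuple[int | None, dict[int, float]]:
    """Smallest training size whose mean accuracy beats the permutation null.

    For each candidate size n the observed statistic is the mean held-out
    accuracy of the NNLS classifier over ``reps`` random training subsets.
    The null distribution repeats the identical protocol on label-permuted
    data; the p-value is the usual add-one permutation estimate.  Returns
    (smallest significant n or None, {n: p-value}).
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    n = X.shape[1]
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if any(s >= n for s in candidate_sizes):
        raise ValueError("candidate sizes must leave held-out samples")
    if sorted(candidate_sizes) != list(candidate_sizes):
        raise ValueError("candidate_sizes must be ascending")
    rng = np.random.default_rng(seed)
    p_values: dict[int, float] = {}
    best: int | None = None
    for size in candidate_sizes:
        obs = _mean_accuracy_at_size(X, labels, size, reps, rng)
        null = np.empty(n_permutations)
        for b in range(n_permutations):
            perm = rng.permutation(labels)
            null[b] = _mean_accuracy_at_size(X, perm, size, 1, rng)
        p = (1.0 + float(np.sum(null >= obs))) / (n_permutations + 1.0)
        p_values[size] = p
        if best is None and p < alpha:
            best = size
    return best, p_values


def fit_learning_curve(
    sizes: ArrayLike,
    errors: ArrayLike,
    weights: ArrayLike | None = None,
) -> LearningCurve:
    """Least-squares fit of e(n) = a n^(-alpha) + b.

    Bounds: a >= 0, alpha in (0, 3], b in [0, 1).  Initialized from a
    log-log regression of errors - min(errors) + eps against n, which is
    exact when the data lie on the curve.
    """
    sizes = np.asarray(sizes, dtype=float)
    errors = np.asarray(errors, dtype=float)
    if len(np.unique(sizes)) < 3:
        raise ValueError("need at least 3 distinct sizes")
    if errors.min() < 0 or errors.max() > 1:
        raise ValueError("errors must be rates in [0, 1]")

    eps = 1e-9
    shifted = errors - errors.min() + eps
    slope, intercept = np.polyfit(np.log(sizes), np.log(shifted), 1)
    a0 = float(np.clip(np.exp(intercept), 1e-8, 1e3))
    alpha0 = float(np.clip(-slope, 1e-3, 3.0))
    b0 = float(np.clip(errors.min(), 0.0, 1.0 - 1e-9))

    def model(n, a, alpha, b):
        return a * n ** (-alpha) + b

    sigma = None if weights is None else 1.0 / np.sqrt(np.asarray(weights, float))
    popt, _ = curve_fit(
        model,
        sizes,
        errors,
        p0=[a0, alpha0, b0],
        bounds=([0.0, 1e-6, 0.0], [np.inf, 3.0, 1.0 - 1e-12]),
        sigma=sigma,
        maxfev=20000,
    )
    fitted = model(sizes, *popt)
    return LearningCurve(
        a=float(popt[0]),
        alpha=float(popt[1]),
        b=float(popt[2]),
        sizes=sizes,
        errors=errors,
        rss=float(np.sum((fitted - errors) ** 2)),
    )


def friedman_test(
    accuracies: ArrayLike, names: list[str] | None = None
) -> ComparisonTable:
    """Friedman rank test: do k classifiers perform equally over N datasets?

    Ranks are per dataset, 1 = best accuracy, ties averaged.  The statistic
    chi2_F = 12N/(k(k+1)) [sum_j R_j^2 - k(k+1)^2/4] is referred to a
    chi-square with k-1 df; the Iman-Davenport F refinement is reported
    alongside.
    """
    acc = np.asarray(accuracies, dtype=float)
    if acc.ndim != 2:
        raise ValueError("accuracies must be a k x N matrix")
    if np.isnan(acc).any():
        raise ValueError("accuracy table must be complete (no NaN)")
    k, N = acc.shape
    if k < 2 or N < 2:
        raise ValueError("need at least 2 classifiers and 2 datasets")
    ranks = np.empty_like(acc)
    for j in range(N):
        ranks[:, j] = stats.rankdata(-acc[:, j])
    R = ranks.mean(axis=1)
    chi2 = 12.0 * N / (k * (k + 1)) * (float(np.sum(R**2)) - k * (k + 1) ** 2 / 4.0)
    chi2 = max(chi2, 0.0)
    p = float(stats.chi2.sf(chi2, k - 1))
    denom = N * (k - 1) - chi2
    if denom <= 0:
        F, pF = np.inf, 0.0
    else:
        F = (N - 1) * chi2 / denom
        pF = float(stats.f.sf(F, k - 1, (k - 1) * (N - 1)))
    return ComparisonTable(
        accuracies=acc,
        ranks=ranks,
        mean_ranks=R,
        chi2_F=float(chi2),
        p_value=p,
        iman_davenport_F=float(F),
        iman_davenport_p=pF,
        names=names,
    )


def nemenyi_cd(k: int, N: int, alpha: float = 0.05) -> float:
    """Nemenyi critical difference CD = q_alpha(k) sqrt(k(k+1)/(6N)).

    ``q_alpha`` is the studentized-range quantile at infinite degrees of
    freedom divided by sqrt 2 (so q_alpha(2) is the two-sided normal
    quantile, 1.960 at alpha = 0.05).
    """
    if not 2 <= k <= 20:
        raise ValueError("k must be between 2 and 20")
    if alpha not in (0.05, 0.10):
        raise ValueError("alpha must be 0.05 or 0.10")
    q = stats.studentized_range.ppf(1 - alpha, k, np.inf) / np.sqrt(2.0)
    return float(q * np.sqrt(k * (k + 1) / (6.0 * N)))


def cd_groups(mean_ranks: ArrayLike, cd: float) -> list[tuple[int, ...]]:
    """Maximal groups of classifiers not significantly different from each
    other (mean-rank span <= CD); the bars of the CD diagram."""
    r = np.asarray(mean_ranks, dtype=float)
    order = np.argsort(r)
    groups: list[tuple[int, ...]] = []
    k = len(r)
    for i in range(k):
        members = [order[j] for j in range(i, k) if r[order[j]] - r[order[i]] <= cd]
        if len(members) > 1:
            g = tuple(members)
            if not any(set(g) <= set(prev) for prev in groups):
                groups.append(g)
    return groups


def render_cd_diagram(
    table: ComparisonTable, path, alpha: float = 0.05
) -> list[tuple[int, ...]]:
    """Draw the critical-difference diagram and return the group structure.

    Classifiers sit at their mean ranks on a 1..k axis; a bar spans each
    maximal group whose mean ranks all lie within one CD.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    k, N = table.accuracies.shape
    cd = nemenyi_cd(k, N, alpha)
    table.CD = cd
    table.alpha = alpha
    names = table.names or [f"clf{i + 1}" for i in range(k)]
    groups = cd_groups(table.mean_ranks, cd)

    fig, ax = plt.subplots(figsize=(7, 2 + 0.35 * k))
    ax.set_xlim(0.5, k + 0.5)
    ax.set_ylim(-1.2 - 0.35 * max(len(groups), 1), 1.6)
    ax.spines[["left", "right", "bottom"]].set_visible(False)
    ax.get_yaxis().set_visible(False)
    ax.xaxis.set_ticks_position("top")
    ax.set_xticks(range(1, k + 1))
    ax.plot([1, 1 + cd], [1.25, 1.25], lw=3, color="k")
    ax.text(1 + cd / 2, 1.35, f"CD = {cd:.3f}", ha="center", fontsize=8)
    order = np.argsort(table.mean_ranks)
    for pos, idx in enumerate(order):
        r = table.mean_ranks[idx]
        ax.plot([r, r], [0, 0.9], color="k", lw=1)
        ax.text(
            r, 1.0, names[idx], rotation=60, ha="left", va="bottom", fontsize=8
        )
    for gi, g in enumerate(groups):
        lo = min(table.mean_ranks[i] for i in g)
        hi = max(table.mean_ranks[i] for i in g)
        y = -0.3 - 0.35 * gi
        ax.plot([lo - 0.03, hi + 0.03], [y, y], lw=3, color="0.3")
    ax.axhline(0, color="k", lw=1)
    fig.savefig(path, bbox_inches="tight")
    plt.close(fig)
    return groups
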