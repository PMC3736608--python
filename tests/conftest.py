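import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


def random_psd(rng, p, rank=None):
    """Random PSD matrix via M'M, optionally rank-deficient."""
    r = rank if rank is not None else p
    M = rng.standard_normal((r, p))
    return M.T @ M


def brute_force_nnqp(H, g):
    """Global NNQP minimizer by enumerating all 2^p active sets.

    For convex problems, the minimizer over the feasible candidates (the
    unconstrained optimum on each free set, kept if non-negative) is the
    global solution.  Exponential: only for small p.
    """
    p = len(g)
    best, best_obj = np.zeros(p), 0.0
    for mask in range(1, 2**p):
        free = np.array([(mask >> i) & 1 == 1 for i in range(p)])
        idx = np.flatnonzero(free)
        try:
            zf = np.linalg.solve(H[np.ix_(idx, idx)], -g[idx])
        except np.linalg.LinAlgError:
            continue
        if np.any(zf < 0):
            continue
        z = np.zeros(p)
        z[idx] = zf
        obj = 0.5 * z @ H @ z + g @ z
        if obj < best_obj - 1e-15:
            best, best_obj = z, obj
    return best
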