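"""Recover rising and falling temporal programs from mixed-sign data.

Emulates factorizing a standardized time-series expression matrix: two
planted temporal profiles (one rising, one falling) mix into the observed
samples.  Because the data are mixed-sign, the basis is left sign-free
(t1 = 0) while the coefficients stay non-negative, with a small l1 penalty
on the basis and l2 smoothing on the coefficients.
"""

import numpy as np

from nmfkit import FitOptions, VSMFConfig, vsmf

rng = np.random.default_rng(1)
t = np.linspace(0, 1, 16)
rise, fall = t - 0.5, 0.5 - t
A_true = np.column_stack([rise, fall])
Y_true = np.vstack(
    [np.r_[rng.random(6) + 1, rng.random(6) * 0.1],
     np.r_[rng.random(6) * 0.1, rng.random(6) + 1]]
)
X = A_true @ Y_true + 0.01 * rng.standard_normal((16, 12))

res = vsmf(
    X, k=2,
    cfg=VSMFConfig(alpha1=0.01, lambda2=0.01, t1=False, t2=True),
    algo="active_set",
    opts=FitOptions(max_iter=200, seed=3),
)
corr = np.abs(np.corrcoef(res.A.T, A_true.T)[:2, 2:])
print("correlation of recovered basis vectors with planted profiles:")
print(np.round(corr, 3))
print("each planted profile is matched by one recovered basis vector "
      f"(best match per profile: {np.round(corr.max(axis=0), 3).tolist()})")
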