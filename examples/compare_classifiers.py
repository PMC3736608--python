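"""Compare classifiers across datasets with the Friedman + Nemenyi test.

Simulates an accuracy table of four classifiers over ten datasets (one
consistently better, one consistently worse), runs the Friedman rank test,
and draws the critical-difference diagram.
"""

import numpy as np

from nmfkit import friedman_test, nemenyi_cd, render_cd_diagram

rng = np.random.default_rng(0)
base = 0.75 + 0.05 * rng.standard_normal((4, 10))
base[0] += 0.08   # classifier "nnls" consistently better
base[3] -= 0.08   # classifier "weak" consistently worse
acc = np.clip(base, 0, 1)

table = friedman_test(acc, names=["nnls", "svm", "knn", "weak"])
print("mean ranks:", np.round(table.mean_ranks, 2).tolist())
print(f"Friedman chi2_F = {table.chi2_F:.3f}, p = {table.p_value:.4f}")
print(f"Iman-Davenport F = {table.iman_davenport_F:.3f}, "
      f"p = {table.iman_davenport_p:.4f}")

cd = nemenyi_cd(k=4, N=10, alpha=0.05)
print(f"Nemenyi critical difference (alpha = 0.05): CD = {cd:.3f}")
groups = render_cd_diagram(table, "cd_diagram.svg")
print("groups not significantly different (bars in cd_diagram.svg):", groups)
# two classifiers differ significantly iff their mean ranks are > CD apart
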