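"""Group statistics: weight comparisons and whole-curve SPM.

Compares matched synergy weights between a patient-like and a healthy
cohort (Shapiro-Wilk/Levene-routed t or rank-sum tests, Cohen's d) and
compares activation-coefficient curves with a permutation SPM whose
field-wide threshold controls the error over all 101 phase nodes.
"""

import numpy as np

from synergykit import cohens_d, spm_compare_curves

# effect size exactly as reported from group summary statistics:
# gluteus maximus weight in the hip synergy, n = 22 per group
d = cohens_d(0.50, 0.25, 22, 0.32, 0.13, 22)
print(f"Cohen's d for GM weights (0.50+-0.25 vs 0.32+-0.13, n=22): {d:.3f}")
print("-> a large effect (> 0.8): patients load the gluteus maximus more.\n")

# SPM: inject a mid-phase amplitude difference and find its extent
rng = np.random.default_rng(0)
kernel = np.hanning(21)
kernel /= kernel.sum()


def smooth_curves(n):
    raw = rng.standard_normal((n, 121))
    return np.apply_along_axis(lambda r: np.convolve(r, kernel, "valid"), 1, raw)


group1 = smooth_curves(22)
group1[:, 50:81] += 1.2  # higher activation at 50-80 % of the phase
group2 = smooth_curves(22)

res = spm_compare_curves(group1, group2, alpha=0.05, n_perm=2000, seed=1)
print(f"SPM critical threshold (max-|t| permutation): {res.threshold:.2f}")
for c in res.clusters:
    print(
        f"  supra-threshold cluster {c.start_pct:.0f}-{c.end_pct:.0f} % "
        f"of the phase, p = {c.p:.4f}"
    )
print("-> the detected interval brackets the injected 50-80 % difference;")
print("   cluster p-values are permutation tail probabilities of extent.")
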