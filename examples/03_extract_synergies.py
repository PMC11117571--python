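"""Synergy extraction: one subject's trials -> W, C and the synergy count.

Generates one synthetic subject (4 true modules, 3 trials, SNR 20 dB),
concatenates the trials into the data matrix V (10 x 303), and selects
the synergy number by the dual-VAF protocol: smallest k with global
VAF >= 90 % and every per-muscle VAF >= 75 %.
"""

import numpy as np

from synergykit import (
    assemble_data_matrix,
    make_ground_truth,
    select_synergy_number,
    synthesize_subject,
)

gt = make_ground_truth(seed=42)
subject = synthesize_subject(gt, "healthy", subject_seed=7)
V = assemble_data_matrix([t.values for t in subject.trials])
print(f"data matrix V: {V.shape[0]} muscles x {V.shape[1]} samples (3 trials x 101)")

result = select_synergy_number(V, k_max=8, seed=0, n_restarts=20)
for row in result.vaf_table():
    marker = " <- selected" if row["k"] == result.n_opt else ""
    print(
        f"  k={row['k']}: global VAF {100 * row['vaf_global']:5.1f} %, "
        f"min muscle VAF {100 * row['vaf_local_min']:5.1f} %{marker}"
    )
print(f"selected synergy number: {result.n_opt} (true: {gt.k_true})")

W = result.selected.W
print("\nsynergy vectors (muscle weights, unit-norm columns):")
header = "      " + "".join(f"  syn{j + 1}" for j in range(W.shape[1]))
print(header)
for name, weights in zip(gt.muscle_names, W):
    print(f"  {name:>3} " + "".join(f" {w:5.2f}" for w in weights))
print("-> each column is one spatial module; large weights mark the")
print("   muscles recruited together by that module.")
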