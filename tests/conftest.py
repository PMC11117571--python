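"""Shared fixtures: seeded RNGs and the default synthetic cohort.

The heavyweight fixtures (full 22+22 dataset, per-subject rank
selection) are session-scoped so the synergy-count, clustering and
recovery tests all reuse one set of decompositions.
"""

import numpy as np
import pytest

from synergykit import (
    assemble_data_matrix,
    make_ground_truth,
    select_synergy_number,
    synthesize_dataset,
)

DATASET_SEED = 0


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def ground_truth():
    return make_ground_truth(seed=42)


@pytest.fixture(scope="session")
def default_dataset():
    """The default study-conditions cohort: 22+22 subjects, 3 trials,
    SNR 20 dB."""
    return synthesize_dataset(seed=DATASET_SEED)


@pytest.fixture(scope="session")
def healthy_rank_selection(default_dataset):
    """Dual-VAF rank selection for every healthy-like subject."""
    out = {}
    for sub in default_dataset.by_group("healthy"):
        V = assemble_data_matrix([t.values for t in sub.trials])
        out[sub.subject_id] = select_synergy_number(
            V, k_max=8, seed=sub.seed, n_restarts=20
        )
    return out
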