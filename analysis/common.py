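"""Shared paths and the study configuration for the analysis drivers.

The synthetic study: one planted table whose rows are split into a
training part at the published 6.37:1 negative:positive ratio and a
held-out part at ~16:1, sharing the same planted signal columns.
"""

from pathlib import Path

import numpy as np

from ppiselect import FeatureTable, SyntheticSpec, generate_table

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
DATA = RESULTS / "data"

SEED = 1

N_TRAIN_POS, N_TRAIN_NEG = 120, 764   # ratio 6.37
N_TEST_POS, N_TEST_NEG = 60, 960      # ratio 16

STUDY_SPEC = SyntheticSpec(
    n_pos=N_TRAIN_POS + N_TEST_POS,
    n_neg=N_TRAIN_NEG + N_TEST_NEG,
    n_features=60,
    n_informative=12,
    effect=1.5,
    n_redundant=12,
    zero_inflation=0.3,
    seed=SEED,
)


def split_study(full: FeatureTable) -> tuple[FeatureTable, FeatureTable]:
    pos = np.flatnonzero(full.y == 1)
    neg = np.flatnonzero(full.y == 0)
    train = full.subset_rows(np.r_[pos[:N_TRAIN_POS], neg[:N_TRAIN_NEG]])
    test = full.subset_rows(np.r_[pos[N_TRAIN_POS:], neg[N_TRAIN_NEG:]])
    return train, test


def study_tables() -> tuple[FeatureTable, FeatureTable, object]:
    full, truth = generate_table(STUDY_SPEC)
    train, test = split_study(full)
    return train, test, truth
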