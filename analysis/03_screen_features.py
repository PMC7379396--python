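"""Stage 1: shadow-feature screening of the training table.

Features whose forest importance beats the best row-permuted shadow in a
majority of iterations are confirmed; the survivors (confirmed plus
undecided) feed the ranking stage.
"""

import json

from ppiselect import BorutaConfig, boruta_run, read_table, selected_features
from ppiselect.evaluation import derive_seed

from common import DATA, RESULTS, SEED

train = read_table(DATA / "train.csv")
result = boruta_run(
    train, BorutaConfig(max_iter=20, n_trees=50, seed=derive_seed(SEED, "boruta"))
)
kept = selected_features(result, keep_undecided=True)

truth = json.loads((DATA / "planted_truth.json").read_text())
signal = set(truth["informative"]) | {int(v) for v in truth["redundant"].values()} | {
    int(k) for k in truth["redundant"]
}

with open(RESULTS / "screening.tsv", "w") as fh:
    fh.write("feature\tstatus\tmean_importance\n")
    for i, status in enumerate(result.status):
        fh.write(
            f"{train.feature_names[i]}\t{status}\t{result.importance_history[i].mean():.6f}\n"
        )
(RESULTS / "screening_selected.json").write_text(json.dumps(kept))

print(f"{len(kept)} of {train.n_features} features retained "
      f"after {result.n_iterations} iterations")
print(f"planted signal recall: {len(signal & set(kept))}/{len(signal)}")
print(f"noise features retained: {len(set(kept) - signal)}")
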