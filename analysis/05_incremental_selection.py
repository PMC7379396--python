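"""Stage 3: incremental feature selection with RF, RIPPER and 1-NN.

Cross-validates each classifier on growing prefixes of the ranking
(SMOTE applied to training folds only) and reports the optimal prefix
and the smaller proposed prefix within 0.015 F-measure of it.
"""

import json

import numpy as np
import pandas as pd

from ppiselect import CVConfig, SmoteConfig, ifs_run, read_table, select_optimal, select_proposed
from ppiselect.classifiers import ForestConfig, forest_factory, nna_factory
from ppiselect.evaluation import derive_seed
from ppiselect.ripper import RipperConfig, ripper_factory

from common import DATA, RESULTS, SEED

train = read_table(DATA / "train.csv")
ranked = pd.read_csv(RESULTS / "ri_table.tsv", sep="\t")["feature_index"].to_numpy()
cv = CVConfig(n_folds=10, seed=derive_seed(SEED, "ifs-cv"))
smote_cfg = SmoteConfig(seed=derive_seed(SEED, "smote"))
ks = sorted(set(range(1, len(ranked) + 1, 2)) | {len(ranked)})

factories = {
    "rf10": forest_factory(ForestConfig(n_trees=10)),
    "rf50": forest_factory(ForestConfig(n_trees=50)),
    "ripper": ripper_factory(RipperConfig()),
    "nna": nna_factory(),
}
selections = {}
for tag, factory in factories.items():
    curve = ifs_run(train, ranked, factory, cv, ks, smote_cfg, tag)
    curve.to_frame().to_csv(RESULTS / f"ifs_{tag}.tsv", sep="\t", index=False)
    sel = select_proposed(curve, select_optimal(curve), 0.015)
    selections[tag] = {
        "optimal_k": sel.optimal_k, "optimal_f": round(sel.optimal_metric, 4),
        "proposed_k": sel.proposed_k, "proposed_f": round(sel.proposed_metric, 4),
    }
    print(f"{tag:7s} optimal k={sel.optimal_k:3d} (F={sel.optimal_metric:.3f})  "
          f"proposed k={sel.proposed_k:3d} (F={sel.proposed_metric:.3f})")

(RESULTS / "selections.json").write_text(json.dumps(selections, indent=2))
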