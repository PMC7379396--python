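"""Rule induction on the proposed features and the held-out evaluation.

Learns an ordered IF-THEN rule set on the proposed RIPPER prefix, then
fits the proposed random forest and the rule set on the (SMOTE-balanced)
training split and scores both on the untouched held-out split.
"""

import json
from dataclasses import replace

import numpy as np
import pandas as pd

from ppiselect import SmoteConfig, apply_ruleset, read_table, smote
from ppiselect.classifiers import ForestConfig, forest_factory
from ppiselect.evaluation import derive_seed, metrics_from_counts, roc_pr_curves
from ppiselect.ripper import RipperConfig, format_ruleset, ripper_fit, ruleset_predictor

from common import DATA, RESULTS, SEED

train = read_table(DATA / "train.csv")
test = read_table(DATA / "test.csv")
ranked = pd.read_csv(RESULTS / "ri_table.tsv", sep="\t")["feature_index"].to_numpy()
selections = json.loads((RESULTS / "selections.json").read_text())
smote_cfg = SmoteConfig(seed=derive_seed(SEED, "rules-smote"))

rule_feats = ranked[: selections["ripper"]["proposed_k"]]
rule_train = train.subset_features(rule_feats)
rs = ripper_fit(rule_train, RipperConfig(seed=derive_seed(SEED, "rules")))
(RESULTS / "rules.txt").write_text(format_ruleset(rs))
acc = (apply_ruleset(rs, rule_train).y_pred == rule_train.y).mean()
print(f"learned {rs.n_rules} rules (incl. default); training accuracy {acc:.3f}")
print(format_ruleset(rs))

report = {}
for tag, feats in (("rf50", ranked[: selections["rf50"]["optimal_k"]]),
                   ("ripper", rule_feats)):
    sub_train = smote(train.subset_features(feats),
                      replace(smote_cfg, seed=derive_seed(SEED, "fit-smote", tag)))
    sub_test = test.subset_features(feats)
    if tag == "rf50":
        predictor = forest_factory(ForestConfig(n_trees=50))(
            sub_train, derive_seed(SEED, "fit", tag)
        )
    else:
        fitted = ripper_fit(sub_train, RipperConfig(seed=derive_seed(SEED, "fit", tag)))
        predictor = ruleset_predictor(fitted, sub_train.feature_names)
    preds = predictor(sub_test.X)
    preds.y_true = sub_test.y
    rep = metrics_from_counts(preds.counts())
    entry = rep.to_dict()
    if len(np.unique(preds.scores)) > 1:
        curves = roc_pr_curves(preds)
        entry["auroc"], entry["aupr"] = curves.auroc, curves.aupr
    report[tag] = {k: round(v, 4) for k, v in entry.items()}
    print(f"{tag:7s} held-out F={entry['f_measure']:.3f}  "
          f"SN={entry['SN']:.3f} SP={entry['SP']:.3f} MCC={entry['MCC']:.3f}")

(RESULTS / "test_report.json").write_text(json.dumps(report, indent=2))
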