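"""End-to-end orchestration of the three-stage analysis.

The stages, in order: load or generate a labeled feature table; dataset
identity diagnostic; shadow-feature screening; Monte Carlo ranking of the
survivors; incremental feature selection with a random-forest grid, a
rule learner, and a nearest-neighbor comparator; optimal/proposed prefix
selection; optional permutation-null significance bands and repeated-CV
comparison; rule-set induction on the selected features; and, when a
test table is supplied, a held-out train/test evaluation report.

Every artifact is written under the output directory and recorded in a
``manifest.json`` together with the derived per-stage seeds and input
hashes, so a rerun with the same configuration reproduces every
deterministic artifact.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np

from . import __version__
from .boruta import BorutaConfig, boruta_run, selected_features
from .classifiers import ForestConfig, forest_factory, nna_factory
from .dataset_io import FeatureTable, identity_histogram, read_table, write_table
from .errors import ValidationError
from .evaluation import CVConfig, cross_validate, derive_seed, metrics_from_counts, roc_pr_curves
from .ifs import (
    IFSCurve,
    ifs_run,
    permutation_bands,
    repeated_cv_compare,
    select_optimal,
    select_proposed,
)
from .mcfs import MCFSConfig, mcfs_run
from .resampling import SmoteConfig, smote
from .ripper import RipperConfig, format_ruleset, ripper_factory, ripper_fit, ruleset_predictor
from .synthetic import SyntheticSpec, generate_table


@dataclass(frozen=True)
class PipelineConfig:
    """One configuration object for a full run.

    Exactly one input source: either ``synthetic`` or ``train_path``
    (with optional ``test_path``).
    """

    out_dir: str
    seed: int = 0
    synthetic: SyntheticSpec | None = None
    train_path: str | None = None
    test_path: str | None = None
    dialect: str = "csv"
    cv: CVConfig = field(default_factory=CVConfig)
    boruta: BorutaConfig = field(default_factory=lambda: BorutaConfig(max_iter=20, n_trees=50))
    mcfs: MCFSConfig = field(default_factory=lambda: MCFSConfig(M=5, T=60))
    forest_grid: tuple[int, ...] = (10, 50)
    ripper: RipperConfig = field(default_factory=RipperConfig)
    smote_cfg: SmoteConfig = field(default_factory=SmoteConfig)
    smote_once: bool = False  # apply SMOTE to the whole table before CV (leaky variant)
    ifs_metric: str = "f_measure"
    ifs_delta: float = 0.015
    ifs_k_stride: int = 1
    n_perm: int = 0  # permutation bands skipped when 0
    band_levels: tuple[float, ...] = (0.95,)
    n_repeats_compare: int = 0  # repeated-CV comparison skipped when 0
    identity_mode: str = "all_vs_all"

    def __post_init__(self) -> None:
        if (self.synthetic is None) == (self.train_path is None):
            raise ValidationError("exactly one input source (synthetic or train_path)")


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute all stages; returns the manifest (also written to disk)."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "seed": cfg.seed, "stages": {}}
    t0 = time.time()

    def record(stage: str, **info) -> None:
        info["wall_s"] = round(time.time() - t0, 2)
        manifest["stages"][stage] = info
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))

    try:
        # ------------------------------------------------------------ input
        if cfg.synthetic is not None:
            spec = replace(cfg.synthetic, seed=derive_seed(cfg.seed, "synthetic"))
            train, truth = generate_table(spec)
            write_table(train, out / "train.csv")
            test = None
            record(
                "input",
                source="synthetic",
                train=str(out / "train.csv"),
                planted_informative=sorted(truth.informative_indices),
            )
        else:
            train = read_table(cfg.train_path, cfg.dialect)
            test = read_table(cfg.test_path, cfg.dialect) if cfg.test_path else None
            record(
                "input",
                source="files",
                train=cfg.train_path,
                train_sha256=_file_hash(cfg.train_path),
                n_rows=train.n_rows,
                n_positive=train.n_positive,
                **(
                    {"test": cfg.test_path, "test_rows": test.n_rows}
                    if test is not None
                    else {}
                ),
            )

        # --------------------------------------------------------- identity
        hist = identity_histogram(
            train, cfg.identity_mode, seed=derive_seed(cfg.seed, "identity")
        )
        hist.to_frame().to_csv(out / "identity_histogram.tsv", sep="\t", index=False)
        record("identity", histogram=str(out / "identity_histogram.tsv"), n_pairs=hist.n_pairs)

        # -------------------------------------------------------- screening
        bcfg = replace(cfg.boruta, seed=derive_seed(cfg.seed, "boruta"))
        bres = boruta_run(train, bcfg)
        retained = selected_features(bres, keep_undecided=True)
        if len(retained) < 2:
            retained = list(range(train.n_features))  # degenerate: keep everything
        _write_tsv(
            out / "screening.tsv",
            ["feature", "status", "mean_importance", "zscore"],
            [
                (
                    train.feature_names[i],
                    bres.status[i],
                    float(bres.importance_history[i].mean()),
                    float(bres.zscores[i]) if np.isfinite(bres.zscores[i]) else "inf",
                )
                for i in range(train.n_features)
            ],
        )
        record("screening", retained=len(retained), table=str(out / "screening.tsv"))

        # ---------------------------------------------------------- ranking
        screened = train.subset_features(retained)
        mres = mcfs_run(screened, replace(cfg.mcfs, seed=derive_seed(cfg.seed, "mcfs")))
        ranked_local = mres.ranked
        ranked = np.array([retained[i] for i in ranked_local])
        mres.to_frame().to_csv(out / "ri_table.tsv", sep="\t", index=False)
        record("ranking", table=str(out / "ri_table.tsv"))

        # --------------------------------------------------------------- ifs
        smote_cfg = cfg.smote_cfg
        cv = replace(cfg.cv, seed=derive_seed(cfg.seed, "ifs-cv"))
        ifs_table = train
        if cfg.smote_once:
            ifs_table = smote(train, replace(smote_cfg, seed=derive_seed(cfg.seed, "smote-once")))
            smote_cfg = None
            cv = replace(cv, smote_inside_folds=False)
        ks = np.arange(1, len(ranked) + 1, cfg.ifs_k_stride)
        if ks[-1] != len(ranked):
            ks = np.append(ks, len(ranked))
        curves: dict[str, IFSCurve] = {}
        for T in cfg.forest_grid:
            tag = f"rf{T}"
            curves[tag] = ifs_run(
                ifs_table, ranked, forest_factory(ForestConfig(n_trees=T)), cv, ks,
                smote_cfg, tag,
            )
        curves["ripper"] = ifs_run(
            ifs_table, ranked, ripper_factory(cfg.ripper), cv, ks, smote_cfg, "ripper"
        )
        curves["nna"] = ifs_run(ifs_table, ranked, nna_factory(), cv, ks, smote_cfg, "nna")
        selections = {}
        for tag, curve in curves.items():
            curve.to_frame().to_csv(out / f"ifs_{tag}.tsv", sep="\t", index=False)
            sel = select_proposed(
                curve, select_optimal(curve, cfg.ifs_metric), cfg.ifs_delta
            )
            selections[tag] = {
                "optimal_k": sel.optimal_k,
                "optimal_metric": sel.optimal_metric,
                "proposed_k": sel.proposed_k,
                "proposed_metric": sel.proposed_metric,
            }
        (out / "selections.json").write_text(json.dumps(selections, indent=2))
        record("ifs", selections=selections)

        best_rf_tag = max(
            (t for t in curves if t.startswith("rf")),
            key=lambda t: selections[t]["optimal_metric"],
        )
        best_T = int(best_rf_tag[2:])
        optimal_k = selections[best_rf_tag]["optimal_k"]

        # ----------------------------------------------------- significance
        if cfg.n_perm:
            band, verdicts, actual = permutation_bands(
                ifs_table,
                ranked,
                forest_factory(ForestConfig(n_trees=best_T)),
                cv,
                n_perm=cfg.n_perm,
                levels=cfg.band_levels,
                seed=derive_seed(cfg.seed, "bands"),
                k_grid=ks,
                smote_cfg=smote_cfg,
            )
            band.to_frame().to_csv(out / "permutation_bands.tsv", sep="\t", index=False)
            record(
                "significance",
                verdicts={str(k): int(v) for k, v in verdicts.items()},
                bands=str(out / "permutation_bands.tsv"),
            )

        if cfg.n_repeats_compare:
            compare = repeated_cv_compare(
                ifs_table,
                ranked[:optimal_k],
                np.arange(train.n_features),
                forest_factory(ForestConfig(n_trees=best_T)),
                replace(cv, n_repeats=cfg.n_repeats_compare),
                smote_cfg,
            )
            compare.to_frame().to_csv(out / "repeated_cv.tsv", sep="\t", index=False)
            record(
                "repeated_cv",
                t_statistic=compare.t_statistic,
                p_value=compare.p_value,
                degenerate=compare.degenerate,
            )

        # ------------------------------------------------------------ rules
        rs = ripper_fit(
            train.subset_features(ranked[: selections["ripper"]["proposed_k"]]),
            replace(cfg.ripper, seed=derive_seed(cfg.seed, "ripper")),
        )
        (out / "rules.txt").write_text(format_ruleset(rs))
        record("rules", n_rules=rs.n_rules, file=str(out / "rules.txt"))

        # ------------------------------------------------------- evaluation
        if test is not None:
            report = {}
            for tag, feats in (
                (best_rf_tag, ranked[:optimal_k]),
                ("ripper", ranked[: selections["ripper"]["optimal_k"]]),
            ):
                sub_train = train.subset_features(feats)
                sub_train = smote(
                    sub_train, replace(cfg.smote_cfg, seed=derive_seed(cfg.seed, "test-smote", tag))
                )
                sub_test = test.subset_features(
                    [test.feature_index(train.feature_names[i]) for i in feats]
                )
                if tag.startswith("rf"):
                    fac = forest_factory(ForestConfig(n_trees=best_T))
                else:
                    fac = ripper_factory(cfg.ripper)
                predictor = fac(sub_train, derive_seed(cfg.seed, "test-fit", tag))
                preds = predictor(sub_test.X)
                preds.y_true = sub_test.y
                rep = metrics_from_counts(preds.counts())
                entry = rep.to_dict()
                if len(np.unique(preds.scores)) > 1:
                    curves_r = roc_pr_curves(preds)
                    entry["auroc"] = curves_r.auroc
                    entry["aupr"] = curves_r.aupr
                report[tag] = entry
            (out / "test_report.json").write_text(json.dumps(report, indent=2))
            record("test_evaluation", report=report)

        manifest["status"] = "success"
    except Exception as exc:
        manifest["status"] = f"failed: {exc}"
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
        raise
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest


def _write_tsv(path: Path, header: list[str], rows: list[tuple]) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(v) for v in row) + "\n")


def _file_hash(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()
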