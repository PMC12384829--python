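"""End-to-end pipeline: generate -> impute -> standardize -> group-wise PCA
-> labels/transitions -> stratified CV training -> best-model selection ->
full-dataset evaluation -> three explainability reports.

A single master seed fans out to per-stage child seeds, so rerunning with the
same configuration produces byte-identical reports (timestamps and wall-time
live only in the manifest).
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import explain, io, network as net, preprocessing as prep
from ._seeds import child_seed
from .cohort import default_cohort_spec, generate_cohort
from .evaluation import (
    cross_validate,
    make_stratified_folds,
    metrics_from_confusion,
    confusion_from_predictions,
    roc_and_auc,
    round_half_up,
    select_best_model,
    transition_error_table,
)

logger = logging.getLogger("pdcognet")

__all__ = ["PipelineConfig", "RunManifest", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Everything one run needs; round-trips losslessly through YAML."""

    out_dir: str = "pdcognet_run"
    master_seed: int = 0
    cohort_csv: str | None = None  # if set (with cohort_meta), generation is skipped
    cohort_meta: str | None = None
    generate: bool = True
    n_subjects: int = 618
    missing_rate: float = 0.1
    impute_method: str = "forest"
    eigenvalue_min: float = 1.5
    min_group_size_for_pca: int = 6
    k_folds: int = 5
    hidden_sizes: tuple[int, ...] = (7,)
    alpha: tuple[float, float] = (0.5, 2.0)
    gamma: float = 1.5
    batch_size: int = 8
    max_epochs: int = 50
    early_stopping_patience: int = 5
    validation_fraction: float = 0.1
    threshold: float = 0.5
    n_permutations: int = 200
    combo_max_size: int = 5
    run_explain: bool = True

    def to_yaml(self, path: str | Path) -> None:
        obj = {k: (list(v) if isinstance(v, tuple) else v) for k, v in vars(self).items()}
        Path(path).write_text(yaml.safe_dump(obj, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        obj = yaml.safe_load(Path(path).read_text())
        for key in ("hidden_sizes", "alpha"):
            if key in obj and obj[key] is not None:
                obj[key] = tuple(obj[key])
        return cls(**obj)


@dataclass
class RunManifest:
    config: dict
    seeds: dict
    outputs: dict = field(default_factory=dict)
    stage_seconds: dict = field(default_factory=dict)


def _stage(manifest: RunManifest, name: str):
    class _Timer:
        def __enter__(self):
            self.t0 = time.perf_counter()
            logger.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            manifest.stage_seconds[name] = round(time.perf_counter() - self.t0, 3)
            if exc is not None:
                logger.error("stage %s failed on %s", name, exc)
            else:
                logger.info("stage %s: done in %.2fs", name, manifest.stage_seconds[name])
            return False

    return _Timer()


def run_pipeline(config: PipelineConfig) -> RunManifest:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = {
        stage: child_seed(config.master_seed, stage)
        for stage in ("generate", "impute", "folds", "explain")
    }
    manifest = RunManifest(config=dict(vars(config)), seeds=seeds)

    with _stage(manifest, "generate"):
        if config.cohort_csv:
            if not config.cohort_meta:
                raise ValueError("cohort_csv given without cohort_meta sidecar")
            cohort = io.read_cohort(config.cohort_csv, config.cohort_meta)
        elif config.generate:
            spec = default_cohort_spec(
                n_subjects=config.n_subjects,
                missing_rate=config.missing_rate,
                seed=seeds["generate"],
            )
            cohort = generate_cohort(spec)
        else:
            raise ValueError("no cohort path configured and generation disabled")
        io.write_cohort(cohort, out / "cohort.csv", out / "cohort_meta.json")
        manifest.outputs["cohort"] = ["cohort.csv", "cohort_meta.json"]
        logger.info("cohort: %d subjects x %d variables", *cohort.X_raw.shape)

    with _stage(manifest, "preprocess"):
        X_full = prep.impute_missing(
            cohort.X_raw,
            prep.ImputeConfig(method=config.impute_method, seed=seeds["impute"]),
        )
        Z = prep.standardize(X_full)
        constant = Z.sds[Z.sds == 0].index.tolist()
        if constant:
            logger.warning("constant column(s) standardized to zeros: %s", constant)
        fm, gmap, pca_info = prep.groupwise_pca(
            Z,
            cohort.group_map,
            prep.PCAConfig(
                eigenvalue_min=config.eigenvalue_min,
                min_group_size_for_pca=config.min_group_size_for_pca,
            ),
        )
        logger.info(
            "features: %d -> %d after group-wise PCA",
            cohort.X_raw.shape[1],
            fm.values.shape[1],
        )
        fm.values.to_csv(out / "features.csv", index=False, float_format="%.17g")
        io.write_json(out / "groups_reduced.json", io.group_map_to_dict(gmap))
        io.write_json(
            out / "scaling.json",
            {"means": Z.means.to_dict(), "sds": Z.sds.to_dict()},
        )
        io.write_json(out / "pca_loadings.json", pca_info)
        labels = cohort.followup_labels
        transitions = cohort.transition_classes
        pd.DataFrame(
            {
                "moca_baseline": cohort.moca_baseline,
                "moca_followup": cohort.moca_followup,
                "baseline_label": cohort.baseline_labels,
                "followup_label": labels,
                "transition_class": transitions,
            }
        ).to_csv(out / "transitions.csv", index=False)
        manifest.outputs["preprocess"] = [
            "features.csv",
            "groups_reduced.json",
            "scaling.json",
            "pca_loadings.json",
            "transitions.csv",
        ]

    X = fm.values.to_numpy()
    Y = net.labels_to_onehot(labels)
    tc = net.TrainConfig(
        batch_size=config.batch_size,
        max_epochs=config.max_epochs,
        early_stopping_patience=config.early_stopping_patience,
        validation_fraction=config.validation_fraction,
        seed=seeds["folds"],
        threshold=config.threshold,
    )
    lc = net.FocalLossConfig(alpha=config.alpha, gamma=config.gamma)

    with _stage(manifest, "train"):
        plan = make_stratified_folds(labels, k=config.k_folds, seed=seeds["folds"])
        pd.DataFrame({"fold": plan.assignments}).to_csv(out / "folds.csv", index=False)
        fold_results = cross_validate(X, Y, plan, tc, lc, hidden_sizes=config.hidden_sizes)
        best_fold, best_params = select_best_model(fold_results)
        (out / "model.json").write_text(best_params.to_json() + "\n")
        manifest.outputs["train"] = ["folds.csv", "model.json"]
        logger.info("selected fold %d as best by Impaired recall", best_fold)

    with _stage(manifest, "evaluate"):
        pred = net.predict(best_params, X, config.threshold)
        p_imp = net.predict_proba_impaired(best_params, X)
        conf = confusion_from_predictions(labels, pred)
        metrics = metrics_from_confusion(conf)
        roc = roc_and_auc(labels, p_imp)
        # pooled held-out aggregate across folds (unbiased counterpart)
        tp = sum(r.confusion.TP for r in fold_results)
        fn = sum(r.confusion.FN for r in fold_results)
        fp = sum(r.confusion.FP for r in fold_results)
        tn = sum(r.confusion.TN for r in fold_results)
        report = {
            "best_fold": best_fold,
            "evaluation_scope": "in-sample (selected model on the entire dataset)",
            "confusion": {"TP": conf.TP, "FP": conf.FP, "TN": conf.TN, "FN": conf.FN},
            "impaired": metrics.impaired,
            "intact": metrics.intact,
            "accuracy": metrics.accuracy,
            "macro_recall": metrics.macro_recall,
            "auc": roc.auc,
            "rounded": {
                "impaired_recall": round_half_up(metrics.impaired["recall"]),
                "impaired_precision": round_half_up(metrics.impaired["precision"]),
                "accuracy": round_half_up(metrics.accuracy),
                "auc": round_half_up(roc.auc),
            },
            "held_out_pooled": {
                "confusion": {"TP": tp, "FP": fp, "TN": tn, "FN": fn},
                "impaired_recall": tp / (tp + fn) if tp + fn else None,
                "accuracy": (tp + tn) / len(labels),
            },
            "per_fold_recall": [r.impaired_recall for r in fold_results],
        }
        io.write_json(out / "metrics.json", report)
        pd.DataFrame([report["confusion"]]).to_csv(out / "confusion.csv", index=False)
        pd.DataFrame(
            {"threshold": roc.thresholds, "fpr": roc.fpr, "tpr": roc.tpr}
        ).to_csv(out / "roc.csv", index=False, float_format="%.17g")
        transition_error_table(transitions, labels, pred).to_csv(
            out / "transition_errors.csv", index=False
        )
        manifest.outputs["evaluate"] = [
            "metrics.json",
            "confusion.csv",
            "roc.csv",
            "transition_errors.csv",
        ]

    if config.run_explain:
        with _stage(manifest, "explain"):
            vf = explain.ValueFunctionConfig(
                n_permutations=config.n_permutations, seed=seeds["explain"]
            )
            shap = explain.shapley_sampling(
                best_params, X, vf, feature_names=fm.column_names
            )
            shap.phi.to_csv(out / "shap_values.csv", index=False, float_format="%.17g")
            shap.mean_abs.rename("mean_abs_shap").to_csv(
                out / "shap_mean_abs.csv", float_format="%.17g"
            )
            gm_res = explain.group_mask_delta_recall(
                best_params, X, labels, gmap, fm.column_names, config.threshold
            )
            gm_res.to_csv(out / "group_mask.csv", index=False, float_format="%.17g")
            combo = explain.combo_mask_recall(
                best_params,
                X,
                labels,
                gmap,
                max_size=config.combo_max_size,
                columns=fm.column_names,
                threshold=config.threshold,
            )
            combo.to_csv(out / "combo_mask.csv", index=False, float_format="%.17g")
            manifest.outputs["explain"] = [
                "shap_values.csv",
                "shap_mean_abs.csv",
                "group_mask.csv",
                "combo_mask.csv",
            ]

    io.write_json(
        out / "manifest.json",
        {
            "config": manifest.config,
            "seeds": manifest.seeds,
            "outputs": manifest.outputs,
            "stage_seconds": manifest.stage_seconds,
        },
    )
    for files in manifest.outputs.values():
        for f in files:
            assert (out / f).exists(), f
    return manifest
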