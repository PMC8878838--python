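"""Seeded end-to-end orchestration: simulate -> qc -> preprocess ->
univariate -> plsda -> train -> ensemble -> evaluate -> enrich.

Every stochastic stage consumes a sub-seed derived by hashing
``(master seed, stage name)``, so adding or reordering stages never
perturbs the draws of earlier ones. Every artifact is written to the run
directory together with a manifest recording stage, sub-seed and content
hash; re-running with the same config reproduces the deterministic
artifacts bit-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from metabscreen import batch_qc, diagnostics, eml, enrichment, io_prep, model_zoo, plsda, univariate
from metabscreen.io_prep import DEFAULT_TRAIN_FRACTION
from metabscreen.model_zoo import MODEL_KINDS, GaConfig
from metabscreen.simulate import CohortSpec, simulate_cohort

STAGES = (
    "simulate", "qc", "preprocess", "univariate", "plsda",
    "train", "ensemble", "evaluate", "enrich",
)


def stage_seed(master: int, stage: str) -> int:
    """Stable sub-seed for a named stage (below 2**31)."""
    digest = hashlib.sha256(f"{master}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class RunConfig:
    seed: int = 0
    cohort: CohortSpec = field(default_factory=CohortSpec)
    prevalence_min_fraction: float = 0.80
    train_fraction: float = DEFAULT_TRAIN_FRACTION
    model_kinds: tuple[str, ...] = MODEL_KINDS
    ga_enabled: bool = True
    # pipeline-scale GA budget; ga_select's own defaults are larger
    ga: GaConfig = field(default_factory=lambda: GaConfig(population=12, generations=8, folds=3))
    outer_folds: int = 5
    inner_folds: int = 3
    plsda_max_components: int = 6
    plsda_folds: int = 7
    n_permutations: int = 2000
    cutoff_mode: str = "zero"  # 'zero' | 'auto' (Youden on training scores)
    make_plots: bool = False

    def validate(self) -> None:
        unknown = set(self.model_kinds) - set(MODEL_KINDS)
        if unknown:
            raise ValueError(f"unknown model kind(s): {sorted(unknown)}")
        if self.cutoff_mode not in ("zero", "auto"):
            raise ValueError(f"unknown cutoff_mode {self.cutoff_mode!r}")
        self.cohort.validate()
        self.ga.validate()

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["model_kinds"] = list(self.model_kinds)
        d["cohort"]["log2fc_range"] = list(self.cohort.log2fc_range)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(d)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "cohort" in d:
            c = dict(d["cohort"])
            if "log2fc_range" in c:
                c["log2fc_range"] = tuple(c["log2fc_range"])
            d["cohort"] = CohortSpec(**c)
        if "ga" in d:
            d["ga"] = GaConfig(**d["ga"])
        if "model_kinds" in d:
            d["model_kinds"] = tuple(d["model_kinds"])
        return cls(**d)


def _json_default(o):
    import numpy as _np

    if isinstance(o, (_np.integer,)):
        return int(o)
    if isinstance(o, (_np.floating,)):
        return float(o)
    if isinstance(o, (_np.bool_,)):
        return bool(o)
    if isinstance(o, _np.ndarray):
        return o.tolist()
    return str(o)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class _Manifest:
    def __init__(self, outdir: Path, config: RunConfig):
        self.outdir = outdir
        self.entries: list[dict] = []
        self.config = config

    def record(self, stage: str, path: Path, seed: int | None) -> None:
        self.entries.append(
            {
                "stage": stage,
                "artifact": str(path.relative_to(self.outdir)),
                "seed": seed,
                "sha256": _sha256(path),
            }
        )

    def write(self) -> Path:
        path = self.outdir / "manifest.json"
        payload = {
            "config_sha256": _sha256(self.outdir / "config.yaml"),
            "artifacts": self.entries,
        }
        path.write_text(json.dumps(payload, indent=2, sort_keys=True))
        return path


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Run all stages in order, writing artifacts and a manifest.

    Returns a summary dict with the key quantities of each stage.
    """
    config.validate()
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    manifest = _Manifest(out, config)
    summary: dict = {}

    def fail(stage, exc):
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    # --- simulate -----------------------------------------------------
    stage = "simulate"
    try:
        seed = stage_seed(config.seed, stage)
        spec = dataclasses.replace(config.cohort, seed=seed)
        cohort = simulate_cohort(spec)
        table, meta = io_prep.table_from_cohort(cohort)
        io_prep.write_peak_table(table, out / "peaks.csv")
        meta.to_csv(out / "metadata.csv", index=False)
        cohort.truth.to_csv(out / "truth.tsv", sep="\t", index=False)
        for f in ("peaks.csv", "metadata.csv", "truth.tsv"):
            manifest.record(stage, out / f, seed)
        summary["n_study"] = len(cohort.study_ids())
        summary["n_features"] = len(cohort.feature_ids)
    except Exception as exc:  # noqa: BLE001
        fail(stage, exc)

    # --- qc -----------------------------------------------------------
    stage = "qc"
    try:
        reports = batch_qc.validate_all_batches(
            table, meta, standard_expected=cohort.standard_expected
        )
        qc_path = out / "qc_report.json"
        qc_path.write_text(
            json.dumps([batch_qc.report_to_dict(r) for r in reports], indent=2, default=_json_default)
        )
        manifest.record(stage, qc_path, None)
        summary["qc_batches_passed"] = sum(r.passed for r in reports)
        summary["qc_batches_total"] = len(reports)
    except Exception as exc:  # noqa: BLE001
        fail(stage, exc)

    # --- preprocess ----------------------------------------------------
    stage = "preprocess"
    try:
        seed = stage_seed(config.seed, stage)
        study_ids = cohort.study_ids()
        filtered = io_prep.prevalence_filter(
            table, config.prevalence_min_fraction, study_ids=study_ids
        )
        split = io_prep.split_train_test(meta, config.train_fraction, seed=seed)
        train_ids = split[split == "train"].index.tolist()
        test_ids = split[split == "test"].index.tolist()
        study_table = filtered.subset(samples=study_ids)
        fm, scaler = io_prep.normalize_transform(
            study_table, fit_ids=train_ids, transform_ids=study_ids
        )
        fm.split = split.loc[study_ids]
        fm.values.to_csv(out / "feature_matrix.csv")
        split.rename_axis("sample_id").to_csv(out / "split.csv")
        manifest.record(stage, out / "feature_matrix.csv", seed)
        manifest.record(stage, out / "split.csv", seed)
        labels = io_prep.pool_controls(meta.set_index("sample_id")["group"]).loc[study_ids]
        summary["n_features_retained"] = len(fm.feature_ids)
        summary["n_train"], summary["n_test"] = len(train_ids), len(test_ids)
    except Exception as exc:  # noqa: BLE001
        fail(stage, exc)

    # --- univariate ----------------------------------------------------
    stage = "univariate"
    try:
        ratios = study_table.normalized()
        vol = univariate.volcano(ratios, labels)
        vol.to_csv(out / "volcano.tsv", sep="\t")
        manifest.record(stage, out / "volcano.tsv", None)
        summary["volcano_significant"] = int(vol["significant"].sum())
    except Exception as exc:  # noqa: BLE001
        fail(stage, exc)

    X_train = fm.values.loc[train_ids]
    X_test = fm.values.loc[test_ids]
    y_train = labels.loc[train_ids]
    y_test = labels.loc[test_ids]

    # --- plsda ----------------------------------------------------------
    stage = "plsda"
    try:
        seed = stage_seed(config.seed, stage)
        best_n, acc_by_n = plsda.select_components(
            X_train, y_train, max_c=config.plsda_max_components,
            folds=config.plsda_folds, seed=seed,
        )
        model = plsda.PLSDAClassifier(n_components=best_n).fit(X_train, y_train)
        q2 = plsda.q2_score(X_train, y_train, best_n, folds=config.plsda_folds, seed=seed)
        p_perm, obs_acc, _ = plsda.permutation_test(
            X_train, y_train, n_perm=config.n_permutations, seed=seed,
            n_components=best_n, folds=config.plsda_folds,
        )
        vip = pd.Series(model.vip_, index=fm.feature_ids, name="vip")
        payload = {
            "n_components": best_n,
            "cv_accuracy_by_n": acc_by_n.to_dict(),
            "r2": model.r2_,
            "q2": q2,
            "permutation_p": p_perm,
            "observed_cv_accuracy": obs_acc,
            "vip_gt_2": vip[vip > 2.0].sort_values(ascending=False).to_dict(),
        }
        (out / "plsda.json").write_text(json.dumps(payload, indent=2, default=_json_default))
        manifest.record(stage, out / "plsda.json", seed)
        summary.update(
            plsda_n_components=best_n, plsda_r2=model.r2_, plsda_q2=q2,
            plsda_permutation_p=p_perm, plsda_n_vip_gt_2=int((vip > 2.0).sum()),
        )
    except Exception as exc:  # noqa: BLE001
        fail(stage, exc)

    # --- train -----------------------------------------------------------
    stage = "train"
    try:
        seed = stage_seed(config.seed, stage)
        screened = model_zoo.prescreen_features(X_train, y_train)
        models = []
        model_dir = out / "models"
        model_dir.mkdir(exist_ok=True)
        for kind in config.model_kinds:
            ga_cfg = (
                dataclasses.replace(config.ga, seed=stage_seed(seed, f"ga:{kind}"))
                if config.ga_enabled
                else None
            )
            tm = model_zoo.train_model(
                kind, X_train[screened], y_train, ga=ga_cfg,
                outer_folds=config.outer_folds, inner_folds=config.inner_folds,
                seed=stage_seed(seed, f"fit:{kind}"),
            )
            tm.predict_samples(X_test)
            mpath = model_dir / f"{kind}.json"
            mpath.write_text(json.dumps(tm.to_dict(), indent=2, default=_json_default))
            manifest.record(stage, mpath, seed)
            models.append(tm)
        relevant = {
            m.kind: set(model_zoo.feature_weight_elbow(m.feature_weights))
            for m in models
        }
        inter = model_zoo.upset_intersections(relevant)
        inter[inter > 0].rename_axis("models").to_csv(out / "upset_counts.csv")
        manifest.record(stage, out / "upset_counts.csv", seed)
        summary["cv_accuracy"] = {m.kind: m.cv_accuracy for m in models}
    except Exception as exc:  # noqa: BLE001
        fail(stage, exc)

    # --- ensemble ---------------------------------------------------------
    stage = "ensemble"
    try:
        if config.cutoff_mode == "auto":
            train_preds = [
                dataclasses.replace(
                    m, predictions=None, estimator=m.estimator
                )
                for m in models
            ]
            for m in train_preds:
                m.predict_samples(X_train)
            train_scores = eml.eml_scores(train_preds)["eml_score"]
            cutoff = eml.optimize_cutoff(train_scores, y_train)
            for m, orig in zip(train_preds, models):
                m.predictions = None
        else:
            cutoff = 0.0
        for m in models:
            m.predict_samples(X_test)
        result = eml.classify(models, cutoff=cutoff)
        ens = pd.DataFrame(
            {
                "eml_score": result.scores,
                "predicted": result.predicted,
                "confidence": result.confidence,
                "true": y_test,
            }
        )
        ens.to_csv(out / "eml_scores.csv")
        manifest.record(stage, out / "eml_scores.csv", None)
        summary["eml_cutoff"] = cutoff
    except Exception as exc:  # noqa: BLE001
        fail(stage, exc)

    # --- evaluate ----------------------------------------------------------
    stage = "evaluate"
    try:
        rows = {}
        for m in models:
            cm = diagnostics.ConfusionMatrix.from_predictions(
                y_test, m.predictions["class"]
            )
            rows[m.kind] = diagnostics.diagnostic_report(cm).to_dict()
        cm_e = diagnostics.ConfusionMatrix.from_predictions(y_test, result.predicted)
        rows["EML"] = diagnostics.diagnostic_report(cm_e).to_dict()
        roc_df, auc = diagnostics.roc_curve(result.scores, y_test)
        roc_df.to_csv(out / "roc_ensemble.csv", index=False)
        report = pd.DataFrame(rows).T.rename_axis("model")
        report.to_csv(out / "diagnostics.tsv", sep="\t")
        manifest.record(stage, out / "diagnostics.tsv", None)
        manifest.record(stage, out / "roc_ensemble.csv", None)
        summary["eml_test_accuracy"] = rows["EML"]["accuracy"]
        summary["eml_auc"] = auc
        best_kind = max(models, key=lambda m: m.cv_accuracy).kind
        best = next(m for m in models if m.kind == best_kind)
        pos = np.asarray(best.estimator.classes_).tolist().index("CRC")
        best_scores = best.estimator.predict_proba(
            np.asarray(X_test[best.features], dtype=float)
        )[:, pos]
        summary["delong_eml_vs_best"] = diagnostics.delong_compare(
            result.scores, best_scores, y_test
        )
    except Exception as exc:  # noqa: BLE001
        fail(stage, exc)

    # --- enrich -------------------------------------------------------------
    stage = "enrich"
    try:
        db = enrichment.load_toy_pathway_db()
        universe = set(fm.feature_ids) & db.all_members()
        hit_list = set().union(*relevant.values()) & universe
        if hit_list:
            enr = enrichment.enrich(hit_list, db, universe)
            enr.to_csv(out / "enrichment.tsv", sep="\t", index=False)
            manifest.record(stage, out / "enrichment.tsv", None)
            summary["enrichment_top_pathway"] = enr.iloc[0]["pathway_id"]
            summary["enrichment_min_q"] = float(enr["fdr_q"].min())
        else:
            summary["enrichment_top_pathway"] = None
    except Exception as exc:  # noqa: BLE001
        fail(stage, exc)

    if config.make_plots:
        from metabscreen import viz

        viz.export_all(out, fm, labels, vol, model, result, y_test, roc_df, auc)

    manifest.write()
    (out / "summary.json").write_text(json.dumps(summary, indent=2, default=_json_default))
    return summary
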