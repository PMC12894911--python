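"""End-to-end runs: simulate -> preprocess -> [harmonize] -> train ->
evaluate -> pseudotime -> learning-curve, driven by one declarative
configuration, with a manifest recording every resolved parameter.

Stages communicate through files inside the run directory, so any
subset of stages can be re-run later against an existing directory, and
every output is re-derivable from the manifest alone.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import attention_net, harmonization, models_eval, pseudotime, synthetic
from .preprocessing import preprocess_table, split_dataset
from .tables import FeatureTable, NormalizationParams

logger = logging.getLogger(__name__)

STAGE_ORDER = (
    "simulate",
    "preprocess",
    "harmonize",
    "train",
    "evaluate",
    "pseudotime",
    "learning_curve",
)


class PipelineConfigError(ValueError):
    pass


class PipelineStateError(RuntimeError):
    pass


def _check_keys(d: dict, allowed, where: str) -> None:
    unknown = set(d) - set(allowed)
    if unknown:
        raise PipelineConfigError(
            f"unknown key(s) {sorted(unknown)} in {where}; allowed: {sorted(allowed)}"
        )


@dataclass
class RunConfig:
    """Resolved parameters for one pipeline run."""

    out_dir: str = "pmikit_run"
    stages: tuple[str, ...] = STAGE_ORDER
    seed: int = 0
    input_dir: str | None = None  # read a cohort instead of simulating
    cohort: dict = field(default_factory=dict)  # SynthConfig overrides
    proportions: tuple[float, float, float] = (0.8, 0.1, 0.1)
    leakage_safe: bool = False  # fit normalization on train split only
    harmonize: dict = field(
        default_factory=lambda: {
            "mz_jitter_ppm": 2.0,
            "rt_jitter": 10.0,
            "frac_exclusive": 0.3,
            "mz_window": 5.0,
            "rt_window": 30.0,
        }
    )
    model: dict = field(
        default_factory=lambda: {
            "search": False,
            "n_configs": 10,
            "repeats": 2,
            "patience": 25,
            "max_epochs": 300,
        }
    )
    pmi_range: tuple[int, int] = (1, 13)
    pseudotime: dict = field(
        default_factory=lambda: {
            "alpha": 0.05,
            "k": 3,
            "tau": 0.6,
            "min_count": 5,
            "source": "activations",
        }
    )
    learning_curve: dict = field(
        default_factory=lambda: {
            "sizes": [16, 32, 64, 128, 256, 512, 1024],
            "reps": 25,
            "cv_folds": 5,
        }
    )

    def __post_init__(self) -> None:
        for s in self.stages:
            if s not in STAGE_ORDER:
                raise PipelineConfigError(f"unknown stage {s!r}")
        self.stages = tuple(s for s in STAGE_ORDER if s in self.stages)
        _check_keys(
            self.harmonize,
            ("mz_jitter_ppm", "rt_jitter", "frac_exclusive", "mz_window", "rt_window"),
            "harmonize",
        )
        _check_keys(
            self.model,
            ("search", "n_configs", "repeats", "patience", "max_epochs", "hyperparams"),
            "model",
        )
        _check_keys(
            self.pseudotime, ("alpha", "k", "tau", "min_count", "source"), "pseudotime"
        )
        _check_keys(self.learning_curve, ("sizes", "reps", "cv_folds"), "learning_curve")
        allowed_cohort = {f.name for f in dataclasses.fields(synthetic.SynthConfig)}
        _check_keys(self.cohort, allowed_cohort, "cohort")

    @classmethod
    def from_dict(cls, doc: dict) -> "RunConfig":
        allowed = {f.name for f in dataclasses.fields(cls)}
        _check_keys(doc, allowed, "run config")
        doc = dict(doc)
        for key in ("stages", "proportions", "pmi_range"):
            if key in doc:
                doc[key] = tuple(doc[key])
        return cls(**doc)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_manifest(self) -> dict:
        doc = dataclasses.asdict(self)
        doc["stages"] = list(self.stages)
        return doc


class PipelineRun:
    """Executes stages in order inside one run directory."""

    def __init__(self, config: RunConfig) -> None:
        self.config = config
        self.out = Path(config.out_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.manifest: dict = {"config": config.to_manifest(), "stages": {}}
        # in-memory state, lazily reloaded from disk when absent
        self._raw: FeatureTable | None = None
        self._truth: synthetic.GroundTruth | None = None
        self._std: FeatureTable | None = None
        self._params: NormalizationParams | None = None
        self._split = None
        self._model: attention_net.PMIRegressor | None = None

    # -- state accessors -------------------------------------------------
    def _cohort_config(self) -> synthetic.SynthConfig:
        overrides = dict(self.config.cohort)
        overrides.setdefault("seed", self.config.seed)
        return synthetic.SynthConfig(**overrides)

    def raw_table(self) -> FeatureTable:
        if self._raw is None:
            path = self.out / "cohort"
            if not (path / "intensities.csv").exists():
                raise PipelineStateError(
                    "no cohort available; run the simulate stage or set input_dir"
                )
            self._raw = FeatureTable.read(path)
        return self._raw

    def standardized(self) -> FeatureTable:
        if self._std is None:
            path = self.out / "standardized"
            if not (path / "intensities.csv").exists():
                raise PipelineStateError("run the preprocess stage first")
            self._std = FeatureTable.read(path)
            self._params = NormalizationParams.from_json(
                self.out / "normalization.json"
            )
            labels = pd.read_csv(self.out / "split.csv", index_col="sample_id")[
                "split"
            ]
            labels.index = labels.index.astype(str)
            from .preprocessing import SplitAssignment

            self._split = SplitAssignment(
                labels=labels,
                proportions=self.config.proportions,
                seed=self.config.seed,
            )
        return self._std

    def model(self) -> attention_net.PMIRegressor:
        if self._model is None:
            path = self.out / "model"
            if not (path / "architecture.json").exists():
                raise PipelineStateError("run the train stage first")
            self._model = attention_net.PMIRegressor.load(path)
        return self._model

    def _split_tables(self):
        std = self.standardized()
        return {
            name: std.subset_samples(self._split.mask(name))
            for name in ("train", "validation", "test")
        }

    # -- stages ----------------------------------------------------------
    def stage_simulate(self) -> None:
        cfg = self._cohort_config()
        table, truth = synthetic.generate_cohort(cfg)
        table.write(self.out / "cohort")
        truth.write(self.out / "ground_truth.csv")
        self._raw, self._truth = table, truth
        self.manifest["stages"]["simulate"] = {
            "config": dataclasses.asdict(cfg),
            "shape": [table.n_samples, table.n_features],
        }
        logger.info(
            "simulate: %d samples x %d features", table.n_samples, table.n_features
        )

    def stage_preprocess(self) -> None:
        if self.config.input_dir and self._raw is None:
            self._raw = FeatureTable.read(self.config.input_dir)
        raw = self.raw_table()
        split = split_dataset(raw, self.config.proportions, seed=self.config.seed)
        if self.config.leakage_safe:
            train_raw = raw.subset_samples(split.mask("train"))
            _, params, _ = preprocess_table(train_raw)
            std, _, n_imp = preprocess_table(raw, params=params)
        else:
            std, params, n_imp = preprocess_table(raw)
        std.write(self.out / "standardized")
        params.to_json(self.out / "normalization.json")
        split.labels.rename_axis("sample_id").to_csv(self.out / "split.csv")
        self._std, self._params, self._split = std, params, split
        self.manifest["stages"]["preprocess"] = {
            "n_imputed": n_imp,
            "leakage_safe": self.config.leakage_safe,
            "split_counts": split.counts(),
            "ddof": params.ddof,
            "shape": [std.n_samples, std.n_features],
        }
        logger.info("preprocess: split counts %s", split.counts())

    def stage_harmonize(self) -> None:
        h = self.config.harmonize
        cfg = self._cohort_config()
        ref, new, matching = synthetic.generate_platform_pair(
            cfg,
            mz_jitter_ppm=h["mz_jitter_ppm"],
            rt_jitter=h["rt_jitter"],
            frac_exclusive=h["frac_exclusive"],
        )
        tol = harmonization.MatchTolerance(
            mz_window=h["mz_window"], rt_window=h["rt_window"]
        )
        hmap = harmonization.match_features(
            harmonization.FeatureCatalog.from_table(ref),
            harmonization.FeatureCatalog.from_table(new),
            tol,
        )
        hmap.to_csv(self.out / "harmonization_map.csv")
        new.write(self.out / "platform_b")
        report = harmonization.overlap_report(
            hmap, harmonization.FeatureCatalog.from_table(new)
        )
        truth_pairs = matching.pairs
        agreement = sum(
            (pd.isna(hmap.pairs.at[r, "new_feature_id"]) and truth_pairs[r] is None)
            or hmap.pairs.at[r, "new_feature_id"] == truth_pairs[r]
            for r in truth_pairs
        ) / len(truth_pairs)
        self.manifest["stages"]["harmonize"] = {
            **report,
            "planted_agreement": agreement,
            "shape": [new.n_samples, new.n_features],
        }
        logger.info("harmonize: %s (agreement %.3f)", report, agreement)

    def stage_train(self) -> None:
        tables = self._split_tables()
        mc = self.config.model
        patience = mc.get("patience", 25)
        max_epochs = mc.get("max_epochs", 300)
        if mc.get("search"):
            result = attention_net.hyperparameter_search(
                tables["train"],
                tables["validation"],
                n_configs=mc.get("n_configs", 10),
                repeats=mc.get("repeats", 2),
                seed=self.config.seed,
                patience=patience,
                max_epochs=max_epochs,
            )
            hp = dataclasses.replace(result.best().hp, seed=self.config.seed)
            search_summary = [
                {
                    "use_attention": e.hp.use_attention,
                    "n_hidden_layers": e.hp.n_hidden_layers,
                    "nodes_per_layer": list(e.hp.nodes_per_layer),
                    "val_mae": e.score,
                }
                for e in result.entries
            ]
        else:
            hp_kwargs = dict(mc.get("hyperparams") or {})
            hp_kwargs.setdefault("seed", self.config.seed)
            if "nodes_per_layer" in hp_kwargs:
                hp_kwargs["nodes_per_layer"] = tuple(hp_kwargs["nodes_per_layer"])
            if "dropout_per_layer" in hp_kwargs:
                hp_kwargs["dropout_per_layer"] = tuple(hp_kwargs["dropout_per_layer"])
            hp = attention_net.HyperParams(**hp_kwargs)
            search_summary = None
        model = attention_net.build_model(hp, tables["train"].n_features)
        attention_net.train(
            model,
            tables["train"],
            tables["validation"],
            patience=patience,
            max_epochs=max_epochs,
        )
        model.normalization = self._params
        model.save(self.out / "model")
        self._model = model
        self.manifest["stages"]["train"] = {
            "hyperparams": dataclasses.asdict(hp),
            "best_epoch": model.best_epoch,
            "stopped_epoch": model.stopped_epoch,
            "best_val_loss": model.best_val_loss,
            "search": search_summary,
            "shape": [tables["train"].n_samples, tables["train"].n_features],
        }
        logger.info(
            "train: best epoch %d, val loss %.4f", model.best_epoch, model.best_val_loss
        )

    def stage_evaluate(self) -> None:
        tables = self._split_tables()
        model = self.model()
        test = tables["test"]
        preds = attention_net.predict(model, test)
        truth = test.pmi.astype(float)
        report = models_eval.evaluate(preds, truth, pmi_range=self.config.pmi_range)
        report_all = models_eval.evaluate(preds, truth)
        baseline = float(
            np.mean(np.abs(truth - np.median(tables["train"].pmi)))
        )
        doc = {
            "ffnn": report.to_dict(),
            "ffnn_full_range": report_all.to_dict(),
            "constant_median_mae": baseline,
            "pmi_range": list(self.config.pmi_range),
        }
        try:
            doc["day_one_bias"] = models_eval.day_one_bias(preds, truth)
        except models_eval.EvaluationError:
            doc["day_one_bias"] = None
        (self.out / "evaluation.json").write_text(json.dumps(doc, indent=2))
        report.per_pmi_quantiles.to_csv(self.out / "per_pmi_quantiles.csv")
        self.manifest["stages"]["evaluate"] = {
            "test_mae": report.mae,
            "test_median_ae": report.median_ae,
            "test_r2": report.r2,
            "constant_median_mae": baseline,
            "shape": [test.n_samples, test.n_features],
        }
        logger.info(
            "evaluate: MAE %.3f / median %.3f / R2 %.3f (constant-median MAE %.3f)",
            report.mae,
            report.median_ae,
            report.r2,
            baseline,
        )

    def stage_pseudotime(self) -> None:
        tables = self._split_tables()
        std = self.standardized()
        pc = self.config.pseudotime
        pmi = std.pmi
        if pc["source"] == "activations":
            model = self.model()
            matrix = attention_net.attention_activations(model, std)
        elif pc["source"] == "abundances":
            matrix = std.values()
        else:
            raise PipelineConfigError(
                f"pseudotime source must be 'activations' or 'abundances', got {pc['source']!r}"
            )
        screen = pseudotime.spearman_screen(
            matrix, pmi, alpha=pc["alpha"], feature_ids=std.feature_ids
        )
        screen.to_csv(self.out / "feature_screen.csv")
        pts = pseudotime.build_pseudotime(
            std,
            screen.selected_ids,
            pmi_filter=self.config.pmi_range,
            min_count=pc["min_count"],
        )
        pts.to_csv(self.out / "pseudotime_series.csv")
        clusters = pseudotime.cluster_trajectories(pts, k=pc["k"])
        clusters = pseudotime.label_trends(clusters, pts, tau=pc["tau"])
        pd.DataFrame(
            {
                "cluster": clusters.assignments,
                "trend": clusters.feature_labels(),
            }
        ).rename_axis("feature_id").to_csv(self.out / "trend_clusters.csv")
        (self.out / "dendrogram.nwk").write_text(clusters.to_newick())
        sizes = {
            clusters.labels[cid]: int(n)
            for cid, n in clusters.cluster_sizes().items()
        }
        self.manifest["stages"]["pseudotime"] = {
            "n_selected": screen.n_selected(),
            "cluster_sizes": sizes,
            "alpha": pc["alpha"],
            "shape": [matrix.shape[0], matrix.shape[1]],
        }
        logger.info(
            "pseudotime: %d features selected; cluster sizes %s",
            screen.n_selected(),
            sizes,
        )

    def stage_learning_curve(self) -> None:
        tables = self._split_tables()
        lc = self.config.learning_curve
        sizes = [s for s in lc["sizes"] if s <= tables["train"].n_samples]
        result = models_eval.run_learning_curve(
            tables["train"].values(),
            tables["train"].pmi.astype(float),
            tables["test"].values(),
            tables["test"].pmi.astype(float),
            sizes=sizes,
            reps=lc["reps"],
            cv_folds=lc["cv_folds"],
            seed=self.config.seed,
        )
        result.to_frame().to_csv(self.out / "learning_curve.csv")
        self.manifest["stages"]["learning_curve"] = {
            "sizes": result.sizes,
            "reps": lc["reps"],
            "mean_mae": result.mean.tolist(),
        }
        logger.info("learning curve: mean MAE %s", np.round(result.mean, 3).tolist())

    # -- driver ----------------------------------------------------------
    def run(self) -> Path:
        handler = logging.FileHandler(self.out / "run.log")
        handler.setFormatter(
            logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s")
        )
        root = logging.getLogger("pmikit")
        root.addHandler(handler)
        try:
            for stage in self.config.stages:
                getattr(self, f"stage_{stage}")()
                (self.out / "manifest.json").write_text(
                    json.dumps(self.manifest, indent=2)
                )
        finally:
            root.removeHandler(handler)
            handler.close()
        return self.out


def run_pipeline(config: RunConfig) -> Path:
    """Execute the configured stages; returns the run directory."""
    return PipelineRun(config).run()
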