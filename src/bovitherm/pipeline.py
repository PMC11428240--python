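"""End-to-end orchestration: generate -> preprocess -> features ->
benchmark -> tune -> explain, with config, logging and provenance.

A run is reproducible from its config alone.  One global seed fans out to
per-stage seeds through a stable hash of the stage name, so stages draw
from isolated streams while the user controls a single knob.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, bench, explain, featuresets, gwo, preprocess, synthetic, thermal

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "stage_seed", "run_pipeline"]

STAGES = ("generate", "preprocess", "features", "bench", "tune", "explain")


def stage_seed(seed: int, stage: str) -> int:
    """Derive a per-stage seed from the global seed (CRC32 of the stage name)."""
    return (int(seed) * 1_000_003 + zlib.crc32(stage.encode())) % (2**31 - 1)


@dataclass
class RunConfig:
    """Fully serializable configuration of one pipeline run."""

    seed: int = 0
    out_dir: str = "runs/run0"
    generator: dict = field(default_factory=dict)     # GeneratorConfig overrides
    groups: tuple[str, ...] = featuresets.GROUPS      # registry group selection
    families: tuple[str, ...] = bench.FAMILIES
    split: dict = field(default_factory=dict)         # SplitConfig overrides
    tune_family: str = "XGBoost"
    tune_feature_set: str = "IRTave_TK"
    gwo_population: int = 30
    gwo_epochs: int = 200
    explain_max_rows: int = 500
    zscore_threshold: float = 3.0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["groups"] = list(self.groups)
        d["families"] = list(self.families)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        for key in ("groups", "families"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (tuple, np.ndarray)):
        return list(obj)
    raise TypeError(f"not serializable: {type(obj)}")


def run_pipeline(config: RunConfig) -> Path:
    """Execute all stages; return the run directory.

    Emits cohort CSVs, the preprocessing report, the feature-set registry,
    benchmark results, tuned-model artifacts, SHAP tables, and a manifest
    recording seeds and versions.  A stage failure aborts with the stage
    name after persisting the manifest and any partial outputs.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "seed": config.seed,
        "stage_seeds": {s: stage_seed(config.seed, s) for s in STAGES},
        "config": config.to_dict(),
        "stages_completed": [],
    }

    def persist_manifest():
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=_json_default)

    stage = "generate"
    try:
        gen_cfg = synthetic.GeneratorConfig(
            seed=stage_seed(config.seed, "generate"), **config.generator
        )
        table, truth = synthetic.gen_cohort(gen_cfg)
        synthetic.write_cohort(table, out / "cohort.csv", gen_cfg)
        truth.to_csv(out / "cohort_truth.csv", index=False)
        manifest["n_rows"] = len(table)
        manifest["stages_completed"].append(stage)

        stage = "preprocess"
        processed, report = preprocess.preprocess_table(
            table, threshold=config.zscore_threshold
        )
        report.to_json(out / "preprocess_report.json")
        manifest["stages_completed"].append(stage)

        stage = "features"
        featured = thermal.compute_features(processed)
        featured.to_csv(out / "processed_features.csv", index=False)
        registry = featuresets.build_registry(groups=config.groups)
        featuresets.registry_to_json(registry, out / "registry.json")
        manifest["registry_size"] = len(registry)
        manifest["stages_completed"].append(stage)

        stage = "bench"
        split_cfg = bench.SplitConfig(
            seed=stage_seed(config.seed, "bench"), **config.split
        )
        results = bench.benchmark(registry, featured, config.families, split_cfg)
        results.to_csv(out / "benchmark_results.csv", index=False)
        bench.aggregate_by_set(results).to_csv(out / "benchmark_by_set.csv", index=False)
        manifest["stages_completed"].append(stage)

        stage = "tune"
        spec = next(s for s in registry if s.name == config.tune_feature_set)
        gwo_cfg = gwo.GwoConfig(
            population=config.gwo_population, epochs=config.gwo_epochs,
            seed=stage_seed(config.seed, "tune"),
        )
        tune_split = bench.SplitConfig(seed=stage_seed(config.seed, "bench"), **config.split)
        result = gwo.tune(config.tune_family, spec, featured, gwo_cfg, tune_split)
        with open(out / "tuned_model.json", "w") as fh:
            json.dump(dataclasses.asdict(result), fh, indent=2, default=_json_default)
        manifest["stages_completed"].append(stage)

        stage = "explain"
        X, y = featuresets.materialize(featured, spec)
        X_tr, X_te, y_tr, y_te = bench.split_train_test(X, y, tune_split)
        model = bench.build_estimator(
            config.tune_family, result.best_params, seed=tune_split.seed
        )
        model.fit(X_tr.to_numpy(float), y_tr)
        r2, mae, rmse = bench.metrics(y_te, model.predict(X_te.to_numpy(float)))
        manifest["tuned_test_metrics"] = {"r2": r2, "mae": mae, "rmse": rmse}
        X_explain = X_te.iloc[: config.explain_max_rows]
        shap = explain.explain(model, X_explain)
        pd.DataFrame(shap.values, columns=shap.feature_names).to_csv(
            out / "shap_values.csv", index=False
        )
        explain.summary_stats(shap).to_csv(out / "shap_summary.csv", index=False)
        explain.waterfall_data(shap, 0).to_csv(out / "shap_waterfall_row0.csv", index=False)
        manifest["shap_base_value"] = shap.base_value
        manifest["stages_completed"].append(stage)
    except Exception as err:
        manifest["failed_stage"] = stage
        manifest["error"] = str(err)
        persist_manifest()
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {err}") from err

    persist_manifest()
    return out
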