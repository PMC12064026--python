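"""Stage orchestration: synth -> extract -> cluster-eval / classify-eval / benchmark.

Each stage reads its prerequisites from ``config.out_dir``, fails with an
actionable message when they are missing, and writes outputs stamped with the
config hash and seed. Outputs are pure functions of the config, so a rerun
with an identical config overwrites byte-identically.
"""

from __future__ import annotations

import json
import sys
from pathlib import Path

import numpy as np
import pandas as pd

from . import benchmark as bench
from . import cluster as clu
from . import supervised as sup
from .embeddings import EmbeddingMatrix, extract
from .indices import IndexConfig
from .manifest import RunConfig, load_manifest
from .simulate import DatasetSpec, FrequencyResponse, RecorderSpec, SceneParams, \
    SiteSpec, generate_dataset, random_tilt_filter

STAGES = ("synth", "extract", "cluster-eval", "classify-eval", "benchmark")


def log_event(stage: str, **fields) -> None:
    """Line-delimited JSON log to stderr."""
    print(json.dumps({"stage": stage, **fields}, default=str), file=sys.stderr)


def _stamp(config: RunConfig) -> dict:
    return {"config_hash": config.config_hash(), "seed": config.seed}


def dataset_spec_from_dict(raw: dict) -> DatasetSpec:
    """Build a DatasetSpec from a plain (YAML/JSON) dictionary."""
    sites = tuple(
        SiteSpec(
            s["site_id"], s["habitat_class"],
            random_tilt_filter(s["filter_seed"]) if "filter_seed" in s else None,
        )
        for s in raw["sites"]
    )
    recorders = tuple(
        RecorderSpec(
            r["recorder_id"],
            random_tilt_filter(r["filter_seed"]) if "filter_seed" in r else None,
        )
        for r in raw["recorders"]
    )
    base = SceneParams(**{k: tuple(v) if k == "chorus_tone_set" else v
                          for k, v in raw.get("base_scene", {}).items()})
    return DatasetSpec(
        dataset_id=raw["dataset_id"],
        sites=sites,
        recorders=recorders,
        minutes_per_site=raw.get("minutes_per_site", 10),
        n_days=raw.get("n_days", 2),
        base_scene=base,
        class_params=raw.get("class_params", {}),
        start_date=raw.get("start_date", "2024-01-01"),
        seed=raw.get("seed", 0),
    )


def _require(path: Path, hint: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(
            f"missing prerequisite {path}; run the '{hint}' stage first"
        )
    return path


def run_pipeline(config: RunConfig, stage: str, dataset_spec: DatasetSpec | None = None,
                 task: str = "habitat_class") -> dict:
    """Run one pipeline stage and return the paths of the artifacts written."""
    if stage not in STAGES:
        raise ValueError(f"unknown stage {stage!r}; expected one of {STAGES}")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict = {}

    if stage == "synth":
        if dataset_spec is None:
            raise ValueError("synth stage requires a dataset spec")
        manifest = generate_dataset(dataset_spec, out)
        artifacts["manifest"] = str(out / "manifest.csv")
        log_event(stage, n_minutes=len(manifest), **_stamp(config))
        return artifacts

    manifest = load_manifest(_require(Path(config.manifest), "synth"))
    emb_path = out / f"embeddings_{config.extractor}.csv"

    if stage == "extract":
        kwargs = {}
        if config.extractor == "compound_index":
            kwargs["config"] = IndexConfig.preset(config.index_preset)
        em = extract(manifest, config.extractor, **kwargs)
        em.save(emb_path)
        artifacts["embeddings"] = str(emb_path)
        log_event(stage, n=em.n, d=em.d, **_stamp(config))
        return artifacts

    em = EmbeddingMatrix.load(_require(emb_path, "extract"))
    labels = dict(zip(manifest["file"], manifest[task]))

    if stage == "cluster-eval":
        reduced = clu.reduce_dims(em, d=config.reduce_dim,
                                  method=config.reduce_method, seed=config.seed)
        ap = clu.AffinityPropagation(damping=config.damping).fit(reduced.vectors)
        result = ap.result(reduced.row_keys)
        classes = [labels[k] for k in result.row_keys]
        fidelity = clu.chi_square(clu.contingency(result.assignments, classes))
        pd.DataFrame({"file": result.row_keys, "cluster": result.assignments}).to_csv(
            out / "clusters.csv", index=False
        )
        report = {
            "chi2": fidelity.chi2,
            "df": fidelity.df,
            "p": fidelity.p,
            "n_clusters": result.n_clusters,
            "converged": result.converged,
            "table": fidelity.table.to_dict(),
            **_stamp(config),
        }
        (out / "cluster_report.json").write_text(json.dumps(report, indent=2, default=str))
        artifacts["clusters"] = str(out / "clusters.csv")
        artifacts["report"] = str(out / "cluster_report.json")
        log_event(stage, chi2=fidelity.chi2, n_clusters=result.n_clusters,
                  **_stamp(config))
        return artifacts

    if stage == "classify-eval":
        plans = sup.make_blocked_splits(
            manifest, block_by=config.block_by, train_frac=config.train_frac,
            repeats=config.repeats, seed=config.seed,
        )
        from sklearn.ensemble import RandomForestClassifier

        records = [
            sup.run_classification(
                em, labels, plan,
                classifier=RandomForestClassifier(n_estimators=config.n_estimators),
                n_models=config.n_models, seed=config.seed + 1000 * i, split_index=i,
            )
            for i, plan in enumerate(plans)
        ]
        rows = pd.DataFrame(
            {
                "split_index": [r.split_index for r in records],
                "method": [r.method_id for r in records],
                "validation_accuracy": [r.validation_accuracy for r in records],
                "test_accuracy": [r.test_accuracy for r in records],
                "train_fraction": [r.train_fraction for r in records],
                "flags": [";".join(r.flags) for r in records],
            }
        )
        rows.to_csv(out / "eval_records.csv", index=False)
        summary = sup.summarize_records(records)
        confusions = {str(r.split_index): r.confusion.to_dict() for r in records}
        report = {
            "summary": summary.to_dict(),
            "random_baseline": sup.random_baseline(len(set(labels.values()))),
            "n_plans": len(plans),
            "confusions": confusions,
            **_stamp(config),
        }
        (out / "eval_report.json").write_text(json.dumps(report, indent=2, default=str))
        artifacts["records"] = str(out / "eval_records.csv")
        artifacts["report"] = str(out / "eval_report.json")
        log_event(stage, n_plans=len(plans),
                  mean_accuracy=float(rows["test_accuracy"].mean()), **_stamp(config))
        return artifacts

    # benchmark
    if em.extractor_id != "compound_index":
        raise ValueError("single-index benchmark requires compound_index embeddings")
    features = em.to_frame()
    classes = pd.Series([labels[k] for k in em.row_keys], index=features.index)
    report_obj = bench.benchmark_indices(features, classes)
    long_rows = features.reset_index(names="file").melt(
        id_vars="file", var_name="index", value_name="value"
    )
    long_rows["habitat_class"] = long_rows["file"].map(labels)
    long_rows.to_csv(out / "benchmark_long.csv", index=False)
    report = {
        "selected_index": report_obj.selected_index,
        "unambiguous_proportion": report_obj.unambiguous_proportion,
        "per_index": report_obj.per_index.reset_index().to_dict(orient="records"),
        **_stamp(config),
    }
    (out / "benchmark_report.json").write_text(json.dumps(report, indent=2, default=str))
    artifacts["long"] = str(out / "benchmark_long.csv")
    artifacts["report"] = str(out / "benchmark_report.json")
    log_event(stage, selected_index=report_obj.selected_index,
              unambiguous_proportion=report_obj.unambiguous_proportion,
              **_stamp(config))
    return artifacts
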