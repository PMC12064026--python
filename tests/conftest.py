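"""Shared synthetic datasets, rendered once per session."""

from __future__ import annotations

import numpy as np
import pytest

from reefscape.embeddings import extract
from reefscape.manifest import load_manifest
from reefscape.simulate import (
    DatasetSpec,
    RecorderSpec,
    SiteSpec,
    generate_dataset,
    random_tilt_filter,
)

#: strongly divergent habitat classes: a high-activity reef (dense snapping,
#: frequent choruses) versus a quiet one
SEPARABLE_CLASS_PARAMS = {
    "high": {"snap_rate": 60.0, "chorus_rate": 4.0},
    "low": {"snap_rate": 10.0, "chorus_rate": 1.0},
}


def make_dataset_spec(
    dataset_id: str,
    n_sites: int,
    minutes_per_site: int,
    class_params: dict,
    seed: int,
    n_recorders: int = 3,
) -> DatasetSpec:
    half = n_sites // 2
    sites = tuple(
        SiteSpec(
            f"S{i:02d}",
            "high" if i < half else "low",
            random_tilt_filter(100 + i),
        )
        for i in range(n_sites)
    )
    recorders = tuple(
        RecorderSpec(f"R{j}", random_tilt_filter(200 + j)) for j in range(n_recorders)
    )
    return DatasetSpec(
        dataset_id=dataset_id,
        sites=sites,
        recorders=recorders,
        minutes_per_site=minutes_per_site,
        class_params=class_params,
        seed=seed,
    )


def render_dataset(tmp_dir, spec: DatasetSpec) -> dict:
    generate_dataset(spec, tmp_dir)
    manifest = load_manifest(tmp_dir / "manifest.csv")
    labels = dict(zip(manifest["file"], manifest["habitat_class"]))
    return {"dir": tmp_dir, "manifest": manifest, "labels": labels}


@pytest.fixture(scope="session")
def cluster40(tmp_path_factory) -> dict:
    """2-class, 4-site, 40-minute separable dataset with both embeddings."""
    out = tmp_path_factory.mktemp("cluster40")
    spec = make_dataset_spec("c40", 4, 10, SEPARABLE_CLASS_PARAMS, seed=42)
    data = render_dataset(out, spec)
    data["compound"] = extract(data["manifest"], "compound_index")
    data["logmel"] = extract(data["manifest"], "logmel_projection")
    return data


@pytest.fixture(scope="session")
def separable12(tmp_path_factory) -> dict:
    """12-site, 5-minutes-per-site strongly separated dataset (compound path)."""
    out = tmp_path_factory.mktemp("separable12")
    spec = make_dataset_spec("sep12", 12, 5, SEPARABLE_CLASS_PARAMS, seed=42,
                             n_recorders=4)
    data = render_dataset(out, spec)
    data["compound"] = extract(data["manifest"], "compound_index")
    return data


#: mildly divergent classes whose index distributions partially overlap
OVERLAP_CLASS_PARAMS = {
    "high": {"snap_rate": 30.0},
    "low": {"snap_rate": 20.0},
}


@pytest.fixture(scope="session")
def overlap8(tmp_path_factory) -> dict:
    """8-site dataset with partially overlapping classes (compound path)."""
    out = tmp_path_factory.mktemp("overlap8")
    spec = make_dataset_spec("ov8", 8, 4, OVERLAP_CLASS_PARAMS, seed=42)
    data = render_dataset(out, spec)
    data["compound"] = extract(data["manifest"], "compound_index")
    return data


@pytest.fixture(scope="session")
def overlap8_accuracy(overlap8) -> dict:
    return blocked_accuracy(overlap8, n_plans=8, n_models=10)


@pytest.fixture(scope="session")
def null12(tmp_path_factory) -> dict:
    """12-site dataset whose two classes are generated identically."""
    out = tmp_path_factory.mktemp("null12")
    spec = make_dataset_spec("null12", 12, 5, {}, seed=42, n_recorders=4)
    data = render_dataset(out, spec)
    data["compound"] = extract(data["manifest"], "compound_index")
    return data


def blocked_accuracy(data: dict, n_plans: int = 10, n_models: int = 50) -> dict:
    """Mean blocked test accuracy of the compound-index random-forest path."""
    from sklearn.ensemble import RandomForestClassifier

    from reefscape.supervised import make_blocked_splits, run_classification

    plans = make_blocked_splits(data["manifest"], repeats=n_plans, seed=0)
    accs, pooled = [], 0
    for i, plan in enumerate(plans):
        rec = run_classification(
            data["compound"], data["labels"], plan,
            classifier=RandomForestClassifier(n_estimators=10),
            n_models=n_models, seed=100 * i,
        )
        accs.append(rec.test_accuracy)
        pooled += int(rec.confusion.to_numpy().sum())
    return {"mean": float(np.mean(accs)), "accuracies": accs, "n_pooled": pooled}


@pytest.fixture(scope="session")
def separable12_accuracy(separable12) -> dict:
    return blocked_accuracy(separable12)


@pytest.fixture(scope="session")
def null12_accuracy(null12) -> dict:
    return blocked_accuracy(null12)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
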