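"""Manifest and run-configuration handling.

A manifest is a CSV with one row per one-minute recording and columns
``file,dataset_id,site_id,habitat_class,recorder_id,timestamp_iso8601``. The
``file`` column is the unique key; paths are resolved relative to the
manifest's own directory.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

__all__ = [
    "REQUIRED_COLUMNS",
    "ManifestError",
    "load_manifest",
    "write_manifest",
    "RunConfig",
]

REQUIRED_COLUMNS = (
    "file",
    "dataset_id",
    "site_id",
    "habitat_class",
    "recorder_id",
    "timestamp_iso8601",
)


class ManifestError(ValueError):
    """Manifest validation failure; carries all row-level problems at once."""

    def __init__(self, problems: list[str]):
        self.problems = list(problems)
        super().__init__("manifest validation failed:\n  " + "\n  ".join(self.problems))


def load_manifest(path: str | os.PathLike, check_files: bool = False) -> pd.DataFrame:
    """Load and validate a manifest CSV.

    Adds helper columns ``timestamp`` (parsed datetime), ``date`` and ``hour``
    and a ``path`` column with file paths resolved against the manifest
    directory. All row-level problems are collected and reported together.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"manifest not found: {path}")
    df = pd.read_csv(path, dtype=str)
    problems: list[str] = []
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ManifestError([f"missing required columns: {missing}"])
    dup = df["file"][df["file"].duplicated()].unique()
    for key in dup:
        rows = df.index[df["file"] == key].tolist()
        problems.append(f"duplicate file key {key!r} in rows {rows}")
    ts = pd.to_datetime(df["timestamp_iso8601"], errors="coerce", format="ISO8601")
    for i in df.index[ts.isna()]:
        problems.append(
            f"row {i}: unparseable timestamp {df.loc[i, 'timestamp_iso8601']!r}"
        )
    if check_files:
        for i, fname in df["file"].items():
            if not (path.parent / fname).exists():
                problems.append(f"row {i}: referenced file missing: {fname}")
    if problems:
        raise ManifestError(problems)
    df = df.copy()
    df["timestamp"] = ts
    df["date"] = ts.dt.date.astype(str)
    df["hour"] = ts.dt.hour + ts.dt.minute / 60.0
    df["path"] = [str(path.parent / f) for f in df["file"]]
    return df


def write_manifest(df: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write the canonical manifest columns to CSV."""
    pd.DataFrame({c: df[c] for c in REQUIRED_COLUMNS}).to_csv(path, index=False)


@dataclass
class RunConfig:
    """Pipeline run configuration with explicit seeds throughout.

    Serialises to YAML; :meth:`config_hash` gives a stable short hash that is
    embedded in every output artifact so runs are traceable and idempotent.
    """

    manifest: str = "manifest.csv"
    out_dir: str = "outputs"
    extractor: str = "compound_index"
    index_preset: str = "default"
    reduce_method: str = "umap"
    reduce_dim: int = 10
    damping: float = 0.5
    block_by: str = "site"
    train_frac: tuple = (0.66, 0.75)
    repeats: int = 100
    n_models: int = 50
    n_estimators: int = 100
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "train_frac" in raw:
            raw["train_frac"] = tuple(raw["train_frac"])
        return cls(**raw)

    def to_yaml(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]
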