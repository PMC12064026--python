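"""Embedding extractors: frame -> fixed-length vector, plus per-minute aggregation.

Two built-in extractors share one contract:

``compound_index``
    the 44-dimension hand-crafted acoustic-index vector per minute;
``logmel_projection``
    a seeded fixed Gaussian random projection of each flattened 96x64 log-mel
    patch to 128 dimensions, averaged across the minute's 62 patches. It is a
    weightless stand-in that exercises the identical plumbing as a pretrained
    convolutional embedding network (which outputs a 128-d penultimate-layer
    feature set); any trained network can be registered under the same
    contract.

Extractors are sklearn-style transformers: ``transform`` maps a list of
:class:`~reefscape.audio.AudioClip` to an (n, d) matrix.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .audio import DEFAULT_RATE, AudioClip, load_audio, log_mel_patches, resample
from .indices import IndexConfig, compound_feature_names, compound_index

__all__ = [
    "EmbeddingMatrix",
    "aggregate_minute",
    "CompoundIndexExtractor",
    "LogMelProjectionExtractor",
    "register_extractor",
    "get_extractor",
    "extract",
]


@dataclass(frozen=True)
class EmbeddingMatrix:
    """An (n_minutes, d) embedding matrix with manifest keys aligned to rows."""

    vectors: np.ndarray
    row_keys: tuple
    extractor_id: str
    feature_names: tuple | None = None

    def __post_init__(self) -> None:
        vectors = np.asarray(self.vectors, dtype=np.float64)
        if vectors.ndim != 2:
            raise ValueError("vectors must be 2-D (n_minutes, d)")
        if len(self.row_keys) != vectors.shape[0]:
            raise ValueError(
                f"{len(self.row_keys)} keys for {vectors.shape[0]} rows"
            )
        if len(set(self.row_keys)) != len(self.row_keys):
            raise ValueError("row keys must be unique")
        if not np.all(np.isfinite(vectors)):
            raise ValueError("embedding entries must be finite")
        object.__setattr__(self, "vectors", vectors)
        object.__setattr__(self, "row_keys", tuple(self.row_keys))

    @property
    def d(self) -> int:
        return self.vectors.shape[1]

    @property
    def n(self) -> int:
        return self.vectors.shape[0]

    def mapping(self) -> dict:
        """key -> vector, independent of row order."""
        return {k: self.vectors[i] for i, k in enumerate(self.row_keys)}

    def to_frame(self) -> pd.DataFrame:
        cols = self.feature_names or [f"e{j}" for j in range(self.d)]
        return pd.DataFrame(self.vectors, index=list(self.row_keys), columns=list(cols))

    def save(self, path: str | os.PathLike) -> None:
        """Write vectors as CSV (key + d columns) with a JSON sidecar holding
        the extractor id and dimension."""
        path = Path(path)
        df = self.to_frame()
        df.index.name = "file"
        df.to_csv(path)
        sidecar = {"extractor_id": self.extractor_id, "d": self.d, "n": self.n}
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, path: str | os.PathLike) -> "EmbeddingMatrix":
        path = Path(path)
        df = pd.read_csv(path, index_col="file")
        sidecar = json.loads(path.with_suffix(".json").read_text())
        return cls(df.to_numpy(float), tuple(df.index), sidecar["extractor_id"],
                   tuple(df.columns))


def aggregate_minute(frame_vectors: np.ndarray) -> np.ndarray:
    """Element-wise mean of the k frame vectors of one minute (k x d -> d)."""
    fv = np.asarray(frame_vectors, dtype=np.float64)
    if fv.ndim != 2 or fv.shape[0] < 1:
        raise ValueError("frame_vectors must be a non-empty (k, d) matrix")
    return fv.mean(axis=0)


class CompoundIndexExtractor(TransformerMixin, BaseEstimator):
    """Per-minute 44-dimension compound acoustic-index extractor."""

    extractor_id = "compound_index"

    def __init__(self, config: IndexConfig | None = None):
        self.config = config

    def fit(self, X=None, y=None):
        return self

    @property
    def feature_names_(self) -> list[str]:
        return compound_feature_names(self.config or IndexConfig())

    @property
    def d(self) -> int:
        return 44

    def transform(self, clips: list[AudioClip]) -> np.ndarray:
        config = self.config or IndexConfig()
        names = compound_feature_names(config)
        return np.stack([compound_index(c, config).as_array(names) for c in clips])


class LogMelProjectionExtractor(TransformerMixin, BaseEstimator):
    """Seeded fixed linear projection of flattened log-mel patches to d=128.

    The projection matrix is Gaussian with entries ~ N(0, 1/6144), drawn once
    from ``weight_seed``; per-patch projections are averaged over the minute.
    Being a random projection it approximately preserves relative distances
    (Johnson-Lindenstrauss), which is what downstream clustering consumes.
    """

    extractor_id = "logmel_projection"

    def __init__(self, d: int = 128, weight_seed: int = 20240101):
        self.d = d
        self.weight_seed = weight_seed

    def fit(self, X=None, y=None):
        return self

    def _weights(self, in_dim: int) -> np.ndarray:
        rng = np.random.default_rng(self.weight_seed)
        return rng.standard_normal((in_dim, self.d)) / np.sqrt(in_dim)

    def transform(self, clips: list[AudioClip]) -> np.ndarray:
        out = []
        weights = None
        for clip in clips:
            patches = log_mel_patches(clip)
            flat = np.stack([p.values.ravel() for p in patches])
            if weights is None:
                weights = self._weights(flat.shape[1])
            out.append(aggregate_minute(flat @ weights))
        return np.stack(out)


_REGISTRY: dict = {
    "compound_index": CompoundIndexExtractor,
    "logmel_projection": LogMelProjectionExtractor,
}


def register_extractor(name: str, factory) -> None:
    """Register an external extractor factory under the shared contract
    (callable returning an object with ``transform`` and ``extractor_id``)."""
    _REGISTRY[name] = factory


def get_extractor(name: str, **kwargs):
    if name not in _REGISTRY:
        raise KeyError(
            f"unknown extractor {name!r}; registered: {sorted(_REGISTRY)}"
        )
    return _REGISTRY[name](**kwargs)


def extract(
    manifest: pd.DataFrame,
    extractor_id: str,
    on_error: str = "raise",
    **extractor_kwargs,
) -> EmbeddingMatrix:
    """Extract one embedding row per manifest minute.

    Audio is loaded from the manifest's resolved ``path`` column (or ``file``)
    and resampled to 16 kHz. ``on_error="skip"`` drops unreadable rows and
    records them in the returned matrix's error report instead of aborting.
    """
    if on_error not in ("raise", "skip"):
        raise ValueError("on_error must be 'raise' or 'skip'")
    extractor = get_extractor(extractor_id, **extractor_kwargs)
    paths = manifest["path"] if "path" in manifest.columns else manifest["file"]
    keys, vectors, errors = [], [], []
    for key, p in zip(manifest["file"], paths):
        try:
            clip = resample(load_audio(p), DEFAULT_RATE)
            vec = extractor.transform([clip])[0]
        except Exception as exc:  # noqa: BLE001 - row-level error report
            if on_error == "raise":
                raise RuntimeError(f"embedding extraction failed for {key!r}") from exc
            errors.append((key, str(exc)))
            continue
        keys.append(key)
        vectors.append(vec)
    if not keys:
        raise RuntimeError("no rows could be embedded")
    names = tuple(extractor.feature_names_) if hasattr(extractor, "feature_names_") else None
    em = EmbeddingMatrix(np.stack(vectors), tuple(keys), extractor_id, names)
    object.__setattr__(em, "errors", errors)
    return em
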