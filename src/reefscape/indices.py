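"""Acoustic indices and the 44-dimension per-minute compound index.

Eight indices are computed for each 0.96-s segment: the acoustic complexity
index (ACI), a diversity index (ADI or its evenness counterpart AEI), the
acoustic entropy H = Ht * Hf, the amplitude index M (median of the fast
envelope), the bioacoustic index (BI), spectral entropy Hf, temporal entropy
Ht, and the normalised difference soundscape index (NDSI). Seven of these are
evaluated over three frequency bands — low (0.05-2 kHz, fish-dominated),
medium (2-8 kHz, snapping-shrimp-dominated) and full (0.05-8 kHz) — while
NDSI contrasts a biophony band against an anthrophony band, giving 22 values
per segment. The per-minute compound index is the mean and standard deviation
of each value across the minute's 62 segments: 44 dimensions.

All indices are relative (no absolute sound-pressure calibration): dB values
are referenced to the spectrogram maximum, and amplitude-scale invariance
holds for every index except M, which scales linearly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .audio import AudioClip, Spectrogram, band_slice, bandpass, spectrogram

__all__ = [
    "IndexConfig",
    "IndexWarning",
    "SegmentFeatures",
    "CompoundIndex",
    "envelope_fast",
    "aci",
    "temporal_entropy",
    "spectral_entropy",
    "acoustic_entropy",
    "median_amplitude",
    "adi",
    "aei",
    "bioacoustic_index",
    "ndsi",
    "segment_features",
    "compound_index",
    "feature_names",
    "compound_feature_names",
]

#: index short names in slot order within each band
BAND_INDEX_NAMES = ("ACI", "DIV", "H", "M", "BI", "Hf", "Ht")
BAND_NAMES = ("low", "medium", "full")


class IndexWarning(UserWarning):
    """Raised (as a warning) for degenerate inputs such as silent segments."""


@dataclass(frozen=True)
class IndexConfig:
    """Parameters of the compound-index front end.

    bands
        (low, high) Hz per analysis band; defaults: low 50-2000,
        medium 2000-8000, full 50-8000 (below 50 Hz is excluded everywhere
        to suppress geophony and recorder self-noise).
    ndsi_anthro, ndsi_bio
        anthrophony / biophony bands for NDSI. Default (50-2000, 2000-8000);
        the ``"williams2022"`` preset uses (50-1000, 2000-5000).
    envelope_nt
        block size of the fast amplitude envelope (max |x| per block).
    adi_db_threshold
        occupancy threshold in dB relative to the spectrogram maximum.
    adi_bin_count
        number of equal-width frequency sub-bands for ADI/AEI (bin_step is
        one tenth of the band's range).
    diversity_index
        which index fills the diversity slot: "AEI" (default) or "ADI".
    """

    bands: dict = field(
        default_factory=lambda: {
            "low": (50.0, 2000.0),
            "medium": (2000.0, 8000.0),
            "full": (50.0, 8000.0),
        }
    )
    ndsi_anthro: tuple = (50.0, 2000.0)
    ndsi_bio: tuple = (2000.0, 8000.0)
    envelope_nt: int = 256
    adi_db_threshold: float = -50.0
    adi_bin_count: int = 10
    diversity_index: str = "AEI"

    def __post_init__(self) -> None:
        for name, (lo, hi) in self.bands.items():
            if not lo < hi:
                raise ValueError(f"band {name!r} bounds not ascending: ({lo}, {hi})")
        if self.envelope_nt < 1:
            raise ValueError("envelope_nt must be >= 1")
        if self.adi_bin_count < 2:
            raise ValueError("adi_bin_count must be >= 2")
        if self.diversity_index not in ("ADI", "AEI"):
            raise ValueError("diversity_index must be 'ADI' or 'AEI'")

    @classmethod
    def preset(cls, name: str) -> "IndexConfig":
        """Named configurations: "default" or "williams2022" (NDSI bands
        0.05-1 kHz vs 2-5 kHz)."""
        if name == "default":
            return cls()
        if name == "williams2022":
            return cls(ndsi_anthro=(50.0, 1000.0), ndsi_bio=(2000.0, 5000.0))
        raise ValueError(f"unknown preset {name!r}")


def feature_names(config: IndexConfig | None = None) -> list[str]:
    """The 22 per-segment feature names in canonical order."""
    config = config or IndexConfig()
    names = []
    for band in BAND_NAMES:
        for idx in BAND_INDEX_NAMES:
            label = config.diversity_index if idx == "DIV" else idx
            names.append(f"{label}_{band}")
    names.append("NDSI")
    return names


def compound_feature_names(config: IndexConfig | None = None) -> list[str]:
    """The 44 per-minute feature names (mean/sd interleaved per feature)."""
    out = []
    for name in feature_names(config):
        out.append(f"mean_{name}")
        out.append(f"sd_{name}")
    return out


@dataclass(frozen=True)
class SegmentFeatures:
    """The 22 index values of one 0.96-s segment, keyed by feature name."""

    values: dict

    def __post_init__(self) -> None:
        if len(self.values) != 22:
            raise ValueError(f"expected 22 features, got {len(self.values)}")
        for k, v in self.values.items():
            if not np.isfinite(v):
                raise ValueError(f"feature {k!r} is not finite: {v}")

    def as_array(self, names: list[str]) -> np.ndarray:
        return np.array([self.values[n] for n in names], dtype=np.float64)


@dataclass(frozen=True)
class CompoundIndex:
    """44 per-minute values: mean and standard deviation of each segment feature."""

    values: dict

    def __post_init__(self) -> None:
        if len(self.values) != 44:
            raise ValueError(f"expected 44 features, got {len(self.values)}")
        for k, v in self.values.items():
            if k.startswith("sd_") and v < 0:
                raise ValueError(f"standard deviation {k!r} negative: {v}")

    def as_array(self, names: list[str] | None = None) -> np.ndarray:
        names = names or list(self.values)
        return np.array([self.values[n] for n in names], dtype=np.float64)


def envelope_fast(segment: AudioClip | np.ndarray, nt: int = 256) -> np.ndarray:
    """Fast amplitude envelope: max |x| over consecutive non-overlapping
    ``nt``-sample blocks; a trailing partial block is discarded."""
    x = segment.samples if isinstance(segment, AudioClip) else np.asarray(segment, float)
    if nt < 1:
        raise ValueError("nt must be >= 1")
    if len(x) < nt:
        raise ValueError(f"segment of {len(x)} samples shorter than one {nt}-sample block")
    n_blocks = len(x) // nt
    return np.abs(x[: n_blocks * nt]).reshape(n_blocks, nt).max(axis=1)


def aci(spec: Spectrogram) -> float:
    """Acoustic complexity index: per-bin sum over time of |dS/dt| divided by
    the bin's total magnitude, summed over bins. Bins that are silent across
    the whole segment contribute zero."""
    if spec.n_frames < 2:
        raise ValueError("ACI requires at least 2 time frames")
    s = spec.magnitude
    num = np.abs(np.diff(s, axis=1)).sum(axis=1)
    den = s.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    return float(ratio.sum())


def _shannon_unit(p: np.ndarray) -> float:
    """Shannon entropy of a probability mass, normalised to [0, 1] by log2(n)."""
    n = len(p)
    if n < 2:
        return 0.0
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum() / np.log2(n))


def temporal_entropy(envelope: np.ndarray) -> float:
    """Temporal entropy Ht in [0, 1]: normalised Shannon entropy of the
    amplitude envelope treated as a probability mass. All-zero input is
    defined as 0 (with a warning)."""
    env = np.asarray(envelope, dtype=np.float64)
    if env.size == 0:
        raise ValueError("empty envelope")
    total = env.sum()
    if total <= 0:
        warnings.warn("all-zero envelope; Ht defined as 0", IndexWarning, stacklevel=2)
        return 0.0
    return _shannon_unit(env / total)


def spectral_entropy(spec: Spectrogram) -> float:
    """Spectral entropy Hf in [0, 1]: normalised Shannon entropy of the mean
    spectrum across frames."""
    if spec.n_bins < 2:
        raise ValueError("spectral entropy requires at least 2 frequency bins")
    mean_spec = spec.magnitude.mean(axis=1)
    total = mean_spec.sum()
    if total <= 0:
        warnings.warn("all-zero spectrum; Hf defined as 0", IndexWarning, stacklevel=2)
        return 0.0
    return _shannon_unit(mean_spec / total)


def acoustic_entropy(ht: float, hf: float) -> float:
    """Acoustic entropy H = Ht * Hf."""
    if not (0.0 <= ht <= 1.0 and 0.0 <= hf <= 1.0):
        raise ValueError(f"Ht and Hf must lie in [0, 1], got ({ht}, {hf})")
    return ht * hf


def median_amplitude(envelope: np.ndarray) -> float:
    """Amplitude index M: median of the envelope (midpoint of the central
    pair for even length)."""
    env = np.asarray(envelope, dtype=np.float64)
    if env.size == 0:
        raise ValueError("empty envelope")
    return float(np.median(env))


def _occupancy(spec: Spectrogram, config: IndexConfig) -> np.ndarray:
    """Per-sub-band occupancy: fraction of spectrogram cells above the dB
    threshold relative to the spectrogram maximum, over ``adi_bin_count``
    equal-width frequency sub-bands spanning the sliced band."""
    peak = spec.magnitude.max()
    if peak <= 0:
        return np.zeros(config.adi_bin_count)
    with np.errstate(divide="ignore"):
        db = 20.0 * np.log10(np.where(spec.magnitude > 0, spec.magnitude, np.nan) / peak)
    above = np.nan_to_num(db, nan=-np.inf) > config.adi_db_threshold
    lo, hi = spec.bin_freqs[0], spec.bin_freqs[-1]
    edges = np.linspace(lo, hi + 1e-9, config.adi_bin_count + 1)
    occ = np.zeros(config.adi_bin_count)
    which = np.clip(np.searchsorted(edges, spec.bin_freqs, side="right") - 1,
                    0, config.adi_bin_count - 1)
    for b in range(config.adi_bin_count):
        cells = above[which == b]
        occ[b] = cells.mean() if cells.size else 0.0
    return occ


def adi(spec: Spectrogram, config: IndexConfig | None = None) -> float:
    """Acoustic diversity index: Shannon entropy (natural log) of the
    occupancy proportions across 10 equal-width sub-bands."""
    config = config or IndexConfig()
    occ = _occupancy(spec, config)
    total = occ.sum()
    if total <= 0:
        warnings.warn("no occupied sub-bands; ADI defined as 0", IndexWarning, stacklevel=2)
        return 0.0
    p = occ / total
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum())


def aei(spec: Spectrogram, config: IndexConfig | None = None) -> float:
    """Acoustic evenness index: Gini coefficient of the sub-band occupancies,
    sum_ij |x_i - x_j| / (2 n^2 mean)."""
    config = config or IndexConfig()
    occ = _occupancy(spec, config)
    mu = occ.mean()
    if mu <= 0:
        warnings.warn("no occupied sub-bands; AEI defined as 0", IndexWarning, stacklevel=2)
        return 0.0
    n = len(occ)
    diff = np.abs(occ[:, None] - occ[None, :]).sum()
    return float(diff / (2 * n * n * mu))


def bioacoustic_index(spec: Spectrogram, db_floor: float = 1e-12) -> float:
    """Bioacoustic index: area under the mean dB spectrum after subtracting
    its in-band minimum (bins x bin width). Invariant to constant dB offsets."""
    if spec.n_bins < 2:
        raise ValueError("bioacoustic index requires at least 2 bins")
    mean_spec = spec.magnitude.mean(axis=1)
    db = 20.0 * np.log10(np.maximum(mean_spec, db_floor))
    shifted = db - db.min()
    bin_width = float(np.mean(np.diff(spec.bin_freqs)))
    return float(shifted.sum() * bin_width)


def ndsi(
    spec: Spectrogram,
    anthro: tuple = (50.0, 2000.0),
    bio: tuple = (2000.0, 8000.0),
) -> float:
    """Normalised difference soundscape index (beta - alpha) / (beta + alpha)
    with beta, alpha the total power in the biophony / anthrophony bands."""
    alpha = float((band_slice(spec, *anthro).magnitude ** 2).sum())
    beta = float((band_slice(spec, *bio).magnitude ** 2).sum())
    if alpha + beta <= 0:
        warnings.warn("zero power in both NDSI bands; NDSI defined as 0",
                      IndexWarning, stacklevel=2)
        return 0.0
    return (beta - alpha) / (beta + alpha)


def segment_features(segment: AudioClip, config: IndexConfig | None = None) -> SegmentFeatures:
    """All 22 index values for one segment.

    Spectral indices (ACI, ADI/AEI, Hf, BI) are computed on the band-sliced
    magnitude spectrogram; envelope indices (Ht, M) on the fast envelope of
    the band-passed waveform; H = Ht * Hf; NDSI on the full spectrogram.
    """
    config = config or IndexConfig()
    spec = spectrogram(segment)
    values: dict = {}
    for band in BAND_NAMES:
        lo, hi = config.bands[band]
        spec_b = band_slice(spec, lo, hi)
        env = envelope_fast(bandpass(segment, lo, hi), config.envelope_nt)
        ht = temporal_entropy(env)
        hf = spectral_entropy(spec_b)
        div = aei(spec_b, config) if config.diversity_index == "AEI" else adi(spec_b, config)
        values[f"ACI_{band}"] = aci(spec_b)
        values[f"{config.diversity_index}_{band}"] = div
        values[f"H_{band}"] = acoustic_entropy(ht, hf)
        values[f"M_{band}"] = median_amplitude(env)
        values[f"BI_{band}"] = bioacoustic_index(spec_b)
        values[f"Hf_{band}"] = hf
        values[f"Ht_{band}"] = ht
    values["NDSI"] = ndsi(spec, config.ndsi_anthro, config.ndsi_bio)
    ordered = {name: values[name] for name in feature_names(config)}
    return SegmentFeatures(ordered)


def compound_index(minute: AudioClip, config: IndexConfig | None = None) -> CompoundIndex:
    """Per-minute compound index: mean and population standard deviation of
    each of the 22 segment features across the minute's segments (62 for a
    60-s recording), in a fixed order."""
    from .audio import segment_minute

    config = config or IndexConfig()
    segments = segment_minute(minute)
    names = feature_names(config)
    rows = np.stack([segment_features(s, config).as_array(names) for s in segments])
    means = rows.mean(axis=0)
    sds = rows.std(axis=0, ddof=0)
    values: dict = {}
    for j, name in enumerate(names):
        values[f"mean_{name}"] = float(means[j])
        values[f"sd_{name}"] = float(sds[j])
    return CompoundIndex(values)
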