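"""Acoustic indices: hand-computed values, brute-force oracles, invariants."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from reefscape.audio import AudioClip, Spectrogram, spectrogram
from reefscape.indices import (
    BAND_NAMES,
    CompoundIndex,
    IndexConfig,
    IndexWarning,
    aci,
    acoustic_entropy,
    adi,
    aei,
    bioacoustic_index,
    compound_feature_names,
    compound_index,
    envelope_fast,
    feature_names,
    median_amplitude,
    ndsi,
    segment_features,
    spectral_entropy,
    temporal_entropy,
)

# ---------------------------------------------------------------- oracles
# Deliberately naive loop-based reimplementations, kept independent of the
# library code paths.


def brute_aci(mag):
    total = 0.0
    for f in range(mag.shape[0]):
        num = sum(abs(mag[f, t + 1] - mag[f, t]) for t in range(mag.shape[1] - 1))
        den = sum(mag[f, :])
        if den > 0:
            total += num / den
    return total


def brute_norm_entropy(values, log=np.log2):
    total = sum(values)
    if total == 0:
        return 0.0
    acc = 0.0
    for v in values:
        p = v / total
        if p > 0:
            acc -= p * log(p)
    return acc / log(len(values))


def brute_gini(values):
    n = len(values)
    mu = sum(values) / n
    if mu == 0:
        return 0.0
    acc = sum(abs(xi - xj) for xi in values for xj in values)
    return acc / (2 * n * n * mu)


def brute_occupancy(mag, freqs, threshold_db=-50.0, n_bins=10):
    peak = mag.max()
    lo, hi = freqs[0], freqs[-1]
    edges = [lo + (hi + 1e-9 - lo) * k / n_bins for k in range(n_bins + 1)]
    occ = []
    for k in range(n_bins):
        cells = []
        for f in range(mag.shape[0]):
            if edges[k] <= freqs[f] < edges[k + 1] or (
                k == n_bins - 1 and freqs[f] >= edges[k]
            ):
                for t in range(mag.shape[1]):
                    level = (
                        20 * np.log10(mag[f, t] / peak) if mag[f, t] > 0 else -np.inf
                    )
                    cells.append(level > threshold_db)
        occ.append(np.mean(cells) if cells else 0.0)
    return occ


def brute_adi(mag, freqs):
    occ = brute_occupancy(mag, freqs)
    total = sum(occ)
    if total == 0:
        return 0.0
    return -sum(
        (o / total) * np.log(o / total) for o in occ if o > 0
    )


def brute_bi(mag, freqs):
    mean_spec = mag.mean(axis=1)
    db = [20 * np.log10(max(v, 1e-12)) for v in mean_spec]
    lo = min(db)
    width = np.mean(np.diff(freqs))
    return sum(v - lo for v in db) * width


def brute_ndsi(mag, freqs, anthro=(50, 2000), bio=(2000, 8000)):
    alpha = beta = 0.0
    for f in range(mag.shape[0]):
        p = (mag[f] ** 2).sum()
        if anthro[0] <= freqs[f] < anthro[1]:
            alpha += p
        if bio[0] <= freqs[f] < bio[1]:
            beta += p
    return (beta - alpha) / (beta + alpha)


def random_spectrogram(rng, n_bins=40, n_frames=12, fmax=8000.0):
    mag = rng.uniform(0, 1, size=(n_bins, n_frames))
    freqs = np.linspace(100, fmax, n_bins)
    times = np.arange(n_frames) * 0.01
    return Spectrogram(mag, freqs, times, 0.025, 0.01)


# ----------------------------------------------------------------- tests


class TestEnvelope:
    def test_constant_amplitude(self):
        env = envelope_fast(np.full(1024, 0.3))
        np.testing.assert_allclose(env, 0.3)

    def test_block_count(self):
        assert len(envelope_fast(np.zeros(512))) == 2
        assert len(envelope_fast(np.zeros(700))) == 2  # remainder discarded

    def test_matches_per_block_max_oracle(self, rng):
        x = rng.standard_normal(2048)
        env = envelope_fast(x, 256)
        expected = [max(abs(v) for v in x[i * 256 : (i + 1) * 256]) for i in range(8)]
        np.testing.assert_allclose(env, expected)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            envelope_fast(np.zeros(100), 256)


class TestAci:
    def test_time_constant_spectrogram_is_zero(self):
        spec = Spectrogram(np.ones((3, 5)), np.arange(3.0), np.arange(5.0) * 0.01,
                           0.025, 0.01)
        assert aci(spec) == 0.0

    def test_hand_computed_toy(self):
        mag = np.array([[1.0, 2.0, 1.0], [2.0, 2.0, 2.0]])
        spec = Spectrogram(mag, np.array([0.0, 1.0]), np.array([0.0, 0.01, 0.02]),
                           0.025, 0.01)
        assert aci(spec) == pytest.approx(0.5)

    def test_scale_invariance(self, rng):
        spec = random_spectrogram(rng)
        scaled = Spectrogram(spec.magnitude * 7.3, spec.bin_freqs, spec.frame_times,
                             0.025, 0.01)
        assert aci(scaled) == pytest.approx(aci(spec))

    def test_single_frame_rejected(self):
        spec = Spectrogram(np.ones((3, 1)), np.arange(3.0), np.array([0.0]),
                           0.025, 0.01)
        with pytest.raises(ValueError):
            aci(spec)


class TestEntropies:
    def test_uniform_envelope_has_unit_entropy(self):
        assert temporal_entropy(np.ones(16)) == pytest.approx(1.0)

    def test_degenerate_envelope_has_zero_entropy(self):
        env = np.zeros(10)
        env[3] = 1.0
        assert temporal_entropy(env) == 0.0

    def test_hand_computed_toy(self):
        # p = (1/4, 1/4, 1/2): H = 1.5 bits over log2(3)
        assert temporal_entropy(np.array([1.0, 1.0, 2.0])) == pytest.approx(
            1.5 / np.log2(3)
        )
        mag = np.array([[1.0], [1.0], [2.0]])
        spec = Spectrogram(mag, np.arange(3.0), np.array([0.0]), 0.025, 0.01)
        assert spectral_entropy(spec) == pytest.approx(1.5 / np.log2(3))

    def test_acoustic_entropy_is_product(self):
        assert acoustic_entropy(1.0, 1.0) == 1.0
        assert acoustic_entropy(0.0, 0.7) == 0.0
        h = 1.5 / np.log2(3)
        assert acoustic_entropy(h, h) == pytest.approx(h * h)

    def test_all_zero_envelope_warns_and_returns_zero(self):
        with pytest.warns(IndexWarning):
            assert temporal_entropy(np.zeros(8)) == 0.0


class TestMedianAmplitude:
    def test_examples(self):
        assert median_amplitude(np.full(5, 0.4)) == pytest.approx(0.4)
        assert median_amplitude(np.array([0.1, 0.5, 0.2])) == pytest.approx(0.2)
        assert median_amplitude(np.array([0.1, 0.3])) == pytest.approx(0.2)


class TestDiversityIndices:
    def _uniform_spec(self):
        mag = np.ones((20, 6))
        freqs = np.linspace(100, 2000, 20)
        return Spectrogram(mag, freqs, np.arange(6.0) * 0.01, 0.025, 0.01)

    def test_full_occupancy_gives_ln10_and_zero_gini(self):
        spec = self._uniform_spec()
        assert adi(spec) == pytest.approx(np.log(10))
        assert aei(spec) == pytest.approx(0.0)

    def test_single_occupied_subband(self):
        mag = np.zeros((20, 6))
        mag[0, :] = 1.0  # only the first sub-band occupied
        freqs = np.linspace(100, 2000, 20)
        spec = Spectrogram(mag, freqs, np.arange(6.0) * 0.01, 0.025, 0.01)
        assert adi(spec) == pytest.approx(0.0)
        assert aei(spec) == pytest.approx(0.9)  # Gini of (1, 0, ..., 0), n=10

    def test_gini_brute_force_on_known_vector(self):
        assert brute_gini([1.0] + [0.0] * 9) == pytest.approx(0.9)

    def test_empty_occupancy_warns(self):
        mag = np.zeros((20, 6))
        freqs = np.linspace(100, 2000, 20)
        spec = Spectrogram(mag, freqs, np.arange(6.0) * 0.01, 0.025, 0.01)
        with pytest.warns(IndexWarning):
            assert adi(spec) == 0.0
        with pytest.warns(IndexWarning):
            assert aei(spec) == 0.0


class TestBioacousticIndex:
    def test_flat_spectrum_is_zero(self):
        mag = np.full((10, 4), 0.5)
        spec = Spectrogram(mag, np.linspace(100, 1000, 10), np.arange(4.0) * 0.01,
                           0.025, 0.01)
        assert bioacoustic_index(spec) == pytest.approx(0.0)

    def test_two_bin_hand_computation(self):
        # dB spectrum (-10, -20), width 1 -> area 10
        mag = np.array([[10 ** (-10 / 20)], [10 ** (-20 / 20)]])
        spec = Spectrogram(mag, np.array([0.0, 1.0]), np.array([0.0]), 0.025, 0.01)
        assert bioacoustic_index(spec) == pytest.approx(10.0)

    def test_db_offset_invariance(self, rng):
        spec = random_spectrogram(rng)
        shifted = Spectrogram(spec.magnitude * 10 ** (6 / 20), spec.bin_freqs,
                              spec.frame_times, 0.025, 0.01)
        assert bioacoustic_index(shifted) == pytest.approx(bioacoustic_index(spec))


class TestNdsi:
    def test_balanced_bands_give_zero(self):
        mag = np.ones((40, 3))
        freqs = np.linspace(50, 7950, 40)
        spec = Spectrogram(mag, freqs, np.arange(3.0) * 0.01, 0.025, 0.01)
        # 20 bins below 2 kHz? construct equal power explicitly instead
        alpha_bins = (freqs >= 50) & (freqs < 2000)
        beta_bins = (freqs >= 2000) & (freqs < 8000)
        mag[alpha_bins] = 1.0
        mag[beta_bins] = np.sqrt(alpha_bins.sum() / beta_bins.sum())
        spec = Spectrogram(mag, freqs, np.arange(3.0) * 0.01, 0.025, 0.01)
        assert ndsi(spec) == pytest.approx(0.0, abs=1e-12)

    def test_pure_bio_power_gives_one(self):
        freqs = np.linspace(50, 7950, 40)
        mag = np.where((freqs >= 2000)[:, None], 1.0, 0.0) * np.ones((40, 3))
        spec = Spectrogram(mag, freqs, np.arange(3.0) * 0.01, 0.025, 0.01)
        assert ndsi(spec) == pytest.approx(1.0)

    def test_three_to_one_ratio(self):
        freqs = np.array([100.0, 3000.0])
        mag = np.array([[1.0], [np.sqrt(3.0)]])  # power 1 vs 3
        spec = Spectrogram(mag, freqs, np.array([0.0]), 0.025, 0.01)
        assert ndsi(spec) == pytest.approx(0.5)


class TestBruteForceEquivalence:
    """Every index equals the naive loop implementation on random toys."""

    @pytest.mark.parametrize("seed", range(5))
    def test_all_indices_match_oracles(self, seed):
        rng = np.random.default_rng(seed)
        spec = random_spectrogram(rng)
        mag, freqs = spec.magnitude, spec.bin_freqs
        assert aci(spec) == pytest.approx(brute_aci(mag), abs=1e-9)
        assert spectral_entropy(spec) == pytest.approx(
            brute_norm_entropy(mag.mean(axis=1)), abs=1e-9
        )
        assert adi(spec) == pytest.approx(brute_adi(mag, freqs), abs=1e-9)
        assert aei(spec) == pytest.approx(
            brute_gini(brute_occupancy(mag, freqs)), abs=1e-9
        )
        assert bioacoustic_index(spec) == pytest.approx(brute_bi(mag, freqs), abs=1e-9)
        env = rng.uniform(0, 1, 60)
        assert temporal_entropy(env) == pytest.approx(
            brute_norm_entropy(env), abs=1e-9
        )
        ordered = sorted(env)
        assert median_amplitude(env) == pytest.approx((ordered[29] + ordered[30]) / 2)
        full_freqs = np.linspace(100, 7900, 40)
        full_spec = Spectrogram(mag, full_freqs, spec.frame_times, 0.025, 0.01)
        assert ndsi(full_spec) == pytest.approx(
            brute_ndsi(mag, full_freqs), abs=1e-9
        )


@settings(max_examples=60, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=10_000))
def test_range_invariants_on_random_spectrograms(seed):
    """Ht, Hf, H in [0,1]; NDSI in [-1,1]; AEI in [0,1); ACI, BI, M >= 0."""
    rng = np.random.default_rng(seed)
    spec = random_spectrogram(rng, n_bins=int(rng.integers(10, 50)),
                              n_frames=int(rng.integers(2, 20)))
    env = rng.uniform(0, 1, int(rng.integers(2, 100)))
    ht, hf = temporal_entropy(env), spectral_entropy(spec)
    assert 0.0 <= ht <= 1.0 and 0.0 <= hf <= 1.0
    assert 0.0 <= acoustic_entropy(ht, hf) <= 1.0
    assert -1.0 <= ndsi(spec, (100, 4000), (4000, 8000)) <= 1.0
    assert 0.0 <= aei(spec) < 1.0
    assert aci(spec) >= 0.0
    assert bioacoustic_index(spec) >= 0.0
    assert median_amplitude(env) >= 0.0


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=10_000),
       st.floats(min_value=0.1, max_value=50.0))
def test_amplitude_scale_invariance(seed, c):
    """Indices other than M are unchanged under x -> c*x; M scales by c."""
    rng = np.random.default_rng(seed)
    spec = random_spectrogram(rng)
    scaled = Spectrogram(spec.magnitude * c, spec.bin_freqs, spec.frame_times,
                         0.025, 0.01)
    env = rng.uniform(0.01, 1, 40)
    assert aci(scaled) == pytest.approx(aci(spec))
    assert spectral_entropy(scaled) == pytest.approx(spectral_entropy(spec))
    assert adi(scaled) == pytest.approx(adi(spec))
    assert aei(scaled) == pytest.approx(aei(spec))
    assert ndsi(scaled, (100, 4000), (4000, 8000)) == pytest.approx(
        ndsi(spec, (100, 4000), (4000, 8000))
    )
    assert temporal_entropy(env * c) == pytest.approx(temporal_entropy(env))
    assert median_amplitude(env * c) == pytest.approx(c * median_amplitude(env))


class TestPermutationInvariance:
    def test_diversity_indices_ignore_subband_order(self, rng):
        # permuting whole sub-bands permutes occupancies; ADI/AEI unchanged
        mag = rng.uniform(0, 1, size=(20, 6))
        freqs = np.linspace(100, 2000, 20)
        spec = Spectrogram(mag, freqs, np.arange(6.0) * 0.01, 0.025, 0.01)
        # permute pairs of rows within the same sub-band layout (2 bins per band)
        perm = np.arange(20).reshape(10, 2)[rng.permutation(10)].ravel()
        permuted = Spectrogram(mag[perm], freqs, spec.frame_times, 0.025, 0.01)
        assert adi(permuted) == pytest.approx(adi(spec))
        assert aei(permuted) == pytest.approx(aei(spec))


@pytest.fixture(scope="module")
def segment():
    rng = np.random.default_rng(0)
    t = np.arange(15360) / 16000
    x = (0.1 * rng.standard_normal(15360)
         + 0.3 * np.sin(2 * np.pi * 4000 * t)
         + 0.2 * np.sin(2 * np.pi * 300 * t))
    return AudioClip(x, 16000)


class TestSegmentAndCompound:

    def test_exactly_22_finite_values(self, segment):
        feats = segment_features(segment)
        assert len(feats.values) == 22
        assert list(feats.values) == feature_names()
        assert all(np.isfinite(v) for v in feats.values.values())

    def test_pure_bio_band_tone_has_ndsi_near_one(self):
        t = np.arange(15360) / 16000
        clip = AudioClip(0.5 * np.sin(2 * np.pi * 4000 * t), 16000)
        feats = segment_features(clip)
        assert feats.values["NDSI"] > 0.99

    def test_silent_segment_warns_but_completes(self):
        clip = AudioClip(np.zeros(15360), 16000)
        with pytest.warns(IndexWarning):
            feats = segment_features(clip)
        assert len(feats.values) == 22

    def test_adi_config_fills_diversity_slot(self, segment):
        feats = segment_features(segment, IndexConfig(diversity_index="ADI"))
        assert "ADI_low" in feats.values and "AEI_low" not in feats.values

    def test_compound_has_44_named_values(self, segment):
        minute = AudioClip(np.tile(segment.samples, 4), 16000)
        ci = compound_index(minute)
        assert len(ci.values) == 44
        assert list(ci.values) == compound_feature_names()

    def test_identical_segments_have_zero_sd(self, segment):
        minute = AudioClip(np.tile(segment.samples, 3), 16000)
        ci = compound_index(minute)
        single = segment_features(segment)
        for name, value in single.values.items():
            assert ci.values[f"mean_{name}"] == pytest.approx(value)
            assert ci.values[f"sd_{name}"] == pytest.approx(0.0, abs=1e-9)

    def test_two_segment_aggregation_matches_brute_force(self, rng):
        a = AudioClip(rng.uniform(-0.5, 0.5, 15360), 16000)
        b = AudioClip(rng.uniform(-0.5, 0.5, 15360), 16000)
        minute = AudioClip(np.concatenate([a.samples, b.samples]), 16000)
        ci = compound_index(minute)
        fa, fb = segment_features(a).values, segment_features(b).values
        for name in fa:
            mean = (fa[name] + fb[name]) / 2
            sd = np.sqrt(((fa[name] - mean) ** 2 + (fb[name] - mean) ** 2) / 2)
            assert ci.values[f"mean_{name}"] == pytest.approx(mean, abs=1e-12)
            assert ci.values[f"sd_{name}"] == pytest.approx(sd, abs=1e-12)
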