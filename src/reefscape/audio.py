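"""Audio front-end: WAV I/O, resampling, segmentation, spectrograms and log-mel patches.

Every downstream stage consumes :class:`AudioClip` (a mono waveform in [-1, 1]
with its sample rate). One-minute recordings are split into non-overlapping
0.96-s segments — 62 per minute — to match the convolutional front-end's input
window, and the same minute yields 62 non-overlapping 96-frame x 64-mel-bin
log-mel patches from a single 25-ms/10-ms short-time Fourier transform.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field

import numpy as np
from scipy.io import wavfile
from scipy.signal import resample_poly

__all__ = [
    "AudioClip",
    "Spectrogram",
    "LogMelPatch",
    "load_audio",
    "write_wav",
    "resample",
    "segment_minute",
    "spectrogram",
    "band_slice",
    "bandpass",
    "mel_filterbank",
    "log_mel_patches",
    "DEFAULT_RATE",
    "SEGMENT_SECONDS",
    "STFT_WINDOW_S",
    "STFT_HOP_S",
    "N_MELS",
    "PATCH_FRAMES",
    "LOG_OFFSET",
]

#: analysis sample rate (Hz); everything is resampled here before feature extraction
DEFAULT_RATE = 16000
#: segment length in seconds (62 non-overlapping segments per one-minute recording)
SEGMENT_SECONDS = 0.96
STFT_WINDOW_S = 0.025
STFT_HOP_S = 0.010
N_MELS = 64
PATCH_FRAMES = 96
#: additive offset inside the log for log-mel energies
LOG_OFFSET = 0.01
MEL_FMIN = 125.0
MEL_FMAX = 7500.0


@dataclass(frozen=True)
class AudioClip:
    """A mono waveform with its sample rate.

    Samples are float amplitudes nominally in [-1, 1]; all finite.
    """

    samples: np.ndarray
    sample_rate: int

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        if samples.ndim != 1:
            raise ValueError(f"AudioClip requires a 1-D waveform, got shape {samples.shape}")
        if not np.all(np.isfinite(samples)):
            raise ValueError("AudioClip samples must all be finite")
        if self.sample_rate <= 0:
            raise ValueError(f"sample_rate must be positive, got {self.sample_rate}")
        object.__setattr__(self, "samples", samples)

    @property
    def duration(self) -> float:
        """Clip length in seconds."""
        return len(self.samples) / self.sample_rate

    def __len__(self) -> int:
        return len(self.samples)


@dataclass(frozen=True)
class Spectrogram:
    """Magnitude short-time spectrum, indexed [frequency_bin, time_frame]."""

    magnitude: np.ndarray
    bin_freqs: np.ndarray
    frame_times: np.ndarray
    window_s: float
    hop_s: float

    def __post_init__(self) -> None:
        mag = np.asarray(self.magnitude, dtype=np.float64)
        freqs = np.asarray(self.bin_freqs, dtype=np.float64)
        times = np.asarray(self.frame_times, dtype=np.float64)
        if mag.ndim != 2:
            raise ValueError("magnitude must be 2-D [frequency_bin, time_frame]")
        if mag.shape != (len(freqs), len(times)):
            raise ValueError(
                f"magnitude shape {mag.shape} does not match axes "
                f"({len(freqs)} bins, {len(times)} frames)"
            )
        if np.any(mag < 0):
            raise ValueError("magnitude must be non-negative")
        if len(freqs) and freqs[0] < 0:
            raise ValueError("bin_freqs must be non-negative")
        if len(freqs) > 1 and not np.all(np.diff(freqs) > 0):
            raise ValueError("bin_freqs must be strictly ascending")
        if len(times) > 1 and not np.all(np.diff(times) > 0):
            raise ValueError("frame_times must be strictly ascending")
        object.__setattr__(self, "magnitude", mag)
        object.__setattr__(self, "bin_freqs", freqs)
        object.__setattr__(self, "frame_times", times)

    @property
    def n_bins(self) -> int:
        return self.magnitude.shape[0]

    @property
    def n_frames(self) -> int:
        return self.magnitude.shape[1]


@dataclass(frozen=True)
class LogMelPatch:
    """A 96-frame x 64-mel-bin patch of log energies (one 0.96-s input window)."""

    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.float64)
        if values.shape != (PATCH_FRAMES, N_MELS):
            raise ValueError(
                f"log-mel patch must be {PATCH_FRAMES}x{N_MELS}, got {values.shape}"
            )
        if not np.all(np.isfinite(values)):
            raise ValueError("log-mel patch entries must be finite")
        object.__setattr__(self, "values", values)


def load_audio(path: str | os.PathLike) -> AudioClip:
    """Read a PCM WAV file as a mono clip scaled to [-1, 1].

    Multi-channel input is averaged to mono. Integer PCM is scaled by the
    type's full-scale value (e.g. 2**15 for 16-bit).
    """
    if not os.path.exists(path):
        raise FileNotFoundError(f"audio file not found: {path}")
    rate, data = wavfile.read(path)
    if data.dtype == np.int16:
        samples = data.astype(np.float64) / 32768.0
    elif data.dtype == np.int32:
        samples = data.astype(np.float64) / 2147483648.0
    elif data.dtype == np.uint8:
        samples = (data.astype(np.float64) - 128.0) / 128.0
    elif data.dtype in (np.float32, np.float64):
        samples = data.astype(np.float64)
    else:
        raise ValueError(f"unsupported WAV encoding: {data.dtype}")
    if samples.ndim == 2:
        samples = samples.mean(axis=1)
    return AudioClip(samples, int(rate))


def write_wav(clip: AudioClip, path: str | os.PathLike) -> None:
    """Write a clip as 16-bit PCM mono WAV (values clipped to [-1, 1])."""
    scaled = np.clip(clip.samples, -1.0, 1.0)
    pcm = np.clip(np.round(scaled * 32768.0), -32768, 32767).astype(np.int16)
    wavfile.write(path, clip.sample_rate, pcm)


def resample(clip: AudioClip, target_rate: int) -> AudioClip:
    """Resample to ``target_rate`` via polyphase filtering.

    Returns the clip unchanged when the rate already matches. Duration is
    preserved to within one sample; content below the new Nyquist is kept.
    """
    if target_rate <= 0:
        raise ValueError(f"target_rate must be positive, got {target_rate}")
    if target_rate == clip.sample_rate:
        return clip
    g = math.gcd(int(target_rate), int(clip.sample_rate))
    up, down = target_rate // g, clip.sample_rate // g
    samples = resample_poly(clip.samples, up, down)
    return AudioClip(samples, int(target_rate))


def segment_minute(clip: AudioClip, segment_s: float = SEGMENT_SECONDS) -> list[AudioClip]:
    """Split a clip into consecutive non-overlapping ``segment_s`` chunks.

    A trailing remainder shorter than one segment is discarded, so a 60-s
    clip yields 62 segments of 0.96 s.
    """
    seg_len = int(round(segment_s * clip.sample_rate))
    if seg_len <= 0:
        raise ValueError("segment_s must be positive")
    if len(clip) < seg_len:
        raise ValueError(
            f"clip of {clip.duration:.3f} s is shorter than one {segment_s} s segment"
        )
    n_seg = len(clip) // seg_len
    return [
        AudioClip(clip.samples[i * seg_len : (i + 1) * seg_len], clip.sample_rate)
        for i in range(n_seg)
    ]


def spectrogram(
    clip: AudioClip,
    window_s: float = STFT_WINDOW_S,
    hop_s: float = STFT_HOP_S,
    window_fn=np.hanning,
) -> Spectrogram:
    """Magnitude STFT with ``window_s`` windows every ``hop_s`` seconds.

    Frame count is floor((n_samples - window) / hop) + 1; no padding is
    applied, so every frame covers real signal.
    """
    if not (window_s >= hop_s > 0):
        raise ValueError("require window_s >= hop_s > 0")
    win_len = int(round(window_s * clip.sample_rate))
    hop_len = int(round(hop_s * clip.sample_rate))
    if win_len > len(clip):
        raise ValueError(
            f"window of {win_len} samples longer than clip of {len(clip)} samples"
        )
    window = window_fn(win_len)
    n_frames = (len(clip) - win_len) // hop_len + 1
    idx = np.arange(win_len)[None, :] + hop_len * np.arange(n_frames)[:, None]
    frames = clip.samples[idx] * window
    mag = np.abs(np.fft.rfft(frames, axis=1)).T  # [bin, frame]
    bin_freqs = np.fft.rfftfreq(win_len, d=1.0 / clip.sample_rate)
    frame_times = (hop_len * np.arange(n_frames) + win_len / 2) / clip.sample_rate
    return Spectrogram(mag, bin_freqs, frame_times, window_s, hop_s)


def band_slice(spec: Spectrogram, f_low: float, f_high: float) -> Spectrogram:
    """Restrict a spectrogram to bins with center frequency in [f_low, f_high)."""
    if not f_low < f_high:
        raise ValueError(f"require f_low < f_high, got [{f_low}, {f_high})")
    keep = (spec.bin_freqs >= f_low) & (spec.bin_freqs < f_high)
    if not np.any(keep):
        raise ValueError(f"no frequency bins in [{f_low}, {f_high}) Hz")
    return Spectrogram(
        spec.magnitude[keep], spec.bin_freqs[keep], spec.frame_times,
        spec.window_s, spec.hop_s,
    )


def bandpass(clip: AudioClip, f_low: float, f_high: float) -> AudioClip:
    """Zero-phase band-pass by masking FFT bins outside [f_low, f_high)."""
    if not f_low < f_high:
        raise ValueError(f"require f_low < f_high, got [{f_low}, {f_high})")
    spectrum = np.fft.rfft(clip.samples)
    freqs = np.fft.rfftfreq(len(clip), d=1.0 / clip.sample_rate)
    spectrum[(freqs < f_low) | (freqs >= f_high)] = 0.0
    return AudioClip(np.fft.irfft(spectrum, n=len(clip)), clip.sample_rate)


def mel_hz_to_mel(f: np.ndarray | float) -> np.ndarray | float:
    """Hz to mel, 2595 * log10(1 + f / 700)."""
    return 2595.0 * np.log10(1.0 + np.asarray(f, dtype=np.float64) / 700.0)


def mel_mel_to_hz(m: np.ndarray | float) -> np.ndarray | float:
    """Mel to Hz, inverse of :func:`mel_hz_to_mel`."""
    return 700.0 * (10.0 ** (np.asarray(m, dtype=np.float64) / 2595.0) - 1.0)


def mel_filterbank(
    n_mels: int = N_MELS,
    n_fft_bins: int | None = None,
    sample_rate: int = DEFAULT_RATE,
    fmin: float = MEL_FMIN,
    fmax: float = MEL_FMAX,
    bin_freqs: np.ndarray | None = None,
) -> np.ndarray:
    """Triangular mel filterbank, shape (n_mels, n_fft_bins).

    Filters are triangles in the mel domain with edges at ``n_mels + 2``
    equally spaced mel points between ``fmin`` and ``fmax``, evaluated at the
    FFT bin center frequencies.
    """
    if bin_freqs is None:
        if n_fft_bins is None:
            raise ValueError("provide n_fft_bins or bin_freqs")
        n_fft = 2 * (n_fft_bins - 1)
        bin_freqs = np.fft.rfftfreq(n_fft, d=1.0 / sample_rate)
    edges = mel_mel_to_hz(np.linspace(mel_hz_to_mel(fmin), mel_hz_to_mel(fmax), n_mels + 2))
    weights = np.zeros((n_mels, len(bin_freqs)))
    for m in range(n_mels):
        lo, center, hi = edges[m], edges[m + 1], edges[m + 2]
        rising = (bin_freqs - lo) / (center - lo)
        falling = (hi - bin_freqs) / (hi - center)
        weights[m] = np.maximum(0.0, np.minimum(rising, falling))
    return weights


def log_mel_patches(clip: AudioClip, log_offset: float = LOG_OFFSET) -> list[LogMelPatch]:
    """Compute 96x64 log-mel patches for a clip already at 16 kHz.

    A single STFT (25-ms window, 10-ms hop) over the whole clip is
    mel-integrated into 64 bins, log(x + offset) transformed, and partitioned
    into non-overlapping 96-frame patches; a 60-s clip yields 62 patches.
    Trailing frames short of a full patch are discarded.
    """
    if clip.sample_rate != DEFAULT_RATE:
        raise ValueError(
            f"log-mel front-end expects {DEFAULT_RATE} Hz input, got {clip.sample_rate}; "
            "resample first"
        )
    spec = spectrogram(clip)
    if spec.n_frames < PATCH_FRAMES:
        raise ValueError(
            f"clip provides {spec.n_frames} STFT frames; at least {PATCH_FRAMES} required"
        )
    fb = mel_filterbank(bin_freqs=spec.bin_freqs)
    mel_energy = fb @ spec.magnitude  # [mel, frame]
    log_mel = np.log(mel_energy + log_offset).T  # [frame, mel]
    n_patches = log_mel.shape[0] // PATCH_FRAMES
    return [
        LogMelPatch(log_mel[i * PATCH_FRAMES : (i + 1) * PATCH_FRAMES])
        for i in range(n_patches)
    ]
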