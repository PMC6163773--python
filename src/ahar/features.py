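"""Frame-level acoustic features in temporal, spectral and wavelet domains.

Three complementary descriptor families are extracted per 30 ms frame:

* **MFCC** — 13 mel-cepstral coefficients (the first carries frame energy)
  plus their 13 velocity (delta) coefficients: 26 dimensions.
* **MPEG-7 low-level descriptors** — audio spectrum centroid and spread on
  the log-frequency axis, plus per-band spectral flatness over 1/4-octave
  bands: 2 + B dimensions.
* **PWP** (perceptual wavelet packets) — per Bark critical band, a 3-level
  Haar wavelet-packet transform of the band-limited frame; the feature is
  the area under the autocorrelation envelope of the packet coefficients,
  normalized by half the frame size: one dimension per critical band.

All extractors are deterministic and emit finite values for any finite
input, including all-zero audio (log/ratio computations are floored).
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
from scipy.fft import dct, irfft, rfft

from .audio import CANONICAL_RATE, AudioClip

logger = logging.getLogger(__name__)

_LOG_FLOOR = 1e-10      # mel energies before log
_POWER_FLOOR = 1e-12    # spectral power for centroid/spread/flatness
_STD_FLOOR = 1e-8       # normalizer sigma floor

#: Bark critical-band edges (Hz); bands above Nyquist are dropped and the
#: last retained band is capped at Nyquist.
BARK_EDGES = np.array([
    0, 100, 200, 300, 400, 510, 630, 770, 920, 1080, 1270, 1480, 1720,
    2000, 2320, 2700, 3150, 3700, 4400, 5300, 6400, 7700, 9500, 12000,
    15500,
], dtype=float)

FEATURE_SETS = ("mfcc", "mpeg7", "pwp", "concatenated")


@dataclass(frozen=True)
class FrameGrid:
    """Short-time analysis grid: frame/hop lengths in samples, taper, FFT size."""

    frame_length: int
    hop: int
    window: str = "hamming"
    fft_size: int = 512
    sample_rate: int = CANONICAL_RATE

    def __post_init__(self) -> None:
        if not (0 < self.hop <= self.frame_length):
            raise ValueError("require 0 < hop <= frame_length")
        if self.fft_size < self.frame_length:
            raise ValueError("fft_size must be >= frame_length")

    @classmethod
    def default(cls, sample_rate: int = CANONICAL_RATE,
                frame_ms: float = 30.0, hop_ms: float = 10.0,
                fft_size: int = 512) -> "FrameGrid":
        """30 ms frames advancing by 10 ms (20 ms overlap), Hamming taper."""
        return cls(frame_length=int(round(frame_ms * 1e-3 * sample_rate)),
                   hop=int(round(hop_ms * 1e-3 * sample_rate)),
                   fft_size=fft_size, sample_rate=sample_rate)

    @property
    def taper(self) -> np.ndarray:
        if self.window != "hamming":
            raise ValueError(f"unsupported window {self.window!r}")
        return np.hamming(self.frame_length)

    def n_frames(self, n_samples: int) -> int:
        return 1 + (n_samples - self.frame_length) // self.hop


@dataclass
class FeatureSequence:
    """A T x K matrix of per-frame features for one clip."""

    values: np.ndarray
    feature_set: str
    clip_id: str = ""
    label: str | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=np.float64))
        if not np.isfinite(self.values).all():
            raise ValueError("feature values must be finite")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def n_dims(self) -> int:
        return self.values.shape[1]


def frame_signal(clip: AudioClip, grid: FrameGrid) -> np.ndarray:
    """Slice a clip into overlapping windowed frames (T x frame_length).

    Frame count follows T = 1 + floor((len - frame_length) / hop); a clip
    shorter than one frame is rejected.
    """
    if clip.sample_rate != grid.sample_rate:
        raise ValueError(
            f"clip rate {clip.sample_rate} != grid rate {grid.sample_rate}; "
            "resample on ingestion")
    x = clip.samples
    if x.size < grid.frame_length:
        raise ValueError(
            f"clip {clip.clip_id!r} is {x.size} samples; minimum duration is "
            f"one frame = {grid.frame_length} samples "
            f"({grid.frame_length / grid.sample_rate:.3f} s)")
    frames = np.lib.stride_tricks.sliding_window_view(
        x, grid.frame_length)[::grid.hop]
    return frames * grid.taper


def power_spectrum(frames: np.ndarray, grid: FrameGrid) -> np.ndarray:
    """Per-frame power spectrum |DFT|^2, T x (fft_size/2 + 1)."""
    return np.abs(rfft(frames, n=grid.fft_size, axis=-1)) ** 2


# ---------------------------------------------------------------------------
# MFCC
# ---------------------------------------------------------------------------

def _hz_to_mel(f):
    return 2595.0 * np.log10(1.0 + np.asarray(f) / 700.0)


def _mel_to_hz(m):
    return 700.0 * (10.0 ** (np.asarray(m) / 2595.0) - 1.0)


def mel_filterbank(n_filters: int, grid: FrameGrid) -> np.ndarray:
    """Triangular mel filterbank from 0 Hz to Nyquist (n_filters x bins)."""
    nyq = grid.sample_rate / 2.0
    mel_pts = np.linspace(_hz_to_mel(0.0), _hz_to_mel(nyq), n_filters + 2)
    hz_pts = _mel_to_hz(mel_pts)
    freqs = np.arange(grid.fft_size // 2 + 1) * grid.sample_rate / grid.fft_size
    fb = np.zeros((n_filters, freqs.size))
    for i in range(n_filters):
        lo, ctr, hi = hz_pts[i], hz_pts[i + 1], hz_pts[i + 2]
        up = (freqs - lo) / max(ctr - lo, 1e-12)
        down = (hi - freqs) / max(hi - ctr, 1e-12)
        fb[i] = np.clip(np.minimum(up, down), 0.0, None)
    return fb


def delta_coefficients(c: np.ndarray, width: int = 2) -> np.ndarray:
    """Velocity coefficients: linear-regression slope over a +/-width window.

    Edge frames are handled by replication padding; the delta of a
    time-constant sequence is exactly zero.
    """
    pad = np.concatenate([np.repeat(c[:1], width, axis=0), c,
                          np.repeat(c[-1:], width, axis=0)], axis=0)
    num = np.zeros_like(c)
    for n in range(1, width + 1):
        num += n * (pad[width + n: pad.shape[0] - width + n]
                    - pad[width - n: -width - n])
    return num / (2.0 * sum(n * n for n in range(1, width + 1)))


def extract_mfcc(frames: np.ndarray, grid: FrameGrid, n_ceps: int = 13,
                 n_filters: int = 26, clip_id: str = "",
                 label: str | None = None) -> FeatureSequence:
    """13 mel cepstral coefficients + 13 velocities per frame (26 dims).

    Coefficient 0 (retained) tracks log frame energy. Mel energies are
    floored before the log so silent frames stay finite.
    """
    spec = power_spectrum(frames, grid)
    mel = spec @ mel_filterbank(n_filters, grid).T
    logmel = np.log(np.maximum(mel, _LOG_FLOOR))
    ceps = dct(logmel, type=2, norm="ortho", axis=-1)[:, :n_ceps]
    vals = np.hstack([ceps, delta_coefficients(ceps)])
    return FeatureSequence(vals, "mfcc", clip_id, label)


# ---------------------------------------------------------------------------
# MPEG-7 low-level descriptors
# ---------------------------------------------------------------------------

def flatness_bands(grid: FrameGrid, low_edge: float = 62.5,
                   overlap: float = 0.10) -> list[tuple[float, float]]:
    """1/4-octave log-spaced bands from ``low_edge`` to Nyquist.

    Each nominal band [lo, lo * 2^(1/4)] is widened symmetrically by the
    given fractional overlap, following the standard's overlapping-band
    layout.
    """
    nyq = grid.sample_rate / 2.0
    bands = []
    k = 0
    while low_edge * 2 ** ((k + 1) / 4.0) <= nyq * (1 + 1e-9):
        lo = low_edge * 2 ** (k / 4.0)
        hi = low_edge * 2 ** ((k + 1) / 4.0)
        half = overlap / 2.0
        bands.append((lo * (1 - half), hi * (1 + half)))
        k += 1
    return bands


def extract_mpeg7(frames: np.ndarray, grid: FrameGrid, clip_id: str = "",
                  label: str | None = None) -> FeatureSequence:
    """Audio spectrum centroid, spread and per-band flatness (2 + B dims).

    Centroid and spread live on the log-frequency (octave re 1 kHz) axis;
    power below 62.5 Hz is collapsed into a single low coefficient so a DC
    offset cannot drag the centroid. Flatness is the geometric/arithmetic
    mean ratio of spectral power per 1/4-octave band; power is floored so
    silent frames yield defined (mid-axis centroid, flatness 1) values.
    """
    spec = power_spectrum(frames, grid)
    freqs = np.arange(grid.fft_size // 2 + 1) * grid.sample_rate / grid.fft_size

    low = freqs < 62.5
    low_power = spec[:, low].sum(axis=1, keepdims=True)
    p = np.hstack([low_power, spec[:, ~low]])
    # the collapsed coefficient sits at the mid-point of [0, 62.5) Hz
    f = np.concatenate([[31.25], freqs[~low]])
    logf = np.log2(f / 1000.0)

    p = np.maximum(p, _POWER_FLOOR)
    total = p.sum(axis=1)
    centroid = (p * logf).sum(axis=1) / total
    spread = np.sqrt((p * (logf - centroid[:, None]) ** 2).sum(axis=1) / total)

    flat = []
    for lo, hi in flatness_bands(grid):
        sel = (freqs >= lo) & (freqs < hi)
        if not sel.any():
            flat.append(np.ones(spec.shape[0]))
            continue
        band = np.maximum(spec[:, sel], _POWER_FLOOR)
        gm = np.exp(np.log(band).mean(axis=1))
        am = band.mean(axis=1)
        flat.append(gm / am)
    vals = np.column_stack([centroid, spread, *flat])
    return FeatureSequence(vals, "mpeg7", clip_id, label)


# ---------------------------------------------------------------------------
# Perceptual wavelet packets
# ---------------------------------------------------------------------------

def bark_bands(grid: FrameGrid) -> list[tuple[float, float]]:
    """Bark critical bands up to Nyquist (last band capped at Nyquist)."""
    nyq = grid.sample_rate / 2.0
    edges = BARK_EDGES[BARK_EDGES < nyq].tolist() + [nyq]
    return list(zip(edges[:-1], edges[1:]))


def haar_wpt(x: np.ndarray, levels: int = 3) -> np.ndarray:
    """Full Haar wavelet-packet transform along the last axis.

    Returns the concatenated level-``levels`` packet coefficients (natural
    order); the last axis must be divisible by 2**levels. Vectorized over
    leading axes — equivalent to running a Haar WaveletPacket per row.
    """
    n = x.shape[-1]
    if n % (1 << levels):
        raise ValueError(f"last axis ({n}) must be divisible by {1 << levels}")
    packets = [x]
    for _ in range(levels):
        nxt = []
        for p in packets:
            a = (p[..., 0::2] + p[..., 1::2]) / np.sqrt(2.0)
            d = (p[..., 0::2] - p[..., 1::2]) / np.sqrt(2.0)
            nxt.extend([a, d])
        packets = nxt
    return np.concatenate(packets, axis=-1)


def _autocorr_envelope_area(c: np.ndarray) -> np.ndarray:
    """Sum over lags of |biased autocorrelation| along the last axis."""
    n = c.shape[-1]
    nfft = 1 << int(np.ceil(np.log2(2 * n)))
    r = irfft(np.abs(rfft(c, n=nfft, axis=-1)) ** 2, axis=-1)[..., :n] / n
    return np.abs(r).sum(axis=-1)


def extract_pwp(frames: np.ndarray, grid: FrameGrid, clip_id: str = "",
                label: str | None = None) -> FeatureSequence:
    """Perceptual wavelet-packet features: one scalar per Bark band.

    The frame spectrum is partitioned into critical bands; each band-limited
    frame signal undergoes a 3-level Haar wavelet-packet transform, and the
    feature is the area under the autocorrelation envelope of the packet
    coefficients, normalized by 50% of the frame size. The measure is
    quadratic in amplitude and zero for silent frames.
    """
    spec = rfft(frames, n=grid.fft_size, axis=-1)
    freqs = np.arange(grid.fft_size // 2 + 1) * grid.sample_rate / grid.fft_size
    cols = []
    for lo, hi in bark_bands(grid):
        mask = (freqs >= lo) & (freqs < hi)
        band_sig = irfft(spec * mask, n=grid.fft_size, axis=-1)
        coeffs = haar_wpt(band_sig, levels=3)
        cols.append(_autocorr_envelope_area(coeffs) / (0.5 * grid.frame_length))
    return FeatureSequence(np.column_stack(cols), "pwp", clip_id, label)


# ---------------------------------------------------------------------------
# Dispatch and normalization
# ---------------------------------------------------------------------------

def extract_features(clip: AudioClip, feature_set: str = "concatenated",
                     grid: FrameGrid | None = None) -> FeatureSequence:
    """Extract one feature set (or the concatenation of all three)."""
    grid = grid or FrameGrid.default(clip.sample_rate)
    frames = frame_signal(clip, grid)
    if feature_set == "mfcc":
        return extract_mfcc(frames, grid, clip_id=clip.clip_id,
                            label=clip.label)
    if feature_set == "mpeg7":
        return extract_mpeg7(frames, grid, clip_id=clip.clip_id,
                             label=clip.label)
    if feature_set == "pwp":
        return extract_pwp(frames, grid, clip_id=clip.clip_id,
                           label=clip.label)
    if feature_set in ("concatenated", "all"):
        parts = [extract_mfcc(frames, grid), extract_mpeg7(frames, grid),
                 extract_pwp(frames, grid)]
        vals = np.hstack([p.values for p in parts])
        return FeatureSequence(vals, "concatenated", clip.clip_id, clip.label)
    raise ValueError(f"unknown feature_set {feature_set!r}; "
                     f"choose from {FEATURE_SETS}")


def feature_dim(feature_set: str, grid: FrameGrid | None = None) -> int:
    """Fixed per-corpus dimensionality of a feature set."""
    grid = grid or FrameGrid.default()
    dims = {"mfcc": 26,
            "mpeg7": 2 + len(flatness_bands(grid)),
            "pwp": len(bark_bands(grid))}
    dims["concatenated"] = sum(dims.values())
    dims["all"] = dims["concatenated"]
    return dims[feature_set]


@dataclass
class FeatureNormalizer:
    """Mean-removal / variance-scaling statistics fitted on training data."""

    mean: np.ndarray
    std: np.ndarray

    @classmethod
    def fit(cls, training: list[FeatureSequence]) -> "FeatureNormalizer":
        if not training:
            raise ValueError("training set is empty")
        sets = {fs.feature_set for fs in training}
        if len(sets) > 1:
            raise ValueError(f"mixed feature sets in training pool: {sets}")
        pooled = np.vstack([fs.values for fs in training])
        mean = pooled.mean(axis=0)
        std = pooled.std(axis=0)
        degenerate = std < _STD_FLOOR
        if degenerate.any():
            logger.warning("normalizer: %d zero-variance dimensions floored "
                           "at %g", int(degenerate.sum()), _STD_FLOOR)
            std = np.where(degenerate, _STD_FLOOR, std)
        return cls(mean=mean, std=std)

    def apply(self, fs: FeatureSequence) -> FeatureSequence:
        if fs.n_dims != self.mean.size:
            raise ValueError("feature dimensionality mismatch")
        return FeatureSequence((fs.values - self.mean) / self.std,
                               fs.feature_set, fs.clip_id, fs.label,
                               dict(fs.meta))


def fit_normalizer(training: list[FeatureSequence]) -> FeatureNormalizer:
    """Fit mean/variance statistics on the training pool only."""
    return FeatureNormalizer.fit(training)


def apply_normalizer(norm: FeatureNormalizer,
                     fs: FeatureSequence) -> FeatureSequence:
    return norm.apply(fs)


# ---------------------------------------------------------------------------
# Feature container I/O: one .npz per clip + sidecar JSON header
# ---------------------------------------------------------------------------

def save_feature_sequence(directory: str | os.PathLike,
                          fs: FeatureSequence,
                          grid: FrameGrid | None = None) -> str:
    os.makedirs(directory, exist_ok=True)
    stem = os.path.join(os.fspath(directory), fs.clip_id or "features")
    np.savez(stem + ".npz", values=fs.values)
    header = {"clip_id": fs.clip_id, "label": fs.label,
              "feature_set": fs.feature_set, "n_dims": fs.n_dims,
              "n_frames": fs.n_frames, "meta": fs.meta}
    if grid is not None:
        header["frame_grid"] = {"frame_length": grid.frame_length,
                                "hop": grid.hop, "window": grid.window,
                                "fft_size": grid.fft_size,
                                "sample_rate": grid.sample_rate}
    with open(stem + ".json", "w") as fh:
        json.dump(header, fh, indent=1)
    return stem + ".npz"


def load_feature_sequence(npz_path: str | os.PathLike) -> FeatureSequence:
    stem = os.path.splitext(os.fspath(npz_path))[0]
    values = np.load(stem + ".npz")["values"]
    with open(stem + ".json") as fh:
        header = json.load(fh)
    return FeatureSequence(values, header["feature_set"], header["clip_id"],
                           header["label"], header.get("meta", {}))


def load_feature_dir(directory: str | os.PathLike) -> list[FeatureSequence]:
    out = []
    for name in sorted(os.listdir(directory)):
        if name.endswith(".npz"):
            out.append(load_feature_sequence(os.path.join(directory, name)))
    return out
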