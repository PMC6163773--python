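"""Audio clip container, WAV input/output and corpus manifests.

All downstream stages operate at a single canonical sample rate (16 kHz
mono); heterogeneous recordings are resampled on ingestion so frame grids
and spectral band layouts are identical across the corpus.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.io import wavfile
from scipy.signal import resample_poly

#: Canonical pipeline sample rate in Hz.
CANONICAL_RATE = 16_000


@dataclass
class AudioClip:
    """A mono audio clip with waveform in [-1, 1].

    Parameters
    ----------
    samples : ndarray of float
        Mono waveform, values in [-1, 1].
    sample_rate : int
        Sampling rate in Hz, > 0.
    label : str or None
        Activity class identifier, if known.
    clip_id : str
        Unique identifier within a corpus.
    """

    samples: np.ndarray
    sample_rate: int
    label: str | None = None
    clip_id: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1 or self.samples.size == 0:
            raise ValueError("samples must be a non-empty 1-D array")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")

    @property
    def duration(self) -> float:
        """Clip duration in seconds."""
        return self.samples.size / self.sample_rate

    def resampled(self, rate: int = CANONICAL_RATE) -> "AudioClip":
        """Return a copy resampled to ``rate`` (polyphase filtering)."""
        if rate == self.sample_rate:
            return self
        g = np.gcd(int(self.sample_rate), int(rate))
        out = resample_poly(self.samples, rate // g, self.sample_rate // g)
        return AudioClip(out, rate, self.label, self.clip_id, dict(self.meta))


def _to_float(data: np.ndarray) -> np.ndarray:
    """Convert integer PCM to float in [-1, 1]; pass floats through."""
    if np.issubdtype(data.dtype, np.floating):
        return data.astype(np.float64)
    info = np.iinfo(data.dtype)
    scale = max(abs(info.min), info.max)
    offset = 0.0
    if info.min == 0:  # unsigned PCM (e.g. uint8) is offset-binary
        offset = (info.max + 1) / 2.0
        scale = (info.max + 1) / 2.0
    return (data.astype(np.float64) - offset) / scale


def read_wav(path: str | os.PathLike, clip_id: str | None = None,
             label: str | None = None,
             canonical_rate: int | None = CANONICAL_RATE) -> AudioClip:
    """Read a PCM WAV file as a mono :class:`AudioClip`.

    Multi-channel input is averaged to mono; integer PCM of any bit depth
    is rescaled to [-1, 1]; the clip is resampled to ``canonical_rate``
    unless that is None.
    """
    rate, data = wavfile.read(os.fspath(path))
    data = _to_float(np.asarray(data))
    if data.ndim > 1:
        data = data.mean(axis=1)
    cid = clip_id if clip_id is not None else os.path.splitext(
        os.path.basename(os.fspath(path)))[0]
    clip = AudioClip(data, rate, label, cid)
    if canonical_rate is not None:
        clip = clip.resampled(canonical_rate)
    return clip


def write_wav(path: str | os.PathLike, clip: AudioClip) -> None:
    """Write a clip as 16-bit PCM WAV."""
    x = np.clip(clip.samples, -1.0, 1.0)
    wavfile.write(os.fspath(path), int(clip.sample_rate),
                  (x * 32767.0).astype(np.int16))


def read_manifest(path: str | os.PathLike) -> pd.DataFrame:
    """Read a corpus manifest: delimited text with clip_id, path, label."""
    df = pd.read_csv(path, dtype={"clip_id": str, "path": str, "label": str})
    missing = {"clip_id", "path", "label"} - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    if df["clip_id"].duplicated().any():
        raise ValueError("manifest contains duplicate clip_id values")
    return df


def write_manifest(path: str | os.PathLike, df: pd.DataFrame) -> None:
    df.to_csv(path, index=False)


def load_corpus(manifest: pd.DataFrame,
                root: str | os.PathLike = ".") -> list[AudioClip]:
    """Load every clip listed in a manifest, resampled to the canonical rate."""
    clips = []
    for row in manifest.itertuples(index=False):
        p = os.path.join(os.fspath(root), row.path)
        clips.append(read_wav(p, clip_id=row.clip_id, label=row.label))
    return clips
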