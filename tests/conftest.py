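import logging
import warnings

import numpy as np
import pytest

from ahar.audio import CANONICAL_RATE, AudioClip
from ahar.features import FrameGrid

# hmmlearn/sklearn emit convergence chatter on tiny fixtures
warnings.filterwarnings("ignore", category=UserWarning)
warnings.filterwarnings("ignore", category=RuntimeWarning)
logging.getLogger("ahar").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def grid() -> FrameGrid:
    return FrameGrid.default()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def make_tone(freq: float, duration: float = 1.0, amplitude: float = 0.5,
              rate: int = CANONICAL_RATE, label: str | None = None,
              clip_id: str = "tone") -> AudioClip:
    t = np.arange(int(duration * rate)) / rate
    return AudioClip(amplitude * np.sin(2 * np.pi * freq * t), rate,
                     label=label, clip_id=clip_id)


def make_noise(duration: float = 1.0, amplitude: float = 0.3,
               rate: int = CANONICAL_RATE, seed: int = 0,
               clip_id: str = "noise") -> AudioClip:
    x = np.random.default_rng(seed).standard_normal(int(duration * rate))
    return AudioClip(amplitude * x / np.abs(x).max(), rate, clip_id=clip_id)


@pytest.fixture(scope="session")
def tone_1khz() -> AudioClip:
    return make_tone(1000.0)
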