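"""WAV reading/writing and the framing primitives shared by every stage.

All audio is carried between stages as :class:`AudioSignal`: a mono float64
amplitude sequence in nominal range [-1, 1] plus its sample rate.  Framing
follows the usual short-time analysis convention: overlapping windows of
``frame_length`` samples advanced by ``hop_length``, optionally zero-padded so
that frame *i* is centred on sample ``i * hop_length``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.io import wavfile
from scipy.signal import get_window, resample_poly

logger = logging.getLogger(__name__)

__all__ = [
    "AudioSignal",
    "FrameParams",
    "read_wav",
    "write_wav",
    "frame_signal",
]


@dataclass
class AudioSignal:
    """Mono audio samples with their sample rate.

    Parameters
    ----------
    samples : ndarray
        Amplitude sequence, dimensionless, nominal range [-1, 1].
    sample_rate : int
        Sampling frequency in Hz, strictly positive.
    source_id : str
        Free-text provenance label (file path, generator spec, ...).
    meta : dict
        Optional per-signal annotations (e.g. augmentation parameters).
    """

    samples: np.ndarray
    sample_rate: int
    source_id: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ValueError("AudioSignal samples must be one-dimensional")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")

    @property
    def duration(self) -> float:
        """Length in seconds."""
        return len(self.samples) / self.sample_rate

    def __len__(self) -> int:
        return len(self.samples)


@dataclass
class FrameParams:
    """Short-time analysis configuration.

    ``frame_length`` and ``hop_length`` are in samples; ``window`` is any name
    accepted by :func:`scipy.signal.get_window`; with ``center`` the signal is
    zero-padded by ``frame_length // 2`` on both ends so frames are centred on
    sample times.
    """

    frame_length: int = 1024
    hop_length: int = 512
    window: str = "hann"
    center: bool = True

    def __post_init__(self) -> None:
        if not (self.frame_length >= self.hop_length >= 1):
            raise ValueError("need frame_length >= hop_length >= 1")

    @property
    def n_bins(self) -> int:
        """Number of non-negative frequency bins of an rFFT of one frame."""
        return self.frame_length // 2 + 1

    def get_window(self) -> np.ndarray:
        return get_window(self.window, self.frame_length, fftbins=True)

    def n_frames(self, n_samples: int) -> int:
        length = n_samples + (self.frame_length if self.center else 0)
        if length < self.frame_length:
            return 0
        return 1 + (length - self.frame_length) // self.hop_length


class WavFormatError(ValueError):
    """Raised when a file is not a readable PCM/float WAV."""


def read_wav(path, target_rate: int | None = None) -> AudioSignal:
    """Read a PCM or IEEE-float WAV file into a mono :class:`AudioSignal`.

    Multi-channel audio is averaged to mono.  Integer PCM is rescaled to
    [-1, 1].  When ``target_rate`` differs from the file's rate the signal is
    resampled with a polyphase filter.
    """
    try:
        rate, data = wavfile.read(path)
    except Exception as exc:  # scipy raises bare ValueError on bad RIFF
        raise WavFormatError(f"cannot read WAV file {path!r}: {exc}") from exc
    if data.size == 0:
        raise WavFormatError(f"WAV file {path!r} contains no audio")

    if np.issubdtype(data.dtype, np.integer):
        info = np.iinfo(data.dtype)
        scale = float(max(abs(info.min), info.max))
        samples = data.astype(np.float64) / scale
    else:
        samples = data.astype(np.float64)
    if samples.ndim == 2:
        samples = samples.mean(axis=1)

    if target_rate is not None and target_rate != rate:
        g = np.gcd(int(target_rate), int(rate))
        samples = resample_poly(samples, target_rate // g, rate // g)
        rate = target_rate
    return AudioSignal(samples, int(rate), source_id=str(path))


def write_wav(signal: AudioSignal, path, bit_depth: int = 16) -> None:
    """Write a signal to a RIFF WAV file.

    ``bit_depth`` 16 writes integer PCM (samples outside [-1, 1] are clamped
    with a warning); 32 writes IEEE float, which round-trips losslessly.
    """
    if len(signal) == 0:
        raise ValueError("refusing to write an empty signal")
    x = signal.samples
    if bit_depth == 16:
        if np.max(np.abs(x)) > 1.0:
            warnings.warn("samples exceed [-1, 1]; clamping for 16-bit write")
            x = np.clip(x, -1.0, 1.0)
        q = np.clip(np.round(x * 32768.0), -32768, 32767).astype(np.int16)
        wavfile.write(path, signal.sample_rate, q)
    elif bit_depth == 32:
        wavfile.write(path, signal.sample_rate, x.astype(np.float32))
    else:
        raise ValueError("bit_depth must be 16 or 32")


def frame_signal(signal: AudioSignal, params: FrameParams) -> np.ndarray:
    """Slice a signal into overlapping frames.

    Returns an ``(n_frames, frame_length)`` matrix whose row *i* is
    ``x[i*hop : i*hop + frame_length]`` (of the zero-padded signal when
    ``params.center``).  When the signal is shorter than one frame and
    ``center`` is off, a ``(0, frame_length)`` matrix is returned.
    """
    x = signal.samples
    fl, hop = params.frame_length, params.hop_length
    if params.center:
        pad = fl // 2
        x = np.concatenate([np.zeros(pad), x, np.zeros(fl - pad)])
    n = params.n_frames(len(signal))
    if n == 0:
        logger.info("signal shorter than one frame: zero frames produced")
        return np.empty((0, fl))
    idx = np.arange(fl)[None, :] + hop * np.arange(n)[:, None]
    return x[idx]
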