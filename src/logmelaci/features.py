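"""Spectral representations: STFT magnitude, Mel spectrum, Log-Mel, MFCC.

The chain implemented here feeds both the classifiers and the acoustic
indices:

1. short-time Fourier transform magnitude ``|X| = sqrt(Re^2 + Im^2)``;
2. projection onto a bank of (by default 20) triangular Mel filters,
   ``Mel = W @ |X|``;
3. dynamic-range compression ``LogMel = log(1 + Mel)``;
4. optionally MFCC: a DCT-II over log filterbank energies,
   ``C_n = sum_m log(E_m) cos(n (m + 0.5) pi / M)``,
   with first/second-order regression deltas
   ``dC_t = sum_{n=-N}^{N} n C_{t+n} / (2 sum_{n=1}^{N} n^2)``.

The Mel scale uses the HTK convention ``mel(f) = 2595 log10(1 + f/700)``.
Filters have unit apex (no area normalisation); the log base for the Log-Mel
compression is natural.  Both choices are configuration, not physics: the
downstream complexity index is a ratio of same-base logs, so the base rescales
numerator and denominator alike.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .audio_io import AudioSignal, FrameParams, frame_signal

__all__ = [
    "Spectrogram",
    "MelFilterbank",
    "LogMelSpectrogram",
    "MFCCMatrix",
    "stft_complex",
    "istft",
    "stft_magnitude",
    "hz_to_mel",
    "mel_to_hz",
    "mel_filterbank",
    "mel_spectrogram",
    "log_compress",
    "mfcc",
    "delta",
    "second_order_mfcc",
    "LogMelExtractor",
    "MFCCExtractor",
]


# ---------------------------------------------------------------------------
# containers


@dataclass
class Spectrogram:
    """STFT magnitude over a (frequency bin, frame) grid."""

    magnitude: np.ndarray  # (n_bins, n_frames), >= 0
    bin_freqs: np.ndarray  # Hz, strictly increasing 0 .. sr/2
    frame_times: np.ndarray  # seconds, one per frame
    params: FrameParams
    sample_rate: int

    @property
    def n_frames(self) -> int:
        return self.magnitude.shape[1]


@dataclass
class MelFilterbank:
    """Triangular filters mapping linear-frequency bins to Mel bands."""

    weights: np.ndarray  # (n_mels, n_bins), >= 0
    n_mels: int
    fmin_hz: float
    fmax_hz: float
    center_freqs_hz: np.ndarray = field(default=None)  # type: ignore[assignment]


@dataclass
class LogMelSpectrogram:
    """log(1 + Mel) matrix over (mel band, frame); entries are >= 0."""

    values: np.ndarray  # (n_mels, n_frames)
    frame_times: np.ndarray | None = None

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]


@dataclass
class MFCCMatrix:
    """Cepstral coefficients plus first/second temporal derivatives."""

    coeffs: np.ndarray  # (n_coeffs, n_frames)
    delta: np.ndarray | None = None
    delta2: np.ndarray | None = None
    delta_width_N: int = 1


# ---------------------------------------------------------------------------
# STFT and its inverse


def stft_complex(signal: AudioSignal, params: FrameParams) -> np.ndarray:
    """Complex STFT, shape (frame_length//2 + 1, n_frames)."""
    frames = frame_signal(signal, params)
    win = params.get_window()
    return np.fft.rfft(frames * win, axis=1).T


def istft(stft: np.ndarray, params: FrameParams, length: int) -> np.ndarray:
    """Invert :func:`stft_complex` by windowed overlap-add.

    Each inverse-FFT frame is weighted by the analysis window a second time
    and the accumulated result divided by the summed squared window, which
    reconstructs the input exactly (up to float error) wherever the window
    sum is non-zero, for any window/hop combination with full coverage.
    """
    fl, hop = params.frame_length, params.hop_length
    win = params.get_window()
    frames = np.fft.irfft(stft.T, n=fl, axis=1)
    n_frames = frames.shape[0]
    total = fl + hop * (n_frames - 1) if n_frames else fl
    y = np.zeros(total)
    wsum = np.zeros(total)
    for i in range(n_frames):
        sl = slice(i * hop, i * hop + fl)
        y[sl] += frames[i] * win
        wsum[sl] += win**2
    nz = wsum > 1e-12
    y[nz] /= wsum[nz]
    if params.center:
        y = y[fl // 2 :]
    if len(y) < length:
        y = np.concatenate([y, np.zeros(length - len(y))])
    return y[:length]


def stft_magnitude(signal: AudioSignal, params: FrameParams) -> Spectrogram:
    """STFT magnitude spectrogram of a signal."""
    if len(signal) == 0:
        raise ValueError("cannot compute a spectrogram of an empty signal")
    mag = np.abs(stft_complex(signal, params))
    sr = signal.sample_rate
    bin_freqs = np.fft.rfftfreq(params.frame_length, d=1.0 / sr)
    frame_times = np.arange(mag.shape[1]) * params.hop_length / sr
    if not params.center:
        frame_times += params.frame_length / (2 * sr)
    return Spectrogram(mag, bin_freqs, frame_times, params, sr)


# ---------------------------------------------------------------------------
# Mel filterbank


def hz_to_mel(f):
    """HTK Mel scale: 2595 log10(1 + f / 700)."""
    return 2595.0 * np.log10(1.0 + np.asarray(f, dtype=float) / 700.0)


def mel_to_hz(m):
    return 700.0 * (10.0 ** (np.asarray(m, dtype=float) / 2595.0) - 1.0)


def mel_filterbank(
    n_mels: int = 20,
    n_fft: int = 1024,
    sample_rate: int = 22050,
    fmin_hz: float = 0.0,
    fmax_hz: float | None = None,
    area_normalize: bool = False,
) -> MelFilterbank:
    """Bank of triangular filters with centres equally spaced in Mel.

    ``n_mels + 2`` edge points are laid out uniformly between ``mel(fmin)``
    and ``mel(fmax)``; filter k rises linearly from edge k to edge k+1 and
    falls to edge k+2, evaluated at the FFT bin frequencies.  Unit apex by
    default; ``area_normalize`` divides each row by its bandwidth instead.
    """
    if fmax_hz is None:
        fmax_hz = sample_rate / 2.0
    if not (0 <= fmin_hz < fmax_hz <= sample_rate / 2.0):
        raise ValueError(
            f"invalid Mel band [{fmin_hz}, {fmax_hz}] Hz for sample rate {sample_rate}"
        )
    if n_mels < 2:
        raise ValueError("need at least 2 Mel filters")

    edges_hz = mel_to_hz(np.linspace(hz_to_mel(fmin_hz), hz_to_mel(fmax_hz), n_mels + 2))
    bin_freqs = np.fft.rfftfreq(n_fft, d=1.0 / sample_rate)
    weights = np.zeros((n_mels, len(bin_freqs)))
    for k in range(n_mels):
        lo, mid, hi = edges_hz[k], edges_hz[k + 1], edges_hz[k + 2]
        rising = (bin_freqs - lo) / (mid - lo)
        falling = (hi - bin_freqs) / (hi - mid)
        weights[k] = np.maximum(0.0, np.minimum(rising, falling))
        if area_normalize:
            weights[k] *= 2.0 / (hi - lo)
    return MelFilterbank(weights, n_mels, fmin_hz, fmax_hz, center_freqs_hz=edges_hz[1:-1])


def mel_spectrogram(spec: Spectrogram | np.ndarray, fb: MelFilterbank) -> np.ndarray:
    """Project an STFT magnitude onto the Mel filterbank: ``W @ |X|``."""
    mag = spec.magnitude if isinstance(spec, Spectrogram) else np.asarray(spec)
    if fb.weights.shape[1] != mag.shape[0]:
        raise ValueError(
            f"filterbank expects {fb.weights.shape[1]} bins, spectrogram has {mag.shape[0]}"
        )
    return fb.weights @ mag


def log_compress(mel: np.ndarray, base: float | None = None) -> LogMelSpectrogram:
    """Compress a Mel spectrum as ``log(1 + Mel)`` (natural log by default)."""
    mel = np.asarray(mel, dtype=float)
    if np.any(mel < 0):
        raise ValueError("Mel spectrum must be non-negative")
    out = np.log1p(mel)
    if base is not None:
        out = out / np.log(base)
    return LogMelSpectrogram(out)


# ---------------------------------------------------------------------------
# MFCC


def mfcc(mel: np.ndarray, n_coeffs: int = 13, log_floor_eps: float = 1e-10) -> MFCCMatrix:
    """Cepstral coefficients from Mel filterbank energies.

    ``C_n[t] = sum_{m=0}^{M-1} log(E_m[t] + eps) cos(n (m + 0.5) pi / M)``
    for n = 0 .. n_coeffs-1.  The additive eps keeps silent frames finite;
    note this log differs deliberately from the log(1 + x) used for Log-Mel.
    """
    mel = np.asarray(mel, dtype=float)
    M = mel.shape[0]
    if n_coeffs > M:
        raise ValueError(f"n_coeffs={n_coeffs} exceeds the {M} Mel bands available")
    log_e = np.log(mel + log_floor_eps)
    n = np.arange(n_coeffs)[:, None]
    m = np.arange(M)[None, :]
    basis = np.cos(n * (m + 0.5) * np.pi / M)  # (n_coeffs, M)
    return MFCCMatrix(coeffs=basis @ log_e)


def delta(coeffs: np.ndarray, N: int = 1) -> np.ndarray:
    """Regression delta over a +/-N frame window, edges replicate-padded.

    ``d_t = sum_{n=-N}^{N} n C_{t+n} / (2 sum_{n=1}^{N} n^2)``; applying it
    twice yields the second-order (delta-delta) coefficients.
    """
    coeffs = np.atleast_2d(np.asarray(coeffs, dtype=float))
    if N not in (1, 2):
        raise ValueError("delta width N must be 1 or 2")
    if coeffs.shape[1] < 2:
        raise ValueError("need at least 2 frames for a temporal delta")
    padded = np.pad(coeffs, [(0, 0), (N, N)], mode="edge")
    denom = 2.0 * sum(n * n for n in range(1, N + 1))
    out = np.zeros_like(coeffs)
    for n in range(1, N + 1):
        out += n * (padded[:, N + n :][:, : coeffs.shape[1]] - padded[:, N - n : N - n + coeffs.shape[1]])
    return out / denom


def second_order_mfcc(
    signal: AudioSignal,
    params: FrameParams | None = None,
    n_mels: int = 20,
    n_coeffs: int = 13,
    fmin_hz: float = 0.0,
    fmax_hz: float | None = None,
    delta_width_N: int = 1,
) -> MFCCMatrix:
    """Full second-order MFCC chain: STFT -> Mel -> MFCC -> delta -> delta-delta."""
    params = params or FrameParams()
    spec = stft_magnitude(signal, params)
    fb = mel_filterbank(n_mels, params.frame_length, signal.sample_rate, fmin_hz, fmax_hz)
    mel = mel_spectrogram(spec, fb)
    m = mfcc(mel, n_coeffs=n_coeffs)
    d1 = delta(m.coeffs, N=delta_width_N)
    d2 = delta(d1, N=delta_width_N)
    return MFCCMatrix(coeffs=m.coeffs, delta=d1, delta2=d2, delta_width_N=delta_width_N)


# ---------------------------------------------------------------------------
# estimator wrappers


class _SignalTransformer(BaseEstimator, TransformerMixin):
    """Shared plumbing: stateless transformers over (lists of) AudioSignal."""

    def fit(self, X=None, y=None):
        return self

    def transform(self, X):
        if isinstance(X, AudioSignal):
            return self._transform_one(X)
        return [self._transform_one(sig) for sig in X]

    def _frame_params(self) -> FrameParams:
        return FrameParams(self.frame_length, self.hop_length, self.window, self.center)


class LogMelExtractor(_SignalTransformer):
    """Transformer producing log(1 + Mel) spectrograms from audio signals."""

    def __init__(
        self,
        n_mels: int = 20,
        frame_length: int = 1024,
        hop_length: int = 512,
        window: str = "hann",
        center: bool = True,
        fmin_hz: float = 0.0,
        fmax_hz: float | None = None,
    ):
        self.n_mels = n_mels
        self.frame_length = frame_length
        self.hop_length = hop_length
        self.window = window
        self.center = center
        self.fmin_hz = fmin_hz
        self.fmax_hz = fmax_hz

    def _transform_one(self, signal: AudioSignal) -> LogMelSpectrogram:
        params = self._frame_params()
        spec = stft_magnitude(signal, params)
        fb = mel_filterbank(
            self.n_mels, params.frame_length, signal.sample_rate, self.fmin_hz, self.fmax_hz
        )
        lm = log_compress(mel_spectrogram(spec, fb))
        lm.frame_times = spec.frame_times
        return lm


class MFCCExtractor(_SignalTransformer):
    """Transformer producing second-order MFCC matrices from audio signals."""

    def __init__(
        self,
        n_coeffs: int = 13,
        n_mels: int = 20,
        frame_length: int = 1024,
        hop_length: int = 512,
        window: str = "hann",
        center: bool = True,
        fmin_hz: float = 0.0,
        fmax_hz: float | None = None,
        delta_width_N: int = 1,
    ):
        self.n_coeffs = n_coeffs
        self.n_mels = n_mels
        self.frame_length = frame_length
        self.hop_length = hop_length
        self.window = window
        self.center = center
        self.fmin_hz = fmin_hz
        self.fmax_hz = fmax_hz
        self.delta_width_N = delta_width_N

    def _transform_one(self, signal: AudioSignal) -> MFCCMatrix:
        return second_order_mfcc(
            signal,
            self._frame_params(),
            n_mels=self.n_mels,
            n_coeffs=self.n_coeffs,
            fmin_hz=self.fmin_hz,
            fmax_hz=self.fmax_hz,
            delta_width_N=self.delta_width_N,
        )
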