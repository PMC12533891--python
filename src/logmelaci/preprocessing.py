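"""Denoising, voiced-segment extraction and augmentation of field recordings.

Three stages prepare a raw recording for feature extraction:

* **Spectral subtraction** — estimate a stationary noise magnitude spectrum
  ``|D|`` and remove it per frame: ``|X|^p = max(|Y|^p - |D|^p, beta |D|^p)``
  with p=1 (amplitude) or p=2 (power), keeping the noisy phase and
  resynthesising by overlap-add.  Suited to steady backgrounds (wind hum,
  machinery); it does not attempt non-stationary suppression.
* **Endpoint detection** — classify frames as voiced/silent from short-time
  energy ``E_t = sum |x[n]|^2`` and zero-crossing rate
  ``Z_t = 1/2 sum |sgn(x[n]) - sgn(x[n-1])|``, min-max normalised, combined
  as a weighted average, and thresholded at ``mean + 0.5 std``.
* **Augmentation** — pitch-preserving time stretch (phase vocoder) in
  0.8-1.2x speed and zero-filled time shifts of 0-100 ms, applied with a
  seeded RNG until a class reaches a minimum total duration.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import resample_poly
from sklearn.base import BaseEstimator, TransformerMixin

from .audio_io import AudioSignal, FrameParams, frame_signal
from .features import istft, stft_complex

logger = logging.getLogger(__name__)

__all__ = [
    "NoiseProfile",
    "SegmentList",
    "estimate_noise_profile",
    "spectral_subtract",
    "short_time_energy",
    "zero_crossing_rate",
    "detect_endpoints",
    "time_stretch",
    "time_shift",
    "augment_to_minimum",
    "SpectralSubtractor",
    "EndpointDetector",
]


@dataclass
class NoiseProfile:
    """Estimated stationary noise magnitude spectrum |D| per frequency bin."""

    magnitude_spectrum: np.ndarray  # (n_bins,), >= 0
    n_frames_used: int
    power_exponent_p: int = 2

    def __post_init__(self) -> None:
        self.magnitude_spectrum = np.asarray(self.magnitude_spectrum, dtype=float)
        if np.any(self.magnitude_spectrum < 0):
            raise ValueError("noise magnitudes must be non-negative")
        if self.n_frames_used < 1:
            raise ValueError("n_frames_used must be >= 1")


@dataclass
class SegmentList:
    """Voiced intervals in sample coordinates plus the per-frame decisions."""

    segments: list  # [(start_sample, end_sample)], half-open, ordered
    frame_decisions: np.ndarray  # bool per frame
    threshold_used: float

    def __len__(self) -> int:
        return len(self.segments)

    def __iter__(self):
        return iter(self.segments)


# ---------------------------------------------------------------------------
# spectral subtraction


def estimate_noise_profile(
    signal: AudioSignal,
    params: FrameParams | None = None,
    n_noise_frames: int = 5,
    p: int = 2,
) -> NoiseProfile:
    """Average the first ``n_noise_frames`` STFT frames into a noise spectrum.

    The per-bin mean of ``|Y|^p`` over the leading frames, taken to the power
    ``1/p``.  Assumes the recording starts with (near-)pure background; pass
    a dedicated noise clip otherwise.
    """
    if p not in (1, 2):
        raise ValueError("power exponent p must be 1 or 2")
    params = params or FrameParams()
    mag = np.abs(stft_complex(signal, params))
    if mag.shape[1] < n_noise_frames:
        raise ValueError(
            f"signal yields only {mag.shape[1]} frames; "
            f"use n_noise_frames <= {mag.shape[1]}"
        )
    profile = np.mean(mag[:, :n_noise_frames] ** p, axis=1) ** (1.0 / p)
    return NoiseProfile(profile, n_noise_frames, p)


def spectral_subtract(
    signal: AudioSignal,
    noise: NoiseProfile,
    params: FrameParams | None = None,
    floor_beta: float = 0.0,
) -> AudioSignal:
    """Subtract a noise spectrum from every frame and resynthesise.

    Per frame ``|X|^p = max(|Y|^p - |D|^p, floor_beta |D|^p)`` with the noisy
    phase reused; ``floor_beta = 0`` is plain half-wave rectification, small
    positive values suppress musical noise.  Output has the input's length.
    """
    if floor_beta < 0:
        raise ValueError("floor_beta must be >= 0")
    params = params or FrameParams()
    stft = stft_complex(signal, params)
    if stft.shape[0] != len(noise.magnitude_spectrum):
        raise ValueError(
            f"noise profile has {len(noise.magnitude_spectrum)} bins but the "
            f"frame length implies {stft.shape[0]}"
        )
    p = noise.power_exponent_p
    mag_p = np.abs(stft) ** p
    noise_p = noise.magnitude_spectrum[:, None] ** p
    clean_p = np.maximum(mag_p - noise_p, floor_beta * noise_p)
    phase = np.exp(1j * np.angle(stft))
    clean = istft(clean_p ** (1.0 / p) * phase, params, len(signal))
    return AudioSignal(clean, signal.sample_rate, source_id=signal.source_id, meta=dict(signal.meta))


# ---------------------------------------------------------------------------
# endpoint detection


def short_time_energy(frames: np.ndarray) -> np.ndarray:
    """Per-frame energy ``E_t = sum_n |x[n]|^2``."""
    frames = np.atleast_2d(np.asarray(frames, dtype=float))
    return np.sum(frames**2, axis=1)


def zero_crossing_rate(frames: np.ndarray) -> np.ndarray:
    """Per-frame sign-change count ``Z_t = 1/2 sum_n |sgn x[n] - sgn x[n-1]|``.

    ``sgn(0)`` is taken as +1 so that silent frames score zero crossings.
    """
    frames = np.atleast_2d(np.asarray(frames, dtype=float))
    if frames.shape[1] < 2:
        raise ValueError("frames must hold at least 2 samples")
    sgn = np.where(frames >= 0, 1.0, -1.0)
    return 0.5 * np.sum(np.abs(np.diff(sgn, axis=1)), axis=1)


def _minmax(x: np.ndarray) -> np.ndarray:
    span = x.max() - x.min()
    if span <= 0:
        return np.zeros_like(x)
    return (x - x.min()) / span


def _runs_to_segments(
    voiced: np.ndarray, params: FrameParams, n_samples: int, min_segment_frames: int
) -> list:
    segments = []
    fl, hop = params.frame_length, params.hop_length
    offset = -(fl // 2) if params.center else 0
    i = 0
    while i < len(voiced):
        if voiced[i]:
            j = i
            while j + 1 < len(voiced) and voiced[j + 1]:
                j += 1
            if j - i + 1 >= min_segment_frames:
                start = max(0, i * hop + offset)
                end = min(n_samples, j * hop + offset + fl)
                segments.append((start, end))
            else:
                voiced[i : j + 1] = False
            i = j + 1
        else:
            i += 1
    return segments


def detect_endpoints(
    signal: AudioSignal,
    params: FrameParams | None = None,
    energy_weight: float = 0.5,
    min_segment_frames: int = 3,
    or_mode: bool = False,
) -> SegmentList:
    """Partition a recording into voiced segments and silence.

    The default rule thresholds the weighted combination
    ``s = w norm(E) + (1 - w) norm(Z)`` at ``mean(s) + 0.5 std(s)``; voiced
    runs shorter than ``min_segment_frames`` are discarded.  ``or_mode``
    instead thresholds energy and zero-crossing rate separately and marks a
    frame voiced when either exceeds its own mean + 0.5 std.  Min-max
    normalisation makes the decision invariant to global gain.
    """
    if not 0.0 <= energy_weight <= 1.0:
        raise ValueError("energy_weight must lie in [0, 1]")
    params = params or FrameParams()
    frames = frame_signal(signal, params)
    if frames.shape[0] < 2:
        raise ValueError("signal yields fewer than 2 frames")
    e = _minmax(short_time_energy(frames))
    z = _minmax(zero_crossing_rate(frames))

    if or_mode:
        voiced = np.zeros(frames.shape[0], dtype=bool)
        thr = np.nan
        for feat in (e, z):
            if feat.std() <= 0:
                continue
            t = feat.mean() + 0.5 * feat.std()
            voiced |= feat > t
            thr = t  # last computed, kept for reporting
        if not voiced.any():
            logger.warning("no voiced frames found (constant features?)")
    else:
        s = energy_weight * e + (1.0 - energy_weight) * z
        if s.std() <= 0:
            warnings.warn("constant energy/ZCR features; classifying all frames silent")
            return SegmentList([], np.zeros(frames.shape[0], dtype=bool), float("nan"))
        thr = s.mean() + 0.5 * s.std()
        voiced = s > thr
    segments = _runs_to_segments(voiced, params, len(signal), min_segment_frames)
    return SegmentList(segments, voiced, float(thr))


# ---------------------------------------------------------------------------
# augmentation


def _phase_vocoder(stft: np.ndarray, hop: int, frame_length: int, speed: float) -> np.ndarray:
    """Resample an STFT along time by ``speed`` with phase accumulation."""
    n_bins, n_frames = stft.shape
    steps = np.arange(0, n_frames, speed)
    expected = 2.0 * np.pi * hop * np.arange(n_bins) / frame_length
    padded = np.pad(stft, [(0, 0), (0, 2)])
    out = np.zeros((n_bins, len(steps)), dtype=complex)
    phase = np.angle(stft[:, 0])
    for t, step in enumerate(steps):
        i = int(step)
        frac = step - i
        mag = (1 - frac) * np.abs(padded[:, i]) + frac * np.abs(padded[:, i + 1])
        out[:, t] = mag * np.exp(1j * phase)
        dphi = np.angle(padded[:, i + 1]) - np.angle(padded[:, i]) - expected
        dphi -= 2.0 * np.pi * np.round(dphi / (2.0 * np.pi))
        phase = phase + expected + dphi
    return out


def time_stretch(
    signal: AudioSignal,
    speed: float,
    params: FrameParams | None = None,
    pitch_preserving: bool = True,
) -> AudioSignal:
    """Change a signal's duration by ``1/speed`` while keeping its pitch.

    ``speed > 1`` shortens (speeds up), ``speed < 1`` lengthens; the
    recommended augmentation range is [0.8, 1.2].  The default path is a
    phase vocoder; ``pitch_preserving=False`` falls back to plain resampling,
    which shifts pitch and is provided for comparison only.
    """
    if speed <= 0:
        raise ValueError("speed must be positive")
    target = int(round(len(signal) / speed))
    if not pitch_preserving:
        up, down = max(1, int(round(1000 / speed))), 1000
        y = resample_poly(signal.samples, up, down)
    else:
        params = params or FrameParams(frame_length=1024, hop_length=256)
        stft = stft_complex(signal, params)
        if stft.shape[1] < 2:
            y = signal.samples.copy()
        else:
            stretched = _phase_vocoder(stft, params.hop_length, params.frame_length, speed)
            y = istft(stretched, params, target)
    if len(y) < target:
        y = np.concatenate([y, np.zeros(target - len(y))])
    meta = dict(signal.meta, stretch_speed=speed)
    return AudioSignal(y[:target], signal.sample_rate, source_id=signal.source_id, meta=meta)


def time_shift(signal: AudioSignal, tau_ms: float) -> AudioSignal:
    """Displace a signal in time by ``tau_ms``, zero-filling vacated samples.

    Positive tau delays the start; negative advances it.  Output length
    equals input length, so up to ``|tau|`` of content falls off one end.
    """
    shift = int(round(tau_ms * signal.sample_rate / 1000.0))
    n = len(signal)
    if abs(shift) > n:
        raise ValueError(f"|tau| = {abs(tau_ms)} ms exceeds the signal duration")
    y = np.zeros(n)
    if shift >= 0:
        y[shift:] = signal.samples[: n - shift]
    else:
        y[: n + shift] = signal.samples[-shift:]
    meta = dict(signal.meta, shift_ms=tau_ms)
    return AudioSignal(y, signal.sample_rate, source_id=signal.source_id, meta=meta)


def augment_to_minimum(
    signals: list,
    min_total_seconds: float,
    seed: int = 0,
    stretch_range: tuple = (0.8, 1.2),
    shift_range_ms: tuple = (0.0, 100.0),
) -> list:
    """Grow a class's audio pool to a minimum total duration.

    Originals are kept; seeded random stretch/shift copies are appended until
    the summed duration reaches ``min_total_seconds``.  Each derived signal
    records its parameters in ``meta['stretch_speed']`` / ``meta['shift_ms']``.
    """
    if not signals:
        raise ValueError("need at least one input signal")
    rng = np.random.default_rng(seed)
    out = list(signals)
    total = sum(s.duration for s in out)
    i = 0
    while total < min_total_seconds:
        base = signals[i % len(signals)]
        speed = rng.uniform(*stretch_range)
        tau = rng.uniform(*shift_range_ms)
        aug = time_shift(time_stretch(base, speed), tau)
        aug.source_id = f"{base.source_id}#aug{len(out) - len(signals)}"
        out.append(aug)
        total += aug.duration
        i += 1
    return out


# ---------------------------------------------------------------------------
# estimator wrappers


class SpectralSubtractor(BaseEstimator, TransformerMixin):
    """Noise-spectrum estimating denoiser with a fit/transform interface.

    ``fit`` estimates the noise profile from the leading frames of the given
    signal (or an explicit noise clip); ``transform`` subtracts it from one
    or many signals.
    """

    def __init__(
        self,
        frame_length: int = 1024,
        hop_length: int = 512,
        window: str = "hann",
        center: bool = True,
        n_noise_frames: int = 5,
        p: int = 2,
        floor_beta: float = 0.0,
    ):
        self.frame_length = frame_length
        self.hop_length = hop_length
        self.window = window
        self.center = center
        self.n_noise_frames = n_noise_frames
        self.p = p
        self.floor_beta = floor_beta

    def _frame_params(self) -> FrameParams:
        return FrameParams(self.frame_length, self.hop_length, self.window, self.center)

    def fit(self, X, y=None):
        sig = X[0] if isinstance(X, (list, tuple)) else X
        self.noise_profile_ = estimate_noise_profile(
            sig, self._frame_params(), self.n_noise_frames, self.p
        )
        return self

    def transform(self, X):
        if not hasattr(self, "noise_profile_"):
            raise RuntimeError("SpectralSubtractor must be fitted before transform")
        params = self._frame_params()
        if isinstance(X, AudioSignal):
            return spectral_subtract(X, self.noise_profile_, params, self.floor_beta)
        return [spectral_subtract(s, self.noise_profile_, params, self.floor_beta) for s in X]


class EndpointDetector(BaseEstimator, TransformerMixin):
    """Energy/ZCR voice-activity detector returning :class:`SegmentList`."""

    def __init__(
        self,
        frame_length: int = 1024,
        hop_length: int = 512,
        window: str = "hann",
        center: bool = False,
        energy_weight: float = 0.5,
        min_segment_frames: int = 3,
        or_mode: bool = False,
    ):
        self.frame_length = frame_length
        self.hop_length = hop_length
        self.window = window
        self.center = center
        self.energy_weight = energy_weight
        self.min_segment_frames = min_segment_frames
        self.or_mode = or_mode

    def fit(self, X=None, y=None):
        return self

    def transform(self, X):
        params = FrameParams(self.frame_length, self.hop_length, self.window, self.center)
        if isinstance(X, AudioSignal):
            return detect_endpoints(
                X, params, self.energy_weight, self.min_segment_frames, self.or_mode
            )
        return [
            detect_endpoints(s, params, self.energy_weight, self.min_segment_frames, self.or_mode)
            for s in X
        ]
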