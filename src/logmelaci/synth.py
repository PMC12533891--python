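"""Seeded synthetic audio: tones, chirp syllable trains, noise, diel datasets.

Real dawn-chorus corpora are large and uncontrolled; these generators produce
miniature stand-ins with *exact* ground truth.  A "species" is a family of
linear-FM chirp syllables (a frequency band and sweep) repeated at a
characteristic rate; a recording is a train of such syllables with seeded
onset jitter, optionally buried in white or pink noise at a requested SNR.
The diel dataset applies per-period syllable-rate multipliers (default
dawn 3x > night 2x > noon 1x, mirroring the wild dawn-chorus pattern) so that
rhythm-sensitive indices have a constructed ordering to recover.  Everything
is a pure function of its spec: same spec, bit-identical audio.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import chirp as _scipy_chirp
from scipy.signal import get_window

from .audio_io import AudioSignal

__all__ = [
    "SyllableTrainSpec",
    "DielDatasetSpec",
    "GroundTruth",
    "gen_tone",
    "gen_chirp_train",
    "add_noise",
    "gen_diel_dataset",
    "DEFAULT_DIEL_REGIME",
]

#: per-period (syllable-rate multiplier, SNR in dB): dawn busiest and
#: cleanest, noon sparsest and noisiest.
DEFAULT_DIEL_REGIME = {
    "dawn": (3.0, 25.0),
    "night": (2.0, 20.0),
    "noon": (1.0, 15.0),
}


@dataclass
class SyllableTrainSpec:
    """Parameters of one chirp-train recording.

    ``syllable_rate`` is events/s; each syllable sweeps ``f_start`` to
    ``f_end`` Hz over ``syllable_dur`` s under a Hann envelope.
    ``jitter_frac`` displaces each onset by up to that fraction of the
    inter-onset interval (uniform, seeded).
    """

    syllable_rate: float = 4.0
    f_start: float = 2000.0
    f_end: float = 3500.0
    syllable_dur: float = 0.1
    amplitude: float = 0.5
    jitter_frac: float = 0.0
    duration: float = 3.0
    sample_rate: int = 22050
    seed: int = 0
    envelope: str = "hann"  # "hann" (soft onsets) or "tukey" (fast attack)
    taper_frac: float = 0.1  # Tukey taper as a fraction of the syllable

    def __post_init__(self) -> None:
        if self.envelope not in ("hann", "tukey"):
            raise ValueError("envelope must be 'hann' or 'tukey'")
        if min(self.syllable_rate, self.syllable_dur, self.duration) <= 0:
            raise ValueError("rate and durations must be positive")
        if self.syllable_rate * self.syllable_dur > 1.0:
            raise ValueError("syllables do not fit: need rate * dur <= 1")
        if not 0.0 <= self.jitter_frac < 0.5:
            raise ValueError("jitter_frac must lie in [0, 0.5)")


@dataclass
class DielDatasetSpec:
    """Layout of a labelled dawn/noon/night corpus of chirp trains."""

    n_species: int = 3
    n_recordings_per_group: int = 5
    regime: dict = field(default_factory=lambda: dict(DEFAULT_DIEL_REGIME))
    base_specs: list | None = None  # one SyllableTrainSpec per species
    duration: float = 3.0
    sample_rate: int = 22050
    seed: int = 7

    def __post_init__(self) -> None:
        if set(self.regime) != {"dawn", "noon", "night"}:
            raise ValueError("regime must map exactly dawn, noon and night")
        if any(mult <= 0 for mult, _ in self.regime.values()):
            raise ValueError("rate multipliers must be positive")


@dataclass
class GroundTruth:
    """Exact construction-time truth for a generated recording or dataset."""

    segments: list  # [(start_sample, end_sample)] half-open syllable supports
    labels: list = field(default_factory=list)  # [(species, period)] per recording
    generator_params: object = None


def gen_tone(
    freq: float, duration: float, sample_rate: int = 22050, amplitude: float = 0.5
) -> AudioSignal:
    """Pure sinusoid ``amplitude * sin(2 pi f t)`` of exact rounded length."""
    if not 0 < freq < sample_rate / 2:
        raise ValueError(f"frequency {freq} Hz aliases at sample rate {sample_rate}")
    n = int(round(duration * sample_rate))
    t = np.arange(n) / sample_rate
    return AudioSignal(
        amplitude * np.sin(2 * np.pi * freq * t), sample_rate, source_id=f"tone:{freq}Hz"
    )


def gen_chirp_train(spec: SyllableTrainSpec):
    """Train of Hann-enveloped linear-FM syllables with seeded onset jitter.

    Returns ``(AudioSignal, GroundTruth)``; the ground-truth segments are the
    exact sample supports of the syllables, and the signal is identically
    zero outside them.
    """
    rng = np.random.default_rng(spec.seed)
    sr = spec.sample_rate
    n = int(round(spec.duration * sr))
    x = np.zeros(n)

    interval = 1.0 / spec.syllable_rate
    n_syll = int(np.floor(spec.duration * spec.syllable_rate))
    syl_n = int(round(spec.syllable_dur * sr))
    t_syl = np.arange(syl_n) / sr
    if spec.envelope == "tukey":
        envelope = get_window(("tukey", spec.taper_frac), syl_n, fftbins=False)
    else:
        envelope = get_window("hann", syl_n, fftbins=False)

    segments = []
    for k in range(n_syll):
        onset = k * interval
        if spec.jitter_frac > 0:
            onset += rng.uniform(-spec.jitter_frac, spec.jitter_frac) * interval
        onset = min(max(onset, 0.0), spec.duration - spec.syllable_dur)
        start = int(round(onset * sr))
        # seeded per-syllable sweep keeps trains from being exact copies
        f0 = spec.f_start * (1.0 + 0.02 * rng.standard_normal())
        syl = _scipy_chirp(t_syl, f0=f0, f1=spec.f_end, t1=spec.syllable_dur, method="linear")
        stop = min(start + syl_n, n)
        x[start:stop] += spec.amplitude * (envelope * syl)[: stop - start]
        segments.append((start, stop))

    signal = AudioSignal(
        x, sr, source_id=f"chirp_train:rate={spec.syllable_rate}/s,seed={spec.seed}"
    )
    return signal, GroundTruth(segments=segments, generator_params=spec)


def add_noise(signal: AudioSignal, kind: str = "white", snr_db: float = 20.0, seed: int = 0) -> AudioSignal:
    """Add seeded white or pink noise at a requested signal-to-noise ratio.

    The noise is scaled so ``10 log10(P_signal / P_noise) = snr_db`` over the
    whole recording.  ``snr_db = inf`` returns the input unchanged.
    """
    if np.isinf(snr_db) and snr_db > 0:
        return signal
    p_signal = float(np.mean(signal.samples**2))
    if p_signal <= 0:
        raise ValueError("cannot set a finite SNR on a silent signal")
    rng = np.random.default_rng(seed)
    n = len(signal)
    noise = rng.standard_normal(n)
    if kind == "pink":
        # shape the white spectrum by 1/sqrt(f) => 1/f power
        spec = np.fft.rfft(noise)
        f = np.fft.rfftfreq(n, d=1.0 / signal.sample_rate)
        f[0] = f[1] if len(f) > 1 else 1.0
        noise = np.fft.irfft(spec / np.sqrt(f), n=n)
    elif kind != "white":
        raise ValueError("noise kind must be 'white' or 'pink'")
    noise *= np.sqrt(p_signal / 10 ** (snr_db / 10.0) / np.mean(noise**2))
    return AudioSignal(
        signal.samples + noise,
        signal.sample_rate,
        source_id=signal.source_id,
        meta=dict(signal.meta, noise_kind=kind, snr_db=snr_db),
    )


def _default_species_spec(i: int, duration: float, sample_rate: int) -> SyllableTrainSpec:
    return SyllableTrainSpec(
        syllable_rate=1.2 + 0.3 * i,
        f_start=2000.0 + 1500.0 * i,
        f_end=2800.0 + 1500.0 * i,
        syllable_dur=0.1,
        jitter_frac=0.2,
        duration=duration,
        sample_rate=sample_rate,
    )


def gen_diel_dataset(spec: DielDatasetSpec):
    """Labelled dawn/noon/night corpus of chirp trains with exact truth.

    Produces ``n_species * 3 * n_recordings_per_group`` recordings.  Each
    period's syllable rate is the species base rate times the regime
    multiplier, and the regime SNR of white noise is added.  Deterministic
    under ``spec.seed``; recording seeds are derived from it.
    """
    rng = np.random.default_rng(spec.seed)
    recordings = []
    labels = []
    segments = []
    for i in range(spec.n_species):
        species = f"species_{i:02d}"
        base = (
            spec.base_specs[i]
            if spec.base_specs is not None
            else _default_species_spec(i, spec.duration, spec.sample_rate)
        )
        for period in ("dawn", "noon", "night"):
            mult, snr_db = spec.regime[period]
            for r in range(spec.n_recordings_per_group):
                rec_seed = int(rng.integers(0, 2**31 - 1))
                train_spec = SyllableTrainSpec(
                    syllable_rate=base.syllable_rate * mult,
                    f_start=base.f_start,
                    f_end=base.f_end,
                    syllable_dur=base.syllable_dur,
                    amplitude=base.amplitude,
                    jitter_frac=base.jitter_frac,
                    duration=base.duration,
                    sample_rate=base.sample_rate,
                    seed=rec_seed,
                )
                clean, truth = gen_chirp_train(train_spec)
                noisy = add_noise(clean, "white", snr_db, seed=rec_seed + 1)
                noisy.source_id = f"{species}/{period}/rec{r:02d}"
                recordings.append((noisy, species, period))
                labels.append((species, period))
                segments.append(truth.segments)
    return recordings, GroundTruth(segments=segments, labels=labels, generator_params=spec)
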