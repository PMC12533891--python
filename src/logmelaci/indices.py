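"""Acoustic Complexity Index, its Log-Mel variant, and diel comparisons.

The Acoustic Complexity Index (ACI) scores how strongly sound intensity
fluctuates frame-to-frame.  In the canonical (Pieretti) ratio form, within a
clump of consecutive frames each frequency bin b contributes

    D_b = sum_t |I_b(t+1) - I_b(t)|,      ACI = sum_b D_b / sum_t I_b(t),

so rapidly modulated biophony scores high while steady drones score low, and
the ratio cancels any global gain.

The Log-Mel ACI computes the same difference-over-sum ratio per time frame on
a log(1 + x)-compressed 20-band Mel spectrogram:

    d_k(t) = |LogMel(k, t+1) - LogMel(k, t)|,
    ACI_logmel(t) = sum_k d_k(t) / sum_k LogMel(k, t).

The Mel warping concentrates resolution where bird vocalisations live and the
log compression amplifies weak-signal dynamics, making the index sensitive to
rhythm (syllable rate, call intervals) rather than raw loudness.  Unlike the
traditional ACI it is *not* invariant to amplitude scaling, because
log(1 + c x) is not log(1 + x) plus a constant.

:func:`compare_periods` aggregates either index over recordings labelled with
a diel period (dawn / noon / night) to expose circadian vocal rhythm — the
typical wild pattern being highest at dawn, intermediate at night, lowest at
noon.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .audio_io import AudioSignal, FrameParams
from .features import (
    LogMelSpectrogram,
    Spectrogram,
    log_compress,
    mel_filterbank,
    mel_spectrogram,
    stft_magnitude,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ACISeries",
    "DielComparison",
    "aci_traditional",
    "logmel_aci_frames",
    "logmel_aci",
    "compare_periods",
    "TraditionalACI",
    "LogMelACI",
]

PERIODS = ("dawn", "noon", "night")
_SILENT_EPS = 1e-12


@dataclass
class ACISeries:
    """Per-frame (or per-clump) index values plus a recording-level aggregate."""

    per_frame: np.ndarray
    aggregate: float
    index_kind: str  # "traditional" | "logmel"
    aggregation: str  # "mean" | "sum"
    n_frames: int
    n_silent_frames: int = 0


@dataclass
class DielComparison:
    """Group statistics of an index across (species, period) cells."""

    per_group: dict  # (species, period) -> (mean, count, std)
    orderings: dict  # species -> [periods sorted by descending mean]
    index_kind: str

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"species": sp, "period": per, "mean": m, "count": c, "std": s}
            for (sp, per), (m, c, s) in sorted(self.per_group.items())
        ]
        return pd.DataFrame(rows)

    def normalized_spread(self) -> float:
        """Mean over species of (max - min period mean) / pooled within-group std.

        A dimensionless between-period effect size: how far apart the diel
        period means sit relative to within-period variability.
        """
        spreads = []
        for sp in self.orderings:
            stats = [self.per_group[(sp, per)] for per in PERIODS if (sp, per) in self.per_group]
            if len(stats) < 2:
                continue
            means = [m for m, _, _ in stats]
            pooled = np.sqrt(np.mean([s**2 for _, _, s in stats]))
            if pooled <= 0:
                pooled = _SILENT_EPS
            spreads.append((max(means) - min(means)) / pooled)
        return float(np.mean(spreads)) if spreads else 0.0


def _aggregate(values: np.ndarray, how: str) -> float:
    if how == "mean":
        return float(np.mean(values)) if len(values) else 0.0
    if how == "sum":
        return float(np.sum(values))
    raise ValueError("aggregation must be 'mean' or 'sum'")


def aci_traditional(
    spec: Spectrogram | np.ndarray,
    clump_frames: int | None = None,
    aggregation: str = "mean",
    literal_product: bool = False,
) -> ACISeries:
    """Traditional ACI over an intensity spectrogram.

    The spectrogram is split into clumps of ``clump_frames`` consecutive
    frames (default: the whole recording is one clump) and the
    difference-over-sum ratio accumulated per bin within each clump.  Bins
    whose intensity sum is (near) zero contribute 0.  ``literal_product``
    switches to the product form D * sum(I) for auditability; it is not the
    established index and is off by default.
    """
    intensity = spec.magnitude if isinstance(spec, Spectrogram) else np.asarray(spec, dtype=float)
    intensity = np.atleast_2d(intensity)
    n_frames = intensity.shape[1]
    if n_frames < 2:
        raise ValueError("need at least 2 frames to difference")
    if clump_frames is None:
        clump_frames = n_frames
    if clump_frames < 2:
        raise ValueError("clump_frames must be >= 2")

    values = []
    for start in range(0, n_frames, clump_frames):
        block = intensity[:, start : start + clump_frames]
        if block.shape[1] < 2:
            break  # trailing partial clump with nothing to difference
        d = np.sum(np.abs(np.diff(block, axis=1)), axis=1)  # per bin
        sums = np.sum(block, axis=1)
        if literal_product:
            values.append(float(np.sum(d) * np.sum(sums)))
        else:
            ok = sums > _SILENT_EPS
            values.append(float(np.sum(d[ok] / sums[ok])))
    per_clump = np.asarray(values)
    return ACISeries(
        per_clump, _aggregate(per_clump, aggregation), "traditional", aggregation, n_frames
    )


def logmel_aci_frames(lm: LogMelSpectrogram | np.ndarray, aggregation: str = "mean") -> ACISeries:
    """Per-frame Log-Mel ACI: sum_k |dLogMel| / sum_k LogMel, one value per
    frame transition t = 0..T-2.

    Frames whose Log-Mel band sum is below 1e-12 (silence) yield 0 rather
    than dividing; their count is reported in ``n_silent_frames``.
    """
    values = lm.values if isinstance(lm, LogMelSpectrogram) else np.asarray(lm, dtype=float)
    values = np.atleast_2d(values)
    n_frames = values.shape[1]
    if n_frames < 2:
        raise ValueError("need at least 2 frames to difference")
    d = np.sum(np.abs(np.diff(values, axis=1)), axis=0)  # (T-1,)
    denom = np.sum(values[:, :-1], axis=0)  # frame t of each (t, t+1) pair
    silent = denom < _SILENT_EPS
    out = np.zeros(n_frames - 1)
    out[~silent] = d[~silent] / denom[~silent]
    return ACISeries(
        out, _aggregate(out, aggregation), "logmel", aggregation, n_frames, int(silent.sum())
    )


def logmel_aci(
    signal: AudioSignal,
    params: FrameParams | None = None,
    n_mels: int = 20,
    fmin_hz: float = 0.0,
    fmax_hz: float | None = None,
    aggregation: str = "mean",
) -> ACISeries:
    """Full Log-Mel ACI chain on an audio signal.

    STFT magnitude -> 20-band Mel projection -> log(1 + x) -> per-frame
    difference-over-sum ratio -> recording-level aggregate.
    """
    params = params or FrameParams()
    spec = stft_magnitude(signal, params)
    fb = mel_filterbank(n_mels, params.frame_length, signal.sample_rate, fmin_hz, fmax_hz)
    lm = log_compress(mel_spectrogram(spec, fb))
    return logmel_aci_frames(lm, aggregation)


def compare_periods(
    recordings: list,
    index_kind: str = "logmel",
    params: FrameParams | None = None,
    n_mels: int = 20,
    aggregation: str = "mean",
    clump_frames: int | None = None,
) -> DielComparison:
    """Group-aggregate an index over (species, diel period) labelled audio.

    ``recordings`` is a list of ``(AudioSignal, species, period)`` triples
    with period in {dawn, noon, night}.  Returns per-group mean/count/std of
    the recording aggregates and, per species, the periods ordered by
    descending mean.  Empty groups are simply absent (with a warning when a
    species misses a period).
    """
    params = params or FrameParams()
    by_group: dict = {}
    for signal, species, period in recordings:
        if period not in PERIODS:
            raise ValueError(f"unknown diel period {period!r}; expected one of {PERIODS}")
        if index_kind == "logmel":
            series = logmel_aci(signal, params, n_mels=n_mels, aggregation=aggregation)
        elif index_kind == "traditional":
            series = aci_traditional(
                stft_magnitude(signal, params), clump_frames=clump_frames, aggregation=aggregation
            )
        else:
            raise ValueError("index_kind must be 'logmel' or 'traditional'")
        by_group.setdefault((species, period), []).append(series.aggregate)

    per_group = {
        key: (float(np.mean(v)), len(v), float(np.std(v))) for key, v in by_group.items()
    }
    species_names = sorted({sp for sp, _ in per_group})
    orderings = {}
    for sp in species_names:
        present = [per for per in PERIODS if (sp, per) in per_group]
        missing = set(PERIODS) - set(present)
        if missing:
            logger.warning("species %s has no recordings for periods %s", sp, sorted(missing))
        orderings[sp] = sorted(present, key=lambda per: per_group[(sp, per)][0], reverse=True)
    return DielComparison(per_group, orderings, index_kind)


# ---------------------------------------------------------------------------
# estimator wrappers


class _ACIScorer(BaseEstimator, TransformerMixin):
    """Maps (lists of) AudioSignal to recording-level index aggregates."""

    def fit(self, X=None, y=None):
        return self

    def transform(self, X):
        if isinstance(X, AudioSignal):
            return self.score_signal(X).aggregate
        return np.array([self.score_signal(s).aggregate for s in X])

    def _frame_params(self) -> FrameParams:
        return FrameParams(self.frame_length, self.hop_length, self.window, self.center)


class TraditionalACI(_ACIScorer):
    """Canonical difference-over-sum ACI on the linear STFT magnitude."""

    def __init__(
        self,
        frame_length: int = 1024,
        hop_length: int = 512,
        window: str = "hann",
        center: bool = True,
        clump_frames: int | None = None,
        aggregation: str = "mean",
    ):
        self.frame_length = frame_length
        self.hop_length = hop_length
        self.window = window
        self.center = center
        self.clump_frames = clump_frames
        self.aggregation = aggregation

    def score_signal(self, signal: AudioSignal) -> ACISeries:
        spec = stft_magnitude(signal, self._frame_params())
        return aci_traditional(spec, self.clump_frames, self.aggregation)


class LogMelACI(_ACIScorer):
    """Per-frame ACI on the log(1 + x)-compressed Mel spectrogram."""

    def __init__(
        self,
        n_mels: int = 20,
        frame_length: int = 1024,
        hop_length: int = 512,
        window: str = "hann",
        center: bool = True,
        fmin_hz: float = 0.0,
        fmax_hz: float | None = None,
        aggregation: str = "mean",
    ):
        self.n_mels = n_mels
        self.frame_length = frame_length
        self.hop_length = hop_length
        self.window = window
        self.center = center
        self.fmin_hz = fmin_hz
        self.fmax_hz = fmax_hz
        self.aggregation = aggregation

    def score_signal(self, signal: AudioSignal) -> ACISeries:
        return logmel_aci(
            signal,
            self._frame_params(),
            n_mels=self.n_mels,
            fmin_hz=self.fmin_hz,
            fmax_hz=self.fmax_hz,
            aggregation=self.aggregation,
        )
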