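# Methods

This note documents the models and procedures the package implements, the
defaults and why they were chosen, what the synthetic fixtures do and do not
emulate, and the numerical choices a maintainer would otherwise have to
reverse-engineer.

## Analysis configuration

All short-time analysis runs through one `FrameParams` bundle: sample rate
22 050 Hz, frame length 1024 samples (≈46 ms), hop 512 (50 % overlap), Hann
window, centre padding on. These are standard bioacoustics defaults; every
operation is configuration-parametric, so tests pin their own values where a
property depends on them (e.g. endpoint tests use 512/256 without centring
so frame→sample mapping is direct).

STFT magnitude is computed by framing + windowed rFFT; the inverse uses
window-weighted overlap-add divided by the accumulated squared window, which
reconstructs exactly (to float precision) for any window/hop with full
coverage — not just constant-overlap-add pairs. Zero-noise spectral
subtraction is therefore the identity to < 1e-6.

## Spectral subtraction

Per frame, `|X|^p = max(|Y|^p − |D|^p, β·|D|^p)` with the noisy phase
reused, `p ∈ {1, 2}` (amplitude vs power subtraction, default 2). The noise
spectrum `|D|` is the per-bin mean of `|Y|^p` over the leading frames
(default 5), raised to `1/p` — an explicit, replaceable step so callers can
supply a dedicated noise clip. The spectral floor β defaults to 0
(half-wave rectification); small positive values trade residual noise for
less musical noise.

Scope and behaviour worth knowing:

* On a *deterministic* stationary background (machine hum, steady drone)
  self-subtraction removes almost everything: residual RMS ≈ 13 % of input
  with p = 2 and ≈ 3 % with p = 1 on the harmonic-hum fixture.
* On *stochastic* stationary noise (white noise) the per-frame spectrum
  fluctuates around the estimated mean, and half-wave-rectified subtraction
  leaves a theoretical power fraction of about `1/e` (residual RMS ≈ 60 %)
  — the classic musical-noise regime. The method targets steady
  backgrounds; non-stationary suppression is explicitly out of scope.

## Endpoint detection

Frames are scored by short-time energy `E_t = Σ|x[n]|²` and zero-crossing
rate `Z_t = ½ Σ|sgn x[n] − sgn x[n−1]|` with `sgn(0) = +1` (so silence has
zero crossings). Both are min-max normalised over the whole recording —
making the decision invariant to global gain — and combined as
`s = w·norm(E) + (1−w)·norm(Z)` with w = 0.5. The threshold is
`mean(s) + 0.5·std(s)`; voiced runs shorter than 3 frames are discarded.
An `or_mode` thresholds the two features separately (voiced if either
exceeds its own mean + 0.5·std), since both decision rules are defensible;
the combined rule is the default because the threshold statistic is defined
on the weighted average.

A physical caveat the fixtures expose: the ZCR of broadband *white* noise
exceeds that of a band-limited chirp, so under white noise the ZCR term
votes the wrong way. Environmental noise (wind, rain) is low-frequency, so
the boundary-recovery fixtures use pink (1/f) noise, where both features
discriminate correctly. Boundary accuracy is tested against fast-attack
(Tukey-windowed) syllables: with the default Hann syllable envelope the
acoustic onset itself is gradual (~40 ms fade), so "the" boundary is
ill-defined at the one-hop level regardless of detector.

## Augmentation

Time stretching is pitch-preserving via a phase vocoder (analysis hop 256,
frame 1024): STFT magnitudes are linearly interpolated along time at rate
`speed` while phases advance by the expected per-hop increment plus the
wrapped deviation. Output length is fixed to `round(n/speed)`. A plain
resampling mode exists for comparison but shifts pitch and is flagged as
such. Time shifting displaces by `round(τ·sr/1000)` samples and zero-fills.
`augment_to_minimum` cycles through the inputs applying seeded
stretch ∈ [0.8, 1.2] and shift ∈ [0, 100] ms until the pool reaches the
requested total duration (the workflow used to bring scarce classes up to
≥ 20 minutes), recording each copy's parameters in its metadata.

## Features

* Mel scale: HTK convention `mel(f) = 2595·log10(1 + f/700)`; 20 triangular
  filters with unit apex (area normalisation optional), centres equally
  spaced in Mel between 0 Hz and Nyquist. The band is exposed because
  narrowing it to the 1–10 kHz birdsong band is often useful; the full band
  is the neutral default.
* Log-Mel compression is natural `log(1 + x)`. The base only rescales the
  Log-Mel ACI's numerator and denominator identically per entry, so the
  per-frame index is base-invariant; the compression offset (the `1 +`) is
  not, and is kept exactly as defined.
* MFCC: DCT-II over `log(E_m + ε)`, ε = 1e-10, 13 coefficients from 20
  bands. This log is deliberately different from the Log-Mel's
  `log(1 + x)`; the two conventions serve different stages and are kept
  separate. Deltas use the regression form
  `Σ n·C_{t+n} / (2 Σ n²)`, N = 1 by default (N = 2 supported), with
  replicate-padded edges so output length equals input length; delta-delta
  is delta applied twice.

## Indices

Traditional ACI is implemented in the canonical difference-over-sum ratio
form on the linear STFT *magnitude* (not power), with the whole recording
as one clump by default (recordings here are short single vocalisations);
clump length is configurable. Bins with (near-)zero intensity sum
contribute 0. A literal product form `D·ΣI` is available behind
`literal_product=True` for auditability only.

Log-Mel ACI: per frame transition t, `Σ_k d_k(t) / Σ_k LogMel(k, t)` — the
denominator uses frame t of the (t, t+1) pair, per the definition as
written. Frames whose band sum is below 1e-12 yield 0 instead of dividing
and are counted (`n_silent_frames`). The recording-level aggregate is the
mean over frame values by default (duration-invariant, which cross-period
comparison needs); sum is available.

In perfectly noise-free audio the Log-Mel denominator collapses between
syllables and near-silent transition frames produce arbitrarily large
ratios; any realistic noise floor stabilises it. Field recordings always
carry a floor, and the synthetic fixtures therefore add one (see below).

`compare_periods` aggregates per (species, period) cell — mean, count, std
of the recording aggregates — and orders each species' periods by mean. The
between-period effect size reported is `(max − min of period means) /
pooled within-group std`, averaged over species.

## Synthetic fixtures

A "species" is a family of linear-FM chirp syllables (band, sweep, base
rate); a recording is a jittered train of Hann- (or fast-attack Tukey-)
enveloped syllables over silence, plus seeded white or pink noise scaled to
a requested SNR (accurate to < 0.1 dB). Ground truth (syllable supports,
labels, generator parameters) is exact by construction. All generators are
pure functions of their spec.

The default diel regime applies syllable-rate multipliers dawn 3× >
night 2× > noon 1× with SNR 25/20/15 dB respectively — busier periods
recorded cleaner — so the wild dawn-chorus ordering is constructed into the
data; a null regime (identical periods) is used to check that the indices
report no ordering beyond noise. Default corpus: 3 species × 3 periods × 5
recordings of 3 s at 22 050 Hz (45 recordings, ≈ 2.5 min of audio), sized
so the full chain runs in seconds.

What the fixtures do **not** emulate: harmonic stacks and formants of real
birdsong, overlapping singers, reverberation, non-stationary weather noise,
recorder frequency responses. Passing tests show the chain's mathematics
and its sensitivity to rhythm/SNR structure, not field-robustness.

## Classification

Recordings are pooled to fixed-length vectors — per-row mean and std of the
static/delta/delta-delta MFCC matrices (13 × 3 × 2 = 78 values) — and split
8:2 stratified on the joint (species, period) label. The two-layer model
fits one species classifier on everything and one period classifier per
species; prediction routes through layer 1, so a species error sends the
sample to the wrong period model (the routing is reported). The layer
classifier is pluggable; the default is 1-nearest-neighbour, which
memorises separable data and keeps the benchmark about the features, not
the learner. Metrics are one-vs-rest accuracy/precision/recall/F1 per
class, macro-averaged by default (F1 from the averaged precision and
recall); micro pools counts, and micro accuracy equals the plain fraction
correct.

## Problem sizes

The test suite and `scripts/acceptance.py` use: 45-recording diel corpora,
3 × 6 s endpoint fixtures (~27 syllables), 3 s rhythm fixtures at 2/5/10
syllables/s, 2 s tones and hums, and brute-force oracles on matrices up to
20 × 50. The whole suite runs in a few seconds on one CPU.

## Known limitations

* Spectral subtraction leaves musical-noise residue on stochastic
  backgrounds (inherent to half-wave-rectified subtraction).
* The Log-Mel ACI is not gain-invariant (`log(1 + cx) ≠ log(1 + x) + c'`);
  comparisons should use recordings at comparable calibration, or rely on
  the traditional index when gain varies wildly.
* Endpoint boundaries are only as sharp as the sounds' onsets; soft-attack
  envelopes bias detected boundaries inward by a window-scale amount.
* The phase vocoder smears transients slightly at large stretch factors;
  within the 0.8–1.2 augmentation range this is negligible for pooled
  features.
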