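# logmelaci

Eco-acoustic analysis of bird vocalizations: spectral-subtraction denoising,
energy/zero-crossing endpoint detection, stretch/shift augmentation,
Log-Mel and second-order MFCC features, the Acoustic Complexity Index (ACI)
and its Log-Mel variant, and a two-layer species → diel-period recognition
framework — with seeded synthetic fixtures (chirp syllable trains with exact
ground truth) standing in for field recordings.

## The problem

Birds vocalize with a circadian rhythm: most species sing hardest at dawn,
least around noon, with partial recovery at night. Quantifying that rhythm
from recordings needs an index that responds to the *temporal structure* of
vocal activity (syllable rate, call intervals) rather than to loudness. The
classical ACI does this on a linear spectrogram: within a window, each
frequency bin $b$ contributes the ratio of summed frame-to-frame intensity
changes to summed intensity,

$$\mathrm{ACI} = \sum_b \frac{\sum_t \lvert I_b(t{+}1) - I_b(t)\rvert}{\sum_t I_b(t)},$$

which cancels global gain but is weakly sensitive to the faint, Mel-scale
structured dynamics of single vocalizations.

The **Log-Mel ACI** computes the same difference-over-sum ratio per time
frame on a log-compressed 20-band Mel spectrogram. With
$\mathrm{LogMel}(k,t) = \log\!\big(1 + \mathrm{Mel}(k,t)\big)$ and
$d_k(t) = \lvert \mathrm{LogMel}(k,t{+}1) - \mathrm{LogMel}(k,t)\rvert$,

$$\mathrm{ACI}_{\text{Log-Mel}}(t) = \frac{\sum_k d_k(t)}{\sum_k \mathrm{LogMel}(k,t)}.$$

The Mel warping concentrates resolution in the bands where birdsong lives
and the log compression amplifies weak-signal dynamics, so the index
separates dawn/noon/night activity far more cleanly than the linear-spectrum
ACI — at the cost of losing the traditional index's gain invariance.

## Worked example

```python
from logmelaci import compare_periods, logmel_aci
from logmelaci.synth import DielDatasetSpec, gen_diel_dataset

recs, truth = gen_diel_dataset(DielDatasetSpec(seed=7))   # 3 species x 3 periods x 5
sig, species, period = recs[0]
series = logmel_aci(sig)
print(f"{species}/{period}: Log-Mel ACI = {series.aggregate:.4f} over {series.n_frames} frames")

cmp = compare_periods(recs, "logmel")
for sp, order in cmp.orderings.items():
    print(f"{sp}: {' > '.join(order)}")
print(f"normalized between-period spread: {cmp.normalized_spread():.2f}")
```

prints

```
species_00/dawn: Log-Mel ACI = 0.1332 over 130 frames
species_00: dawn > night > noon
species_01: dawn > night > noon
species_02: dawn > night > noon
normalized between-period spread: 48.85
```

Each recording is a seeded chirp-syllable train whose per-period syllable
rate follows the dawn > night > noon regime the generator encodes; the index
recovers that ordering for every species, and the between-period spread
(max − min of period means over pooled within-group std) is an order of
magnitude larger for the Log-Mel ACI than for the traditional ACI on the
same audio (48.85 vs 5.63 here).

The same workflows are available from the shell:

```bash
logmelaci synth --preset diel --n-species 3 --n-per-group 5 --seed 7 --out-dir fixtures/
logmelaci aci --in fixtures/ --manifest fixtures/manifest.csv --index logmel --out results.csv
logmelaci report --results results.csv --out report.csv
logmelaci classify --manifest fixtures/manifest.csv --seed 42 --report metrics.json
```

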