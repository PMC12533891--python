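import numpy as np
import pytest

from logmelaci import (
    AudioSignal,
    FrameParams,
    NoiseProfile,
    SpectralSubtractor,
    augment_to_minimum,
    detect_endpoints,
    estimate_noise_profile,
    gen_tone,
    short_time_energy,
    spectral_subtract,
    time_shift,
    time_stretch,
    zero_crossing_rate,
)
from logmelaci.synth import SyllableTrainSpec, add_noise, gen_chirp_train


def rms(x):
    return np.sqrt(np.mean(np.asarray(x) ** 2))


def stationary_hum(duration=2.0, sr=22050):
    """Deterministic steady background: a stack of machine-hum harmonics."""
    t = np.arange(int(duration * sr)) / sr
    parts = [(0.3, 120.0, 0.1), (0.2, 240.0, 1.0), (0.15, 363.0, 2.2), (0.1, 991.0, 0.5)]
    x = sum(a * np.sin(2 * np.pi * f * t + ph) for a, f, ph in parts)
    return AudioSignal(x, sr, source_id="hum")


class TestShortTimeFeatures:
    def test_energy_hand_values(self):
        e = short_time_energy(np.array([[1.0, -1.0, 1.0, -1.0], [0.0, 0.0, 0.0, 0.0]]))
        assert np.array_equal(e, [4.0, 0.0])

    def test_zcr_hand_values(self):
        z = zero_crossing_rate(np.array([[1.0, -1.0, 1.0, -1.0], [0.5, 0.5, 0.5, 0.5]]))
        assert np.array_equal(z, [3.0, 0.0])

    def test_zcr_silence_is_zero(self):
        assert zero_crossing_rate(np.zeros((1, 64)))[0] == 0.0

    def test_against_brute_force_loops(self, rng):
        frames = rng.standard_normal((200, 32))
        e = short_time_energy(frames)
        z = zero_crossing_rate(frames)
        for i, frame in enumerate(frames):
            assert abs(e[i] - sum(v * v for v in frame)) < 1e-12
            sgn = [1 if v >= 0 else -1 for v in frame]
            brute = 0.5 * sum(abs(sgn[n] - sgn[n - 1]) for n in range(1, len(frame)))
            assert z[i] == brute

    def test_zcr_bounds(self, rng):
        frames = rng.choice([-1.0, 1.0], size=(50, 16))
        z = zero_crossing_rate(frames)
        assert np.all(z >= 0) and np.all(z <= 15)
        assert np.all(z == z.astype(int))


class TestSpectralSubtraction:
    def test_noise_profile_is_leading_frame_average(self, rng):
        sig = AudioSignal(rng.standard_normal(8192), 22050)
        params = FrameParams(512, 256, center=False)
        prof = estimate_noise_profile(sig, params, n_noise_frames=1, p=1)
        from logmelaci.features import stft_complex

        first = np.abs(stft_complex(sig, params))[:, 0]
        assert np.allclose(prof.magnitude_spectrum, first)

    def test_white_noise_profile_roughly_flat(self, rng):
        sig = AudioSignal(rng.standard_normal(22050 * 2), 22050)
        prof = estimate_noise_profile(sig, FrameParams(), n_noise_frames=80, p=2)
        mags = prof.magnitude_spectrum[2:-2]  # DC/Nyquist carry half-bins
        spread_db = 10 * np.log10(mags.max() / mags.min())
        assert spread_db < 12.0  # flat within a few dB at this averaging depth

    def test_leading_silence_profile_near_zero(self):
        sr = 22050
        x = np.concatenate([np.zeros(sr // 2), gen_tone(1000, 0.5, sr).samples])
        prof = estimate_noise_profile(AudioSignal(x, sr), FrameParams(center=False), 5, 2)
        assert np.max(prof.magnitude_spectrum) < 1e-10

    def test_too_few_frames_error(self):
        sig = AudioSignal(np.zeros(2048), 22050)
        with pytest.raises(ValueError, match="n_noise_frames"):
            estimate_noise_profile(sig, FrameParams(1024, 512, center=False), 100)

    def test_zero_profile_is_identity(self, random_signal, default_params):
        prof = NoiseProfile(np.zeros(default_params.n_bins), 1, 2)
        out = spectral_subtract(random_signal, prof, default_params)
        assert len(out) == len(random_signal)
        assert np.max(np.abs(out.samples - random_signal.samples)) < 1e-6

    @pytest.mark.parametrize("p", [1, 2])
    def test_self_subtraction_attenuates_stationary_noise(self, p):
        hum = stationary_hum()
        params = FrameParams()
        prof = estimate_noise_profile(hum, params, n_noise_frames=40, p=p)
        out = spectral_subtract(hum, prof, params, floor_beta=0.0)
        assert rms(out.samples) < 0.2 * rms(hum.samples)

    def test_snr_improves_on_tone_in_noise(self, rng):
        sr = 22050
        tone = gen_tone(1000, 2.0, sr)
        noisy = add_noise(tone, "white", 10.0, seed=2)
        p_noise = np.mean(tone.samples**2) / 10.0  # power of the added noise
        prefix = rng.standard_normal(sr) * np.sqrt(p_noise)
        mix = AudioSignal(np.concatenate([prefix, noisy.samples]), sr)
        params = FrameParams()
        prof = estimate_noise_profile(mix, params, n_noise_frames=30, p=2)
        den = spectral_subtract(mix, prof, params)

        from logmelaci import stft_magnitude

        def tone_snr(x):
            spec = stft_magnitude(AudioSignal(x, sr), params)
            b = int(np.argmin(np.abs(spec.bin_freqs - 1000)))
            on = (spec.magnitude[b - 1 : b + 2].sum(axis=0) ** 2).mean()
            mask = np.ones(spec.magnitude.shape[0], bool)
            mask[b - 3 : b + 4] = False
            off = (spec.magnitude[mask] ** 2).mean()
            return 10 * np.log10(on / off)

        assert tone_snr(den.samples[sr:]) > tone_snr(mix.samples[sr:])

    def test_mismatched_bins_error(self, random_signal, default_params):
        prof = NoiseProfile(np.zeros(10), 1, 2)
        with pytest.raises(ValueError, match="bins"):
            spectral_subtract(random_signal, prof, default_params)

    def test_estimator_fit_transform(self, rng):
        hum = stationary_hum()
        sub = SpectralSubtractor(n_noise_frames=40).fit(hum)
        out = sub.transform(hum)
        assert rms(out.samples) < 0.5 * rms(hum.samples)
        assert sub.get_params()["p"] == 2


class TestDetectEndpoints:
    params = FrameParams(512, 256, center=False)

    @staticmethod
    def planted(seed=0, snr_db=30.0):
        sr = 22050
        spec = SyllableTrainSpec(
            syllable_rate=2.0, syllable_dur=0.5, duration=0.5, f_start=2000.0,
            f_end=3000.0, sample_rate=sr, seed=seed, envelope="tukey",
        )
        sig, _ = gen_chirp_train(spec)
        x = np.concatenate([np.zeros(sr // 2), sig.samples, np.zeros(sr // 2)])
        return add_noise(AudioSignal(x, sr), "pink", snr_db, seed=seed + 1), (sr // 2, sr)

    def test_threshold_arithmetic(self):
        # a two-level series with known mean/std drives the threshold exactly
        sr = 8000
        x = np.concatenate([np.zeros(sr), gen_tone(2000, 1.0, sr, amplitude=0.8).samples])
        segs = detect_endpoints(AudioSignal(x, sr), self.params)
        from logmelaci.audio_io import frame_signal
        from logmelaci.preprocessing import _minmax

        frames = frame_signal(AudioSignal(x, sr), self.params)
        e = _minmax(short_time_energy(frames))
        z = _minmax(zero_crossing_rate(frames))
        s = 0.5 * e + 0.5 * z
        assert segs.threshold_used == pytest.approx(s.mean() + 0.5 * s.std())

    def test_single_planted_segment_recovered(self):
        noisy, (start, end) = self.planted()
        segs = detect_endpoints(noisy, self.params)
        assert len(segs) == 1
        ds, de = segs.segments[0]
        assert abs(ds - start) <= self.params.hop_length
        assert abs(de - end) <= self.params.hop_length

    def test_gain_invariance(self):
        noisy, _ = self.planted()
        a = detect_endpoints(noisy, self.params)
        louder = AudioSignal(noisy.samples * 12.5, noisy.sample_rate)
        b = detect_endpoints(louder, self.params)
        assert a.segments == b.segments
        assert np.array_equal(a.frame_decisions, b.frame_decisions)

    def test_all_silent_input(self):
        sig = AudioSignal(np.zeros(22050), 22050)
        with pytest.warns(UserWarning, match="constant"):
            segs = detect_endpoints(sig, self.params)
        assert segs.segments == []

    def test_short_runs_discarded(self):
        noisy, _ = self.planted()
        segs = detect_endpoints(noisy, self.params, min_segment_frames=10**6)
        assert segs.segments == []

    def test_segments_are_ordered_and_disjoint(self):
        spec = SyllableTrainSpec(syllable_rate=2.0, syllable_dur=0.15, duration=4.0, seed=5)
        sig, _ = gen_chirp_train(spec)
        noisy = add_noise(sig, "pink", 25.0, seed=6)
        segs = detect_endpoints(noisy, self.params)
        for (s1, e1), (s2, e2) in zip(segs.segments, segs.segments[1:]):
            assert e1 > s1 and s2 >= e1


class TestTimeStretch:
    def test_identity_speed(self):
        tone = gen_tone(500, 1.0)
        out = time_stretch(tone, 1.0)
        assert abs(len(out) - len(tone)) <= 256

    def test_slowdown_duration(self):
        tone = gen_tone(500, 2.0)
        out = time_stretch(tone, 0.8)
        assert out.duration == pytest.approx(2.5, abs=256 / 22050)

    @pytest.mark.parametrize("speed", [0.8, 1.2])
    def test_pitch_preserved(self, speed):
        tone = gen_tone(1000, 2.0)
        out = time_stretch(tone, speed)
        freqs = np.fft.rfftfreq(len(out), 1 / out.sample_rate)
        peak = freqs[np.argmax(np.abs(np.fft.rfft(out.samples)))]
        bin_width = out.sample_rate / 1024
        assert abs(peak - 1000.0) <= bin_width

    def test_plain_resampling_shifts_pitch(self):
        tone = gen_tone(1000, 2.0)
        out = time_stretch(tone, 1.2, pitch_preserving=False)
        freqs = np.fft.rfftfreq(len(out), 1 / out.sample_rate)
        peak = freqs[np.argmax(np.abs(np.fft.rfft(out.samples)))]
        assert abs(peak - 1200.0) < 25  # resampling scales frequency by the speed

    def test_invalid_speed(self):
        with pytest.raises(ValueError):
            time_stretch(gen_tone(500, 0.5), 0.0)


class TestTimeShift:
    def test_zero_shift_identity(self, random_signal):
        out = time_shift(random_signal, 0.0)
        assert np.array_equal(out.samples, random_signal.samples)

    def test_100ms_zero_fill(self):
        sig = AudioSignal(np.ones(16000), 16000)
        out = time_shift(sig, 100.0)
        assert len(out) == 16000
        assert np.all(out.samples[:1600] == 0)
        assert np.all(out.samples[1600:] == 1)

    def test_content_rms_preserved(self, random_signal):
        tau = 37.0
        shift = int(round(tau * random_signal.sample_rate / 1000))
        out = time_shift(random_signal, tau)
        kept_in = random_signal.samples[: len(random_signal) - shift]
        assert rms(out.samples[shift:]) == pytest.approx(rms(kept_in))

    def test_round_trip_recovers_interior(self, random_signal):
        tau = 50.0
        shift = int(round(tau * random_signal.sample_rate / 1000))
        back = time_shift(time_shift(random_signal, tau), -tau)
        assert np.array_equal(
            back.samples[: len(random_signal) - shift],
            random_signal.samples[: len(random_signal) - shift],
        )

    def test_excessive_shift_rejected(self):
        with pytest.raises(ValueError):
            time_shift(AudioSignal(np.ones(100), 1000), 150.0)


class TestAugmentToMinimum:
    def test_sufficient_input_unchanged(self):
        sigs = [gen_tone(500, 2.0)]
        out = augment_to_minimum(sigs, 1.0, seed=0)
        assert out == sigs

    def test_reaches_minimum_with_in_range_params(self):
        sigs = [gen_tone(500, 1.0), gen_tone(700, 1.0)]
        out = augment_to_minimum(sigs, 10.0, seed=3)
        assert sum(s.duration for s in out) >= 10.0
        derived = out[2:]
        assert derived
        for s in derived:
            assert 0.8 <= s.meta["stretch_speed"] <= 1.2
            assert 0.0 <= s.meta["shift_ms"] <= 100.0

    def test_seeded_determinism(self):
        sigs = [gen_tone(500, 1.0)]
        a = augment_to_minimum(sigs, 5.0, seed=11)
        b = augment_to_minimum(sigs, 5.0, seed=11)
        assert [s.meta for s in a[1:]] == [s.meta for s in b[1:]]
        for x, y in zip(a[1:], b[1:]):
            assert np.array_equal(x.samples, y.samples)
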