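"""Audio frontend: resampling, STFT framing, mel projection, shaping."""

import numpy as np
import pytest
from scipy.io import wavfile

from cabif.audio_frontend import (
    FrontendParams,
    LogMelSpectrogram,
    Waveform,
    compute_logmel,
    fit_time_axis,
    load_and_resample,
    logmel_spectrogram,
    mel_center_frequencies,
    mel_filterbank,
    normalize_spectrogram,
    save_spectrogram,
    load_spectrogram,
)

PARAMS = FrontendParams()


def _tone(freq, duration, rate, amp=0.5):
    t = np.arange(int(duration * rate)) / rate
    return amp * np.sin(2 * np.pi * freq * t)


class TestLoadAndResample:
    def test_native_rate_mono_is_identity(self, tmp_path):
        samples = _tone(440, 10.0, 16000)
        path = tmp_path / "mono16k.wav"
        wavfile.write(path, 16000, samples.astype(np.float32))
        wave = load_and_resample(path, PARAMS)
        assert wave.sample_rate == 16000
        np.testing.assert_allclose(wave.samples, samples, atol=1e-6)

    def test_stereo_opposite_channels_cancel(self, tmp_path):
        left = _tone(440, 1.0, 48000)
        stereo = np.stack([left, -left], axis=1)
        path = tmp_path / "stereo48k.wav"
        wavfile.write(path, 48000, stereo.astype(np.float32))
        wave = load_and_resample(path, PARAMS)
        assert wave.sample_rate == 16000
        assert wave.samples.size == 16000
        np.testing.assert_allclose(wave.samples, 0.0, atol=1e-7)

    def test_resampling_preserves_spectral_peak(self):
        # 2 s of 440 Hz at 8 kHz -> 32,000 samples at 16 kHz, peak at 440 Hz
        wave = Waveform(samples=_tone(440, 2.0, 8000), sample_rate=8000)
        out = load_and_resample(wave, PARAMS)
        assert out.samples.size == 32000
        spectrum = np.abs(np.fft.rfft(out.samples))
        freqs = np.fft.rfftfreq(out.samples.size, d=1 / 16000)
        peak = freqs[np.argmax(spectrum)]
        bin_width = 16000 / out.samples.size
        assert abs(peak - 440.0) <= bin_width

    def test_missing_file_names_path(self, tmp_path):
        with pytest.raises(FileNotFoundError, match="nope.wav"):
            load_and_resample(tmp_path / "nope.wav", PARAMS)

    def test_int16_pcm_roundtrip(self, tmp_path):
        samples = _tone(300, 0.5, 16000)
        path = tmp_path / "pcm.wav"
        wavfile.write(path, 16000, (samples * 32767).astype(np.int16))
        wave = load_and_resample(path, PARAMS)
        np.testing.assert_allclose(wave.samples, samples, atol=1e-3)


class TestLogmelSpectrogram:
    def test_ten_seconds_gives_501_frames(self):
        wave = Waveform(samples=_tone(440, 10.0, 16000), sample_rate=16000)
        spec = logmel_spectrogram(wave, PARAMS)
        assert spec.values.shape == (64, 501)

    def test_silence_is_constant_log_floor(self):
        wave = Waveform(samples=np.zeros(16000), sample_rate=16000)
        spec = logmel_spectrogram(wave, PARAMS)
        np.testing.assert_allclose(spec.values, np.log(PARAMS.log_floor))

    def test_pure_tone_peaks_at_nearest_mel_band(self):
        wave = Waveform(samples=_tone(1000, 2.0, 16000), sample_rate=16000)
        spec = logmel_spectrogram(wave, PARAMS)
        centers = mel_center_frequencies(PARAMS)
        expected_band = int(np.argmin(np.abs(centers - 1000.0)))
        band_energy = spec.values.mean(axis=1)
        assert abs(int(np.argmax(band_energy)) - expected_band) <= 1

    def test_rate_mismatch_rejected(self):
        wave = Waveform(samples=np.ones(8000), sample_rate=8000)
        with pytest.raises(ValueError, match="rate"):
            logmel_spectrogram(wave, PARAMS)

    def test_shorter_than_hop_rejected(self):
        wave = Waveform(samples=np.ones(100), sample_rate=16000)
        with pytest.raises(ValueError, match="hop"):
            logmel_spectrogram(wave, PARAMS)

    @pytest.mark.parametrize("seed", range(4))
    def test_frame_count_matches_hop_position_oracle(self, seed):
        # brute-force count of centered hop positions for random lengths
        rng = np.random.default_rng(seed)
        for length in rng.integers(16000, 12 * 16000, size=5):
            wave = Waveform(samples=rng.normal(size=int(length)), sample_rate=16000)
            spec = logmel_spectrogram(wave, PARAMS)
            expected = sum(
                1 for start in range(0, int(length) + 1, PARAMS.hop_length)
            )
            assert spec.n_frames == expected

    def test_energy_monotone_in_gain(self, rng):
        samples = rng.normal(size=16000)
        base = Waveform(samples=samples, sample_rate=16000)
        loud = Waveform(samples=3.0 * samples, sample_rate=16000)
        s0 = logmel_spectrogram(base, PARAMS).values
        s1 = logmel_spectrogram(loud, PARAMS).values
        assert np.all(s1 >= s0 - 1e-12)

    def test_deterministic(self, rng):
        samples = rng.normal(size=32000)
        a = logmel_spectrogram(Waveform(samples, 16000), PARAMS).values
        b = logmel_spectrogram(Waveform(samples.copy(), 16000), PARAMS).values
        assert np.array_equal(a, b)


class TestFitTimeAxis:
    def _spec(self, n_frames):
        values = np.arange(64 * n_frames, dtype=float).reshape(64, n_frames)
        return LogMelSpectrogram(values=values, params=PARAMS)

    def test_identity_when_already_target(self):
        s = self._spec(501)
        out = fit_time_axis(s, 501)
        np.testing.assert_array_equal(out.values, s.values)

    def test_center_crop_drops_first_and_last(self):
        s = self._spec(503)
        out = fit_time_axis(s, 501)
        np.testing.assert_array_equal(out.values, s.values[:, 1:502])

    def test_odd_excess_drops_extra_trailing_column(self):
        s = self._spec(504)
        out = fit_time_axis(s, 501)
        np.testing.assert_array_equal(out.values, s.values[:, 1:502])

    def test_symmetric_zero_padding(self):
        s = self._spec(499)
        out = fit_time_axis(s, 501)
        assert out.values.shape == (64, 501)
        np.testing.assert_array_equal(out.values[:, 0], 0.0)
        np.testing.assert_array_equal(out.values[:, -1], 0.0)
        np.testing.assert_array_equal(out.values[:, 1:500], s.values)

    def test_odd_deficit_pads_extra_trailing_zero(self):
        s = self._spec(500)
        out = fit_time_axis(s, 501)
        np.testing.assert_array_equal(out.values[:, -1], 0.0)
        np.testing.assert_array_equal(out.values[:, :500], s.values)

    def test_invalid_target_rejected(self):
        with pytest.raises(ValueError):
            fit_time_axis(self._spec(10), 0)


class TestNormalizeSpectrogram:
    def test_two_level_matrix_maps_to_plus_minus_one(self):
        values = np.tile([0.0, 2.0], (64, 250)).reshape(64, 500)
        s = LogMelSpectrogram(values=values, params=PARAMS)
        out = normalize_spectrogram(s).values
        np.testing.assert_allclose(np.unique(out), [-1.0, 1.0])

    def test_constant_matrix_maps_to_zeros(self):
        s = LogMelSpectrogram(values=np.full((64, 501), 7.0), params=PARAMS)
        np.testing.assert_array_equal(normalize_spectrogram(s).values, 0.0)

    def test_idempotent_on_standardized_input(self, rng):
        values = rng.normal(size=(64, 501))
        values = (values - values.mean()) / values.std()
        s = LogMelSpectrogram(values=values, params=PARAMS)
        np.testing.assert_allclose(normalize_spectrogram(s).values, values, atol=1e-6)


class TestFullPipeline:
    @pytest.mark.parametrize("duration", [1.0, 7.3, 12.0])
    def test_output_shape_law(self, duration):
        wave = Waveform(samples=_tone(800, duration, 16000), sample_rate=16000)
        spec = compute_logmel(wave, PARAMS)
        assert spec.values.shape == (PARAMS.n_mels, PARAMS.target_frames)

    def test_normalized_statistics(self):
        wave = Waveform(samples=_tone(800, 10.0, 16000), sample_rate=16000)
        spec = compute_logmel(wave, PARAMS)
        assert abs(spec.values.mean()) < 1e-4
        assert abs(spec.values.std() - 1.0) < 1e-4

    def test_cache_roundtrip(self, tmp_path, rng):
        wave = Waveform(samples=rng.normal(size=16000), sample_rate=16000)
        spec = compute_logmel(wave, PARAMS)
        save_spectrogram(tmp_path / "cache", spec)
        loaded = load_spectrogram(tmp_path / "cache")
        np.testing.assert_array_equal(loaded.values, spec.values)
        assert loaded.params == spec.params


class TestMelFilterbank:
    def test_filters_cover_band_and_peak_at_one(self):
        fb = mel_filterbank(PARAMS)
        assert fb.shape == (64, 513)
        assert np.all(fb >= 0)
        assert np.all(fb.max(axis=1) > 0.5)

    def test_centers_increase_within_band(self):
        centers = mel_center_frequencies(PARAMS)
        assert centers[0] > PARAMS.f_min
        assert centers[-1] < PARAMS.f_max
        assert np.all(np.diff(centers) > 0)
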