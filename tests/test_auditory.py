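"""Oscillator-model chain: front end, reson bank, periodicity, salience."""

import numpy as np
import pytest

from pupilbeat.auditory import (
    BandOnsetMatrix,
    PeriodicitySurface,
    ResonBank,
    amplitude_envelope,
    average_surface,
    cochlear_bands,
    detect_onsets,
    mean_periodicity_profile,
    model_salience,
    periodicity_surface,
    reduce_bands,
    reson_bank_apply,
    reson_filter,
    temporal_salience,
)
from pupilbeat.synth import MODEL_RATE_HZ, AudioSignal, make_pattern, render_loop

from conftest import RENDER_RATE, TRIO

SR = 16000.0


def _tone(freq, dur_s=1.0, sr=SR, amp=0.5):
    t = np.arange(int(dur_s * sr)) / sr
    return AudioSignal(amp * np.sin(2 * np.pi * freq * t), sr)


class TestFrontEnd:
    def test_pure_tone_energizes_nearest_band(self):
        env = cochlear_bands(_tone(1000.0))
        energies = (env.values**2).sum(axis=1)
        nearest = int(np.argmin(np.abs(env.band_centers_hz - 1000.0)))
        assert int(np.argmax(energies)) == nearest

    def test_silence_gives_zero_matrix(self):
        env = cochlear_bands(AudioSignal(np.zeros(int(SR)), SR))
        assert np.all(env.values == 0)

    def test_white_noise_excites_all_bands(self):
        # 22.05 kHz: every band of the 141-8877 Hz front end is realizable
        rng = np.random.default_rng(0)
        env = cochlear_bands(AudioSignal(0.3 * rng.standard_normal(22050), 22050.0))
        assert np.all((env.values**2).sum(axis=1) > 0)

    def test_band_centers_span_front_end_range(self):
        env = cochlear_bands(_tone(440.0, 0.2, sr=22050.0))
        assert env.n_bands == 40
        assert env.band_centers_hz[0] == pytest.approx(141.0)
        assert env.band_centers_hz[-1] == pytest.approx(8877.0)

    def test_empty_audio_rejected(self):
        with pytest.raises(ValueError):
            cochlear_bands(AudioSignal(np.array([]), SR))


class TestOnsets:
    def _mat(self, rows):
        return BandOnsetMatrix(np.asarray(rows, float), np.arange(len(rows)))

    def test_decreasing_envelope_gives_zeros(self):
        out = detect_onsets(self._mat([[5.0, 4.0, 3.0, 1.0]]))
        assert np.all(out.values == 0)

    def test_step_gives_single_impulse(self):
        out = detect_onsets(self._mat([[0.0, 0.0, 1.0, 1.0]]))
        np.testing.assert_array_equal(out.values, [[0.0, 0.0, 1.0, 0.0]])

    def test_ramp_gives_constant_slope(self):
        s = 0.25
        out = detect_onsets(self._mat([np.arange(10) * s]))
        np.testing.assert_allclose(out.values[0, 1:], s)
        assert out.values[0, 0] == 0.0


class TestReduceBands:
    def test_all_ones_preserved(self):
        m = BandOnsetMatrix(np.ones((40, 7)), np.arange(40.0))
        np.testing.assert_array_equal(reduce_bands(m).values, np.ones((5, 7)))

    def test_single_band_scaled_by_group_size(self):
        v = np.zeros((40, 4))
        v[0] = 8.0
        out = reduce_bands(BandOnsetMatrix(v, np.arange(40.0)))
        np.testing.assert_array_equal(out.values[0], np.full(4, 1.0))
        assert np.all(out.values[1:] == 0)

    def test_matches_group_mean_oracle(self):
        rng = np.random.default_rng(3)
        v = rng.random((40, 11))
        out = reduce_bands(BandOnsetMatrix(v, np.arange(40.0)))
        oracle = np.stack([v[8 * g : 8 * (g + 1)].mean(axis=0) for g in range(5)])
        np.testing.assert_allclose(out.values, oracle)

    def test_indivisible_band_count_rejected(self):
        with pytest.raises(ValueError):
            reduce_bands(BandOnsetMatrix(np.ones((39, 3)), np.arange(39.0)))


class TestResonFilter:
    def test_zero_input_zero_output(self):
        assert np.all(reson_filter(np.zeros(100), 2.0) == 0)

    @pytest.mark.parametrize("f", [0.5, 2.0, 8.0])
    def test_unit_gain_at_resonance(self, f):
        """Steady-state response to a unit sinusoid at resonance has
        amplitude 1 (direct recursion vs analytic magnitude response)."""
        t = np.arange(int(400 * MODEL_RATE_HZ / f)) / MODEL_RATE_HZ
        y = reson_filter(np.sin(2 * np.pi * f * t), f)
        steady = y[y.size // 2 :]
        assert np.max(np.abs(steady)) == pytest.approx(1.0, rel=0.02)

    def test_impulse_rings_at_tuned_frequency(self):
        f = 2.0
        x = np.zeros(800)
        x[0] = 1.0
        y = reson_filter(x, f)
        crossings = np.flatnonzero(np.diff(np.sign(y)) != 0)
        intervals = np.diff(crossings) / MODEL_RATE_HZ
        assert np.median(intervals) == pytest.approx(1.0 / (2 * f), rel=0.05)

    def test_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            reson_filter(np.zeros(10), 60.0)


class TestResonBank:
    def test_impulse_train_drives_nearest_filter_hardest(self, impulse_train_2hz):
        """Brute force over all 99 filters: windowed-RMS energy is maximal
        at the filter nearest 2 Hz."""
        bank = ResonBank.default()
        m = BandOnsetMatrix(impulse_train_2hz[None, :], np.array([500.0]))
        out = reson_bank_apply(m, bank)[0]
        steady = out[:, out.shape[1] // 2 :]
        energy = np.sqrt((steady**2).mean(axis=1))
        nearest = int(np.argmin(np.abs(bank.frequencies_hz - 2.0)))
        # the train's higher harmonics (4, 6, ... Hz) also resonate, so
        # compare among filters below the second harmonic
        energy[bank.frequencies_hz >= 3.0] = 0.0
        assert int(np.argmax(energy)) == nearest

    def test_silence_and_linearity(self):
        bank = ResonBank.default()
        z = BandOnsetMatrix(np.zeros((5, 50)), np.arange(5.0))
        assert np.all(reson_bank_apply(z, bank) == 0)
        rng = np.random.default_rng(1)
        v = rng.random((5, 200))
        one = reson_bank_apply(BandOnsetMatrix(v, np.arange(5.0)), bank)
        two = reson_bank_apply(BandOnsetMatrix(2 * v, np.arange(5.0)), bank)
        np.testing.assert_allclose(two, 2 * one, rtol=1e-10)

    def test_default_bank_geometry(self):
        bank = ResonBank.default()
        assert bank.frequencies_hz.size == 99
        assert bank.frequencies_hz[0] == pytest.approx(0.25)
        assert bank.frequencies_hz[-1] == pytest.approx(10.0)
        assert np.all(np.diff(bank.frequencies_hz) > 0)


class TestPeriodicitySurface:
    def test_constant_signal_constant_surface(self):
        c = 0.7
        surf = periodicity_surface(np.full((3, 500), c), np.arange(3.0))
        np.testing.assert_allclose(surf.energy, c, rtol=1e-9)

    def test_average_of_identical_surfaces(self):
        rng = np.random.default_rng(2)
        s = periodicity_surface(rng.random((4, 300)), np.arange(4.0))
        avg = average_surface([s, s, s])
        np.testing.assert_allclose(avg.energy, s.energy)

    def test_matches_windowed_rms_oracle_interior(self):
        """Interior samples match an explicit brute-force windowed RMS."""
        rng = np.random.default_rng(4)
        x = rng.random((2, 400))
        win_s = 0.51  # odd number of samples at 100 Hz
        surf = periodicity_surface(x, np.arange(2.0), window_s=win_s)
        w = 51
        k = w // 2
        for i in range(k, 400 - k, 37):
            oracle = np.sqrt(np.mean(x[:, i - k : i + k + 1] ** 2, axis=1))
            np.testing.assert_allclose(surf.energy[:, i], oracle, rtol=1e-9)

    def test_window_shorter_than_hop_rejected(self):
        with pytest.raises(ValueError):
            periodicity_surface(np.ones((1, 10)), np.array([1.0]), window_s=0.005, hop_s=0.01)


class TestMeanPeriodicityProfile:
    def test_2hz_train_peak_at_nearest_filter(self, impulse_train_2hz):
        bank = ResonBank.default()
        m = BandOnsetMatrix(impulse_train_2hz[None, :], np.array([500.0]))
        out = reson_bank_apply(m, bank)
        surf = periodicity_surface(out[0], bank.frequencies_hz)
        mpp = mean_periodicity_profile(surf)
        nearest = bank.frequencies_hz[np.argmin(np.abs(bank.frequencies_hz - 2.0))]
        assert nearest in mpp.peak_frequencies_hz

    def test_flat_profile_has_no_peaks(self):
        surf = PeriodicitySurface(np.ones((99, 10)), np.geomspace(0.25, 10, 99), 2.0, 0.01)
        assert mean_periodicity_profile(surf).peak_frequencies_hz.size == 0

    def test_single_spike_single_peak(self):
        e = np.zeros((99, 5))
        e[40] = 1.0
        surf = PeriodicitySurface(e, np.geomspace(0.25, 10, 99), 2.0, 0.01)
        mpp = mean_periodicity_profile(surf)
        assert mpp.peak_frequencies_hz.size == 1
        assert mpp.peak_mask[40]

    def test_peaks_within_bank_range(self, trio_model):
        for name in TRIO:
            peaks = trio_model[name]["mpp"].peak_frequencies_hz
            assert peaks.size > 0
            assert np.all((peaks >= 0.25) & (peaks <= 10.0))


class TestSalience:
    def test_single_peak_single_band_equals_rectified_output(self):
        bank = ResonBank.default()
        rng = np.random.default_rng(5)
        out = rng.standard_normal((1, 99, 300))
        e = np.zeros((99, 5))
        e[10] = 1.0
        mpp = mean_periodicity_profile(
            PeriodicitySurface(e, bank.frequencies_hz, 2.0, 0.01)
        )
        sal = temporal_salience(out, bank, mpp)
        np.testing.assert_allclose(sal.values, np.abs(out[0, 10]))

    def test_two_peaks_match_hand_mean(self):
        bank = ResonBank.default()
        rng = np.random.default_rng(6)
        out = rng.standard_normal((5, 99, 100))
        e = np.zeros((99, 5))
        e[[20, 60]] = 1.0
        mpp = mean_periodicity_profile(
            PeriodicitySurface(e, bank.frequencies_hz, 2.0, 0.01)
        )
        sal = temporal_salience(out, bank, mpp)
        oracle = np.abs(out[:, [20, 60], :]).mean(axis=(0, 1))
        np.testing.assert_allclose(sal.values, oracle)

    def test_full_reson_zero_input_zero_series(self):
        bank = ResonBank.default()
        sal = temporal_salience(np.zeros((5, 99, 50)), bank, None, "full_reson")
        assert np.all(sal.values == 0)

    def test_peak_masked_requires_peaks(self):
        bank = ResonBank.default()
        empty = mean_periodicity_profile(
            PeriodicitySurface(np.zeros((99, 5)), bank.frequencies_hz, 2.0, 0.01)
        )
        with pytest.raises(ValueError):
            temporal_salience(np.zeros((5, 99, 10)), bank, empty, "peak_masked")


class TestAmplitudeEnvelope:
    def test_constant_sinusoid_gives_rms_level(self):
        a = 0.8
        env = amplitude_envelope(_tone(1000.0, 2.0, amp=a))
        steady = env.values[env.values.size // 4 : -env.values.size // 4]
        np.testing.assert_allclose(steady, a / np.sqrt(2), rtol=0.01)

    def test_silence_gives_zero(self):
        env = amplitude_envelope(AudioSignal(np.zeros(int(SR)), SR))
        np.testing.assert_allclose(env.values, 0.0, atol=1e-12)

    def test_am_noise_envelope_spectrum_peaks_at_modulation_rate(self):
        rng = np.random.default_rng(7)
        t = np.arange(int(20 * SR)) / SR
        mod = 1.0 + 0.9 * np.sin(2 * np.pi * 2.0 * t)
        env = amplitude_envelope(AudioSignal(0.2 * mod * rng.standard_normal(t.size), SR))
        x = env.values - env.values.mean()
        spec = np.abs(np.fft.rfft(x)) ** 2
        freqs = np.fft.rfftfreq(x.size, 1 / 100.0)
        assert freqs[np.argmax(spec)] == pytest.approx(2.0, abs=0.1)

    def test_window_longer_than_signal_rejected(self):
        with pytest.raises(ValueError):
            amplitude_envelope(AudioSignal(np.zeros(100), SR), rms_window_ms=1000.0)


class TestModelProperties:
    def test_scaling_audio_scales_salience_and_preserves_peaks(self):
        p = make_pattern("sparse")
        audio = render_loop(p.tiled(2), RENDER_RATE, seed=0)
        sal1, mpp1 = model_salience(audio)
        sal2, mpp2 = model_salience(AudioSignal(0.25 * audio.samples, RENDER_RATE))
        np.testing.assert_array_equal(mpp1.peak_mask, mpp2.peak_mask)
        np.testing.assert_allclose(sal2.values, 0.25 * sal1.values, rtol=1e-6)

    def test_tempo_covariance_of_peak_frequencies(self):
        """Time-stretching an impulse train by s shifts the dominant MPP
        peak frequency by 1/s (nearest-filter resolution)."""
        bank = ResonBank.default()

        def fundamental_peak(period_samples):
            """Lowest MPP peak = the train's fundamental (higher
            harmonics also ring, at any tempo)."""
            x = np.zeros(4000)
            x[::period_samples] = 1.0
            out = reson_bank_apply(BandOnsetMatrix(x[None, :], np.array([1.0])), bank)
            surf = periodicity_surface(out[0], bank.frequencies_hz)
            mpp = mean_periodicity_profile(surf)
            return mpp.peak_frequencies_hz[0]

        f1 = fundamental_peak(50)  # 2 Hz
        f2 = fundamental_peak(100)  # stretched x2 -> 1 Hz
        assert f1 / f2 == pytest.approx(2.0, rel=0.05)

    def test_salience_variants_positively_associated(self, trio_model):
        """The oscillator and envelope predictors agree in direction on
        every preset (they emphasize the same rhythmic events)."""
        for name in TRIO:
            pattern = trio_model[name]["pattern"]
            audio = render_loop(pattern.tiled(3), RENDER_RATE, seed=0)
            loop_samples = trio_model[name]["salience"].values.size
            env, _ = model_salience(
                audio, "amplitude_envelope", loop_samples=loop_samples
            )
            r = np.corrcoef(trio_model[name]["salience"].values, env.values)[0, 1]
            assert r > 0
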