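"""Spectrogram, MPS, modulation filtering and inversion."""

import numpy as np
import pytest

from strfshift import modulation as M

FS = 16000.0


def tone(freq, duration=2.0, fs=FS, am_freq=None):
    t = np.arange(int(duration * fs)) / fs
    x = np.sin(2 * np.pi * freq * t)
    if am_freq is not None:
        x *= 0.5 * (1.0 + np.cos(2 * np.pi * am_freq * t))
    return x


class TestComputeSpectrogram:
    def test_pure_tone_ridge(self):
        spec = M.compute_spectrogram(tone(1000.0), FS)
        interior = spec.values[50:-50]
        ridge_bins = interior.argmax(axis=1)
        expected = np.abs(spec.freqs - 1000.0).argmin()
        assert np.all(np.abs(ridge_bins - expected) <= 1)
        ridge = interior[np.arange(len(interior)), ridge_bins]
        assert ridge.max() - ridge.min() < 1.0  # dB

    def test_silence_all_at_floor(self):
        spec = M.compute_spectrogram(np.zeros(8000), FS)
        assert np.all(spec.values == spec.values.min())

    def test_am_tone_ridge_oscillates_at_am_rate(self):
        spec = M.compute_spectrogram(tone(1000.0, 3.0, am_freq=4.0), FS)
        bin_1k = np.abs(spec.freqs - 1000.0).argmin()
        ridge = 10.0 ** (spec.values[:, bin_1k] / 20.0)
        ridge = ridge - ridge.mean()
        amp = np.abs(np.fft.rfft(ridge))
        freqs = np.fft.rfftfreq(len(ridge), d=spec.time_step)
        peak = freqs[amp.argmax()]
        assert abs(peak - 4.0) <= 0.2

    def test_too_short_input_raises(self):
        with pytest.raises(ValueError):
            M.compute_spectrogram(np.zeros(100), FS)


class TestComputeMPS:
    def test_constant_spectrogram_has_no_modulation_power(self, speech_spectrogram):
        spec = M.Spectrogram(
            values=np.full((100, 40), 3.0),
            freqs=np.linspace(100, 4000, 40),
            time_step=0.002,
            window_sigma=0.0071,
            floor_db=50.0,
            audio_rate=FS,
            n_samples=1,
        )
        mps = M.compute_mps(spec)
        assert np.allclose(mps.amplitude, 0.0)

    def test_am_tone_peak_at_am_frequency(self):
        spec = M.compute_spectrogram(tone(1000.0, 3.0, am_freq=4.0), FS)
        mps = M.compute_mps(spec)
        # strongest non-DC temporal modulation row should sit at +-4 Hz
        power_by_wt = (mps.amplitude**2 * mps.fold_weights()).sum(axis=1)
        power_by_wt[np.abs(mps.wt) < 1.0] = 0.0  # mask DC neighbourhood
        peak_wt = abs(mps.wt[power_by_wt.argmax()])
        assert abs(peak_wt - 4.0) <= 0.35
        # and concentrate at low spectral modulation
        peak_row = mps.amplitude[power_by_wt.argmax()]
        assert mps.wf[peak_row.argmax()] < 0.5

    def test_parseval_identity(self, speech_spectrogram):
        mps = M.compute_mps(speech_spectrogram)
        v = speech_spectrogram.values - speech_spectrogram.values.mean()
        full = v.size * np.sum(v**2)
        assert abs(mps.total_power() - full) / full < 1e-9


class TestApplyModulationFilter:
    def test_allpass_is_identity(self, speech_spectrogram):
        filt = M.ModulationFilter("temporal_lowpass", corner_temporal=1e9)
        out = M.apply_modulation_filter(speech_spectrogram, filt)
        assert np.allclose(out.values, speech_spectrogram.values, atol=1e-8)

    def test_temporal_lowpass_attenuates_am(self):
        spec = M.compute_spectrogram(tone(1000.0, 3.0, am_freq=4.0), FS)
        filt = M.ModulationFilter("temporal_lowpass", corner_temporal=3.0)
        out = M.apply_modulation_filter(spec, filt)
        row = lambda mps, f: (np.abs(mps.wt - f).argmin(), np.abs(mps.wt + f).argmin())
        mb, ma = M.compute_mps(spec), M.compute_mps(out)
        i, j = row(mb, 4.0)
        p_before = (mb.amplitude[i] ** 2).sum() + (mb.amplitude[j] ** 2).sum()
        p_after = (ma.amplitude[i] ** 2).sum() + (ma.amplitude[j] ** 2).sum()
        assert 10 * np.log10(p_before / p_after) >= 20.0

    def test_spectral_lowpass_attenuates_harmonic_ripple(self):
        # harmonic stack, 100 Hz spacing -> 10 cycles/kHz spectral ripple
        t = np.arange(int(2.0 * FS)) / FS
        x = sum(np.sin(2 * np.pi * k * 100.0 * t + 0.7 * k) for k in range(1, 40))
        spec = M.compute_spectrogram(np.asarray(x), FS)
        filt = M.ModulationFilter("spectral_lowpass", corner_spectral=0.5)
        out = M.apply_modulation_filter(spec, filt, restore_profile=False)
        mb, ma = M.compute_mps(spec), M.compute_mps(out)
        i0 = np.abs(mb.wt).argmin()  # static ripple lives at wt = 0
        jr = np.abs(mb.wf - 10.0).argmin()
        sl = slice(max(jr - 2, 0), jr + 3)
        p_before = (mb.amplitude[i0, sl] ** 2).sum()
        p_after = (ma.amplitude[i0, sl] ** 2).sum()
        assert 10 * np.log10(p_before / p_after) >= 20.0

    def test_dc_component_preserved(self, speech_spectrogram):
        filt = M.ModulationFilter("spectral_lowpass", corner_spectral=0.5)
        out = M.apply_modulation_filter(speech_spectrogram, filt)
        assert np.isclose(out.values.mean(), speech_spectrogram.values.mean())

    def test_brick_wall_idempotent(self, speech_spectrogram):
        filt = M.ModulationFilter(
            "temporal_lowpass", corner_temporal=3.0, transition_width=0.0
        )
        once = M.apply_modulation_filter(speech_spectrogram, filt)
        twice = M.apply_modulation_filter(once, filt)
        assert np.allclose(twice.values, once.values, atol=1e-7)

    def test_default_transition_near_idempotent(self, speech_spectrogram):
        filt = M.ModulationFilter("temporal_lowpass", corner_temporal=3.0)
        once = M.apply_modulation_filter(speech_spectrogram, filt)
        twice = M.apply_modulation_filter(once, filt)
        rel = np.linalg.norm(twice.values - once.values) / np.linalg.norm(
            once.values - once.values.mean()
        )
        assert rel < 0.05

    def test_restores_spectral_profile(self, speech_spectrogram):
        filt = M.ModulationFilter("spectral_lowpass", corner_spectral=0.5)
        out = M.apply_modulation_filter(speech_spectrogram, filt)
        p_in = np.mean(10 ** (speech_spectrogram.values / 10.0), axis=0)
        p_out = np.mean(10 ** (out.values / 10.0), axis=0)
        # profile restored up to one overall scale factor
        ratio_db = 10 * np.log10(p_out / p_in)
        assert ratio_db.max() - ratio_db.min() < 0.5


class TestInvertSpectrogram:
    def test_roundtrip_correlation(self, speech_sound, speech_spectrogram):
        res = M.invert_spectrogram(speech_spectrogram, n_iter=30, seed=0)
        spec2 = M.compute_spectrogram(res.waveform, FS)
        n = min(spec2.values.shape[0], speech_spectrogram.values.shape[0])
        c = np.corrcoef(
            speech_spectrogram.values[:n].ravel(), spec2.values[:n].ravel()
        )[0, 1]
        assert c >= 0.95

    def test_error_nonincreasing_in_iterations(self, speech_spectrogram):
        errs = [
            M.invert_spectrogram(speech_spectrogram, n_iter=n, seed=0).rel_error
            for n in (1, 8, 30)
        ]
        assert errs[0] >= errs[1] >= errs[2]

    def test_pure_tone_reconstructed_at_same_frequency(self):
        spec = M.compute_spectrogram(tone(1000.0, 1.0), FS)
        res = M.invert_spectrogram(spec, n_iter=20, seed=0)
        amp = np.abs(np.fft.rfft(res.waveform))
        freqs = np.fft.rfftfreq(res.waveform.size, d=1 / FS)
        assert abs(freqs[amp.argmax()] - 1000.0) <= spec.freq_step

    def test_invalid_iteration_count(self, speech_spectrogram):
        with pytest.raises(ValueError):
            M.invert_spectrogram(speech_spectrogram, n_iter=0)


class TestSynthesizeFilteredSpeech:
    def test_allpass_roundtrip(self, speech_sound):
        filt = M.ModulationFilter("temporal_lowpass", corner_temporal=1e9)
        y = M.synthesize_filtered_speech(speech_sound, FS, filt, seed=0)
        sx = M.compute_spectrogram(speech_sound, FS)
        sy = M.compute_spectrogram(y, FS)
        assert np.corrcoef(sx.values.ravel(), sy.values.ravel())[0, 1] >= 0.95

    def test_rms_matched(self, speech_sound):
        filt = M.ModulationFilter("temporal_lowpass", corner_temporal=3.0)
        y = M.synthesize_filtered_speech(speech_sound, FS, filt, seed=0)
        rms = lambda v: np.sqrt(np.mean(v**2))
        assert abs(rms(y) - rms(speech_sound)) / rms(speech_sound) < 0.01

    def test_temporal_filter_removes_fast_envelope(self):
        from scipy.signal import hilbert

        t = np.arange(int(3.0 * FS)) / FS
        x = (0.55 + 0.45 * np.sin(2 * np.pi * 7.0 * t)) * np.sin(2 * np.pi * 1000 * t)
        filt = M.ModulationFilter("temporal_lowpass", corner_temporal=3.0)
        y = M.synthesize_filtered_speech(x, FS, filt, seed=0)

        def env_amp_at(sig, f):
            env = np.abs(hilbert(sig))
            env = env - env.mean()
            amp = np.abs(np.fft.rfft(env))
            freqs = np.fft.rfftfreq(env.size, d=1 / FS)
            return amp[np.abs(freqs - f).argmin()]

        drop_db = 20 * np.log10(env_amp_at(x, 7.0) / env_amp_at(y, 7.0))
        assert drop_db >= 15.0


def test_filter_validation():
    with pytest.raises(ValueError):
        M.ModulationFilter("bandpass")
    with pytest.raises(ValueError):
        M.ModulationFilter("temporal_lowpass", corner_temporal=-1.0)
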