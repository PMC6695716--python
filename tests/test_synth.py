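"""Synthetic inductive-stream and ECG generators."""

import numpy as np
import pytest

from inducardio.sensor import dequantize_counts
from inducardio.signals import Signal
from inducardio.synth import (
    BASELINE_H,
    FULL_SCALE_H,
    SENSITIVITY_H_PER_M,
    InductiveScenario,
    cardiac_beat_times,
    counts_lsb_displacement,
    gen_cardiac,
    gen_ecg,
    gen_inductive,
    gen_respiration,
)


class TestScenario:
    def test_rate_and_period_bounds(self):
        with pytest.raises(ValueError):
            InductiveScenario(hr_bpm=30)
        with pytest.raises(ValueError):
            InductiveScenario(resp_period_s=6)
        with pytest.raises(ValueError):
            InductiveScenario(resp_amp=1e-4, cardiac_amp=2e-4)

    def test_breath_hold_must_lie_in_recording(self):
        with pytest.raises(ValueError):
            InductiveScenario(breath_hold=(10.0, 40.0))

    def test_pressed_and_unpressed_noise_defaults(self):
        pressed = InductiveScenario(pressed=True)
        loose = InductiveScenario(pressed=False)
        assert pressed.cardiac_amp / pressed.effective_noise_amp >= 5.0
        assert loose.cardiac_amp / loose.effective_noise_amp <= 0.8


class TestRespiration:
    def test_deterministic_under_seed(self):
        a = gen_respiration(InductiveScenario(seed=42))
        b = gen_respiration(InductiveScenario(seed=42))
        np.testing.assert_array_equal(a.samples, b.samples)
        c = gen_respiration(InductiveScenario(seed=43))
        assert not np.array_equal(a.samples, c.samples)

    def test_dominant_frequency_matches_breath_period(self):
        sc = InductiveScenario(resp_period_s=4.0, resp_jitter=0.0, duration_s=60.0)
        r = gen_respiration(sc)
        spectrum = np.abs(np.fft.rfft(r.samples * np.hanning(len(r))))
        freqs = np.fft.rfftfreq(len(r), 1.0 / r.fs)
        assert freqs[spectrum.argmax()] == pytest.approx(0.25, abs=0.02)

    def test_full_breath_hold_silences_output(self):
        sc = InductiveScenario(breath_hold=(0.0, 30.0))
        r = gen_respiration(sc)
        assert np.abs(r.samples).max() < 1e-12

    def test_hold_interval_is_zero_with_short_ramps(self):
        sc = InductiveScenario(breath_hold=(10.0, 20.0))
        r = gen_respiration(sc)
        t = r.times
        inside = (t >= 10.0) & (t <= 20.0)
        assert np.abs(r.samples[inside]).max() < 1e-12
        # breathing resumes within one second of the hold's end
        assert np.abs(r.samples[t > 21.5]).max() > 0.1 * sc.resp_amp


class TestCardiac:
    def test_pulse_count_matches_rate(self):
        sc = InductiveScenario(hr_bpm=60.0, duration_s=10.0)
        assert cardiac_beat_times(sc).size == 10

    def test_autocorrelation_peaks_at_beat_period(self):
        sc = InductiveScenario(hr_bpm=75.0, duration_s=30.0)
        x = gen_cardiac(sc).samples
        x = x - x.mean()
        lag = int(round(60.0 / 75.0 * sc.fs))  # 16 samples
        acf = np.array([np.dot(x[: x.size - k], x[k:]) for k in range(1, 2 * lag)])
        # highest off-zero peak of the brute-force autocorrelation sits at the beat lag
        assert int(acf.argmax()) + 1 == lag

    def test_amplitude_scales_linearly(self):
        a = gen_cardiac(InductiveScenario(cardiac_amp=2.5e-4))
        b = gen_cardiac(InductiveScenario(cardiac_amp=5.0e-4))
        np.testing.assert_allclose(b.samples, 2 * a.samples, rtol=1e-12)

    def test_pulse_wider_than_beat_period_rejected(self):
        with pytest.raises(ValueError):
            gen_cardiac(InductiveScenario(hr_bpm=200.0, cardiac_width_s=0.06))


class TestInductive:
    def test_noise_free_composite_is_quantized_sum(self):
        sc = InductiveScenario(noise_amp=0.0, seed=7)
        counts, parts = gen_inductive(sc, return_components=True)
        assert counts.unit == "counts"
        disp = parts["respiration"].samples + parts["cardiac"].samples
        back = dequantize_counts(counts, FULL_SCALE_H)
        recovered = (BASELINE_H - back.samples) / SENSITIVITY_H_PER_M
        assert np.abs(recovered - disp).max() <= 0.5 * counts_lsb_displacement() * 1.01

    def test_reconstruction_error_bounded_by_noise_plus_lsb(self):
        sc = InductiveScenario(pressed=False, seed=9)
        counts, parts = gen_inductive(sc, return_components=True)
        clean = parts["respiration"].samples + parts["cardiac"].samples
        back = dequantize_counts(counts, FULL_SCALE_H)
        recovered = (BASELINE_H - back.samples) / SENSITIVITY_H_PER_M
        bound = sc.effective_noise_amp + counts_lsb_displacement()
        assert np.abs(recovered - clean).max() <= bound

    def test_unpressed_has_larger_variance(self):
        pressed = gen_inductive(InductiveScenario(pressed=True, seed=5))
        loose = gen_inductive(InductiveScenario(pressed=False, seed=5))
        assert loose.samples.var() > pressed.samples.var()

    def test_deterministic_under_seed(self):
        a = gen_inductive(InductiveScenario(seed=2))
        b = gen_inductive(InductiveScenario(seed=2))
        np.testing.assert_array_equal(a.samples, b.samples)


class TestEcgGenerator:
    def test_beat_count_at_60_bpm(self):
        sig, r_peaks = gen_ecg(duration_s=30.0, hr_bpm=60.0)
        assert r_peaks.size == 30
        assert sig.unit == "millivolt"

    def test_rr_intervals_uniform_at_integer_period(self):
        _, r_peaks = gen_ecg(hr_bpm=60.0, fs=200.0)
        np.testing.assert_array_equal(np.diff(r_peaks), 200)

    def test_r_locations_are_template_maxima_without_noise(self):
        sig, r_peaks = gen_ecg(hr_bpm=60.0, noise_amp=0.0, wander_amp=0.0)
        peak_vals = sig.samples[r_peaks]
        assert np.all(peak_vals >= 0.99 * sig.samples.max())

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            gen_ecg(qrs_width_ms=250.0)
        with pytest.raises(ValueError):
            gen_ecg(hr_bpm=30.0)
        with pytest.raises(ValueError):
            gen_ecg(wander_freq_hz=0.6)
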