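"""Autocorrelation period pick, bpm conversion, and the windowed pipeline."""

import numpy as np
import pytest

from inducardio.rate import (
    autocorrelation,
    bpm_from_period,
    estimate_heart_rate,
    estimate_period,
    estimate_respiration_rate,
    lag_bounds,
    windowed_report,
)
from inducardio.signals import Signal, apply_filter, remove_offset
from inducardio.synth import InductiveScenario, gen_cardiac, gen_inductive


def _sig(x, fs=20.0):
    return Signal(np.asarray(x, dtype=float), fs)


class TestAutocorrelation:
    def test_impulse(self):
        imp = np.zeros(10)
        imp[0] = 1.0
        cxx = autocorrelation(_sig(imp), 5)
        np.testing.assert_allclose(cxx, [1, 0, 0, 0, 0, 0])

    def test_zero_lag_is_energy(self, rng):
        x = rng.normal(size=50)
        cxx = autocorrelation(_sig(x), 10)
        assert cxx[0] == pytest.approx(np.sum(x * x), abs=1e-10)

    def test_matches_bruteforce(self, rng):
        x = rng.normal(size=200)
        cxx = autocorrelation(_sig(x), 35)
        for k in range(36):
            expected = sum(x[i] * x[i + k] for i in range(x.size - k))
            assert abs(cxx[k] - expected) <= 1e-12 * max(1.0, abs(expected))

    def test_sinusoid_peaks_at_multiples_of_period(self):
        x = np.sin(2 * np.pi * np.arange(400) / 20.0)
        cxx = autocorrelation(_sig(x), 60)
        for lag in (20, 40):
            assert cxx[lag] > cxx[lag - 1] and cxx[lag] >= cxx[lag + 1]


class TestLagBounds:
    def test_printed_values_at_20_hz(self):
        assert lag_bounds(20.0) == (6, 30)

    def test_values_at_200_hz(self):
        assert lag_bounds(200.0) == (60, 300)

    def test_degenerate_band_rejected(self):
        with pytest.raises(ValueError):
            lag_bounds(20.0, 100.0, 100.0)
        with pytest.raises(ValueError):
            lag_bounds(1.0, 40.0, 200.0)  # bounds collapse at tiny fs


class TestEstimatePeriod:
    def test_sinusoid_period_recovered(self):
        x = np.sin(2 * np.pi * np.arange(300) / 20.0)
        cxx = autocorrelation(_sig(x), 31)
        assert estimate_period(cxx, 6, 30) == 20

    def test_monotone_autocorrelation_has_no_peak(self):
        cxx = np.linspace(10.0, 0.0, 40)
        assert estimate_period(cxx, 6, 30) is None

    def test_equal_peaks_take_smaller_lag(self):
        cxx = np.zeros(40)
        cxx[10] = cxx[20] = 5.0
        assert estimate_period(cxx, 6, 30) == 10


class TestBpmFromPeriod:
    @pytest.mark.parametrize("t,fs,expected", [(20, 20.0, 60.0), (30, 20.0, 40.0), (6, 20.0, 200.0)])
    def test_conversions(self, t, fs, expected):
        assert bpm_from_period(t, fs) == pytest.approx(expected)

    def test_zero_period_rejected(self):
        with pytest.raises(ValueError):
            bpm_from_period(0, 20.0)


class TestHeartRatePipeline:
    def test_pressed_72_bpm_within_admitted_error(self):
        sc = InductiveScenario(hr_bpm=72.0, pressed=True, seed=11)
        ests = estimate_heart_rate(gen_inductive(sc), window_s=15.0, hop_s=5.0)
        assert all(e.valid for e in ests)
        assert all(abs(e.bpm - 72.0) <= 10.0 for e in ests)

    def test_window_shorter_than_two_periods_rejected(self):
        sc = InductiveScenario(seed=0)
        with pytest.raises(ValueError):
            estimate_heart_rate(gen_inductive(sc), window_s=2.0, hop_s=1.0)

    def test_noiseless_rates_recovered_within_lag_quantum(self):
        for hr in (45.0, 60.0, 90.0, 120.0, 180.0):
            sc = InductiveScenario(hr_bpm=hr, noise_amp=0.0, resp_jitter=0.0, seed=3)
            ests = estimate_heart_rate(gen_inductive(sc))
            t_true = 60.0 / hr * 20.0
            allowed = {int(np.floor(t_true)), int(np.ceil(t_true))}
            assert ests, hr
            for e in ests:
                assert e.valid and e.period_samples in allowed, (hr, e)

    def test_invariant_to_scaling_and_offset(self):
        sc = InductiveScenario(seed=8)
        s = gen_inductive(sc)
        base = [e.bpm for e in estimate_heart_rate(s)]
        scaled = Signal(2.5 * s.samples + 1000.0, s.fs, "counts")
        assert [e.bpm for e in estimate_heart_rate(scaled)] == base

    def test_breath_hold_halves_agree(self):
        sc = InductiveScenario(breath_hold=(15.0, 30.0), seed=3)
        s = gen_inductive(sc)
        halves = [Signal(s.samples[:300], 20.0, "counts"), Signal(s.samples[300:], 20.0, "counts")]
        medians = []
        for half in halves:
            ests = estimate_heart_rate(half, window_s=12.0, hop_s=1.0)
            medians.append(np.median([e.bpm for e in ests if e.valid]))
        assert abs(medians[0] - medians[1]) <= 10.0


class TestRespirationRate:
    def _sstar(self, s, lpf20):
        return apply_filter(lpf20, remove_offset(s), initial="steady")

    def test_four_second_breath_gives_15_rpm(self, lpf20):
        sc = InductiveScenario(resp_period_s=4.0, resp_jitter=0.0, seed=5)
        est = estimate_respiration_rate(self._sstar(gen_inductive(sc), lpf20))
        assert est.valid
        # one lag of quantization around 80 samples
        assert est.rpm == pytest.approx(15.0, abs=1.0)

    def test_breath_hold_only_is_invalid(self, lpf20):
        sc = InductiveScenario(breath_hold=(0.0, 30.0), seed=5)
        est = estimate_respiration_rate(self._sstar(gen_inductive(sc), lpf20))
        assert not est.valid

    def test_cardiac_only_flagged_out_of_band(self, lpf20):
        sc = InductiveScenario(hr_bpm=60.0, seed=5)
        est = estimate_respiration_rate(self._sstar(gen_cardiac(sc), lpf20))
        assert not est.valid


class TestWindowedReport:
    def test_report_columns_and_rates(self):
        sc = InductiveScenario(hr_bpm=72.0, resp_period_s=4.0, seed=11)
        report = windowed_report(gen_inductive(sc))
        assert list(report.columns) == ["window_start_s", "window_end_s", "bpm", "valid", "resp_rate"]
        assert report["valid"].all()
        assert np.nanmedian(np.abs(report["bpm"] - 72.0)) <= 10.0
        assert np.nanmedian(np.abs(report["resp_rate"] - 15.0)) <= 2.0
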