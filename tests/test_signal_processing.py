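import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from heelspring.exceptions import ValidationError
from heelspring.signal_processing import (
    FilterSpec,
    StanceInterval,
    detect_stance,
    downsample_force,
    finite_diff_accel,
    trapz_integral,
    zero_lag_butterworth,
)


class TestZeroLagButterworth:
    def test_dc_gain_is_unity(self):
        x = np.full(1000, 3.7)
        y = zero_lag_butterworth(x, 500.0, FilterSpec(order=4, cutoff=6.0))
        np.testing.assert_allclose(y, x, rtol=1e-9)

    def test_symmetric_pulse_peak_unmoved(self):
        n = 1001
        k = 500
        x = np.maximum(0.0, 1.0 - np.abs(np.arange(n) - k) / 100.0)  # triangle at k
        y = zero_lag_butterworth(x, 500.0, FilterSpec(order=4, cutoff=6.0))
        assert int(np.argmax(y)) == k

    def test_stopband_and_passband(self):
        # 1 Hz passes within 2%, 50 Hz attenuated by > 40 dB through (4th, 6 Hz)
        rate = 500.0
        t = np.arange(0, 10.0, 1.0 / rate)
        x = np.sin(2 * np.pi * 1.0 * t) + np.sin(2 * np.pi * 50.0 * t)
        y = zero_lag_butterworth(x, rate, FilterSpec(order=4, cutoff=6.0))

        def amplitude(sig, f):
            c = np.cos(2 * np.pi * f * t)
            s = np.sin(2 * np.pi * f * t)
            return 2.0 * np.hypot(sig @ c, sig @ s) / t.size

        assert amplitude(y, 1.0) == pytest.approx(1.0, rel=0.02)
        assert 20 * np.log10(amplitude(y, 50.0)) < -40.0

    def test_too_short_series_errors(self):
        with pytest.raises(ValidationError, match="minimum"):
            zero_lag_butterworth(np.ones(5), 500.0, FilterSpec(order=4, cutoff=6.0))

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_linearity(self, seed):
        rng = np.random.default_rng(seed)
        a, b = rng.standard_normal(200), rng.standard_normal(200)
        spec = FilterSpec(order=4, cutoff=20.0)
        lhs = zero_lag_butterworth(2.0 * a + 3.0 * b, 500.0, spec)
        rhs = 2.0 * zero_lag_butterworth(a, 500.0, spec) + 3.0 * zero_lag_butterworth(b, 500.0, spec)
        np.testing.assert_allclose(lhs, rhs, atol=1e-9)


class TestDownsample:
    def test_toy_decimation(self):
        out = downsample_force(np.array([1.0, 2.0, 3.0, 4.0]), 1000.0, 500.0, antialias=None)
        np.testing.assert_array_equal(out, [1.0, 3.0])

    def test_constant_preserved(self):
        out = downsample_force(np.full(2000, 5.0), 1000.0, 500.0,
                               antialias=FilterSpec(order=4, cutoff=100.0))
        np.testing.assert_allclose(out, 5.0, rtol=1e-9)

    @pytest.mark.parametrize("freq,expected,rel", [
        (30.0, 1.0, 0.05),  # passband content survives decimation
        (100.0, 0.5, 0.05),  # at the cutoff the forward-backward pair is -6 dB
    ])
    def test_filtered_decimation_amplitude(self, freq, expected, rel):
        rate = 1000.0
        t = np.arange(0, 4.0, 1.0 / rate)
        x = np.sin(2 * np.pi * freq * t)
        y = downsample_force(x, rate, 500.0, antialias=FilterSpec(order=4, cutoff=100.0))
        td = t[::2]
        c, s = np.cos(2 * np.pi * freq * td), np.sin(2 * np.pi * freq * td)
        amp = 2.0 * np.hypot(y @ c, y @ s) / td.size
        assert amp == pytest.approx(expected, rel=rel)

    def test_non_integer_ratio_errors(self):
        with pytest.raises(ValidationError, match="integer multiple"):
            downsample_force(np.ones(10), 1000.0, 300.0)


class TestFiniteDiff:
    @given(st.tuples(*[st.floats(-10, 10) for _ in range(3)]))
    @settings(max_examples=50, deadline=None)
    def test_exact_on_quadratics(self, coeffs):
        a, b, c = coeffs
        t = np.arange(50) / 500.0
        x = a * t**2 + b * t + c
        accel = finite_diff_accel(x, 500.0)
        np.testing.assert_allclose(accel, 2.0 * a, atol=1e-5 * max(1.0, abs(a)))

    def test_zero_on_linear(self):
        t = np.arange(100) / 500.0
        np.testing.assert_allclose(finite_diff_accel(3.0 * t, 500.0), 0.0, atol=1e-8)

    def test_sine_second_derivative(self):
        t = np.arange(0, 1.0, 1.0 / 500.0)
        x = np.sin(2 * np.pi * t)
        accel = finite_diff_accel(x, 500.0)
        exact = -(2 * np.pi) ** 2 * np.sin(2 * np.pi * t)
        assert np.max(np.abs(accel - exact)) < 1e-3

    def test_short_series_errors(self):
        with pytest.raises(ValidationError):
            finite_diff_accel(np.array([1.0, 2.0]), 500.0)


class TestDetectStance:
    def test_all_zero_gives_empty(self):
        assert detect_stance(np.zeros(1000), 20.0, 500.0) == []

    def test_single_lobe(self):
        t = np.arange(0, 0.5, 1.0 / 500.0)
        fz = np.where((t >= 0.1) & (t <= 0.4),
                      700.0 * np.sin(np.pi * (t - 0.1) / 0.3) ** 2, 0.0)
        intervals = detect_stance(fz, 20.0, 500.0)
        assert len(intervals) == 1

    def test_two_lobes_with_flight_phase(self):
        rate = 500.0
        t = np.arange(0, 1.0, 1.0 / rate)
        lobe = lambda t0: np.where((t >= t0) & (t <= t0 + 0.25),
                                   1500.0 * np.sin(np.pi * (t - t0) / 0.25) ** 2, 0.0)
        fz = lobe(0.1) + lobe(0.55)  # 0.2 s flight between
        intervals = detect_stance(fz, 20.0, rate)
        assert len(intervals) == 2
        # disjoint and sorted
        assert intervals[0].end_frame <= intervals[1].start_frame

    def test_short_blips_discarded(self):
        fz = np.zeros(500)
        fz[100:105] = 100.0  # 10 ms < 50 ms minimum
        assert detect_stance(fz, 20.0, 500.0) == []


class TestTrapzIntegral:
    def test_constant(self):
        y = np.full(251, 10.0)  # 0.5 s at 500 Hz
        assert trapz_integral(y, 500.0) == pytest.approx(5.0, rel=1e-12)

    def test_antisymmetric_is_zero(self):
        y = np.linspace(-1, 1, 101)
        assert trapz_integral(y, 500.0) == pytest.approx(0.0, abs=1e-12)

    def test_half_sine_closed_form(self):
        P, T, rate = 1234.0, 0.3, 5000.0
        t = np.linspace(0, T, int(T * rate) + 1)
        y = P * np.sin(np.pi * t / T)
        assert trapz_integral(y, rate) == pytest.approx(2 * P * T / np.pi, rel=1e-3)

    def test_window_out_of_bounds_errors(self):
        with pytest.raises(ValidationError, match="out of bounds"):
            trapz_integral(np.ones(10), 500.0, StanceInterval(0, 20, 1.0))
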