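"""Filter chain, EMG conditioning, normalizations, and smoothing."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gravgait.conditioning import (
    FilterSpec,
    butterworth,
    condition_emg,
    moving_mean,
    normalize_kinetics,
    normalize_rms,
    phase_rms,
    time_normalize,
)
from gravgait.errors import (
    InvalidAnthropometryError,
    InvalidFilterError,
    InvalidPhaseError,
    InvalidWindowError,
    UndefinedNormalizationError,
)
from gravgait.events import StrideSegmentation


def _seg(rhs1=0.4, rto=1.1, rhs2=1.55):
    return StrideSegmentation(rhs1=rhs1, rto=rto, rhs2=rhs2, source="force")


class TestButterworth:
    def test_dc_gain_is_one(self):
        x = np.full(4000, 3.7)
        y = butterworth(x, FilterSpec("lowpass", 6.0), 1000)
        assert np.abs(y - 3.7).max() < 1e-9

    def test_forward_backward_gives_half_power_at_cutoff(self):
        # |H|^2 = 0.5 at the nominal cutoff after two passes
        t = np.arange(0, 30, 1e-3)
        x = np.sin(2 * np.pi * 6.0 * t)
        y = butterworth(x, FilterSpec("lowpass", 6.0), 1000)
        amp = np.abs(y[10000:20000]).max()
        assert amp == pytest.approx(0.5, abs=0.02)

    def test_zero_lag_preserves_pulse_symmetry(self):
        x = np.zeros(2001)
        x[900:1101] = np.hanning(201)
        y = butterworth(x, FilterSpec("lowpass", 20.0), 1000)
        np.testing.assert_allclose(y, y[::-1], atol=1e-12)

    def test_cutoff_above_nyquist_rejected(self):
        with pytest.raises(InvalidFilterError):
            butterworth(np.zeros(100), FilterSpec("lowpass", 60.0), 100)

    def test_length_preserved(self):
        y = butterworth(np.random.default_rng(0).normal(size=357),
                        FilterSpec("highpass", 30.0), 1000)
        assert y.shape == (357,)


class TestConditionEmg:
    def test_low_frequency_drift_suppressed(self):
        t = np.arange(0, 4, 1e-3)
        drift = np.sin(2 * np.pi * 10.0 * t)
        out = condition_emg(drift)
        assert np.sqrt(np.mean(out[1000:-1000] ** 2)) < 0.02

    def test_zero_in_zero_out(self):
        assert np.all(condition_emg(np.zeros(1000)) == 0.0)

    def test_output_is_nonnegative(self, rng):
        out = condition_emg(rng.normal(size=2000))
        assert np.all(out >= 0.0)


class TestPhaseRms:
    def test_constant_signal_returns_constant(self):
        x = np.full(2000, 1.3)
        assert phase_rms(x, _seg(), "stance") == pytest.approx(1.3)

    def test_full_period_sinusoid_closed_form(self):
        # stance range [400, 1100) holds 7 full 10 Hz periods
        t = np.arange(2000) / 1000.0
        x = 2.0 * np.sin(2 * np.pi * 10.0 * (t - 0.4))
        assert phase_rms(x, _seg(), "stance") == \
            pytest.approx(2.0 / np.sqrt(2.0), rel=1e-6)

    def test_sign_flip_invariance(self, rng):
        x = rng.normal(size=2000)
        assert phase_rms(x, _seg(), "swing") == \
            pytest.approx(phase_rms(-x, _seg(), "swing"))

    def test_empty_phase_rejected(self):
        with pytest.raises(InvalidPhaseError):
            phase_rms(np.ones(2000), _seg(), "midair")


class TestNormalizeRms:
    def test_max_maps_to_one(self):
        out = normalize_rms({"a": 2.0, "b": 4.0})
        assert out == {"a": 0.5, "b": 1.0}

    def test_single_condition_is_one(self):
        assert normalize_rms({"only": 3.3}) == {"only": 1.0}

    def test_all_zero_rejected(self):
        with pytest.raises(UndefinedNormalizationError):
            normalize_rms({"a": 0.0, "b": 0.0})

    @given(st.lists(st.floats(0.01, 100.0), min_size=1, max_size=16))
    @settings(deadline=None, max_examples=50)
    def test_output_in_unit_interval_with_exact_one(self, values):
        out = normalize_rms(dict(enumerate(values)))
        vals = list(out.values())
        assert max(vals) == 1.0
        assert all(0.0 < v <= 1.0 for v in vals)


class TestTimeNormalize:
    def test_linear_ramp_stays_linear_with_exact_endpoints(self):
        t = np.arange(2000) / 1000.0
        x = 3.0 * t
        out = time_normalize(x, t, _seg())
        assert out.values[0] == pytest.approx(3.0 * 0.4)
        assert out.values[-1] == pytest.approx(3.0 * 1.55)
        np.testing.assert_allclose(np.diff(out.values),
                                   np.diff(out.values)[0], rtol=1e-9)

    def test_two_points_are_the_event_values(self):
        t = np.arange(2000) / 1000.0
        x = np.sin(t)
        out = time_normalize(x, t, _seg(), n_points=2)
        assert out.values[0] == pytest.approx(np.sin(0.4), abs=1e-6)
        assert out.values[1] == pytest.approx(np.sin(1.55), abs=1e-6)

    def test_matches_dense_resampling_oracle(self):
        t = np.arange(2000) / 1000.0
        x = np.sin(2 * np.pi * 1.3 * t)
        out = time_normalize(x, t, _seg())
        dense_t = np.linspace(0.4, 1.55, 1001)
        oracle = np.sin(2 * np.pi * 1.3 * dense_t)
        np.testing.assert_allclose(out.values, oracle, atol=1e-3)

    def test_toe_off_percent_recorded(self):
        t = np.arange(2000) / 1000.0
        out = time_normalize(t, t, _seg())
        assert out.toe_off_percent == pytest.approx(
            100 * (1.1 - 0.4) / (1.55 - 0.4))


class TestMovingMean:
    def test_constant_unchanged(self):
        x = np.full(100, 2.5)
        np.testing.assert_allclose(moving_mean(x, 20), x)

    def test_window_one_is_identity(self, rng):
        x = rng.normal(size=50)
        np.testing.assert_allclose(moving_mean(x, 1), x)

    def test_impulse_spreads_to_plateau(self):
        x = np.zeros(200)
        x[100] = 1.0
        y = moving_mean(x, 20)
        # direct convolution oracle in the interior (window [i-9, i+10])
        kernel = np.ones(20) / 20.0
        oracle = np.convolve(x, kernel, mode="full")[10:10 + x.size]
        np.testing.assert_allclose(y[50:150], oracle[50:150], atol=1e-12)
        assert y.sum() == pytest.approx(1.0, abs=1e-9)

    def test_window_longer_than_series_rejected(self):
        with pytest.raises(InvalidWindowError):
            moving_mean(np.ones(10), 20)


class TestNormalizeKinetics:
    def test_bodyweight_normalization_definitional(self):
        f, m, p = normalize_kinetics(np.array([700.0]), np.array([140.0]),
                                     np.array([70.0]), 700.0 / 9.81)
        assert f[0] == pytest.approx(1.0, abs=1e-9)

    def test_gravity_level_does_not_change_normalizer(self):
        # same mass, any simulated gravity: the constant is 1-G bodyweight
        f1, _, _ = normalize_kinetics(np.array([350.0]), None, None, 70.0)
        assert f1[0] == pytest.approx(350.0 / (70.0 * 9.81))

    def test_moment_per_kilogram(self):
        _, m, _ = normalize_kinetics(None, np.array([140.0]), None, 70.0)
        assert m[0] == pytest.approx(2.0)

    def test_nonpositive_mass_rejected(self):
        with pytest.raises(InvalidAnthropometryError):
            normalize_kinetics(np.zeros(3), None, None, 0.0)
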