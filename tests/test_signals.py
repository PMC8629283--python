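"""Kalman smoothing, punch detection, velocity integration, window layout."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from punchlab import signals
from punchlab.signals import (
    ForceCurve,
    ImuSegment,
    detect_punches,
    estimate_impact_velocity,
    extract_window,
    kalman_smooth,
    kalman_steady_state_gain,
)


def _segment(channels, rate=500.0, start=0.0):
    return ImuSegment(rate=rate, channels=np.asarray(channels), start_time=start)


def _six(ch, n):
    """6-channel array with the given waveform on the punch axis, zeros elsewhere."""
    out = np.zeros((6, n))
    out[signals.PUNCH_AXIS] = ch
    return out


class TestKalman:
    def test_reduces_white_noise_variance(self):
        rng = np.random.default_rng(0)
        noisy = 3.0 + rng.normal(0, 1, 1000)
        seg = _segment(_six(noisy, 1000))
        out = kalman_smooth(seg, process_var=1e-3, measurement_var=1.0)
        y = out.channels[signals.PUNCH_AXIS]
        assert np.var(y[100:] - 3.0) < np.var(noisy[100:] - 3.0)

    def test_tracks_ramp_within_steady_state_lag(self):
        """On a noiseless ramp the filter converges to a constant lag fixed
        by the closed-form steady-state gain of the scalar filter."""
        q, r = 1e-2, 1.0
        slope_per_sample = 0.05
        ramp = slope_per_sample * np.arange(1000)
        out = kalman_smooth(_segment(_six(ramp, 1000)), q, r)
        y = out.channels[signals.PUNCH_AXIS]
        k = kalman_steady_state_gain(q, r)
        lag = slope_per_sample * (1 - k) / k
        assert np.max(np.abs(y[50:] - ramp[50:])) < 1.5 * lag

    def test_trusting_measurements_limit(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 1, (6, 200))
        out = kalman_smooth(_segment(x), process_var=1.0, measurement_var=1e-15)
        assert np.allclose(out.channels, x, atol=1e-9)

    def test_commutes_with_constant_offset(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0, 1, 300)
        a = kalman_smooth(_segment(_six(x, 300)), 1e-2, 1.0).channels
        b = kalman_smooth(_segment(_six(x + 5.0, 300)), 1e-2, 1.0).channels
        assert np.allclose(b[signals.PUNCH_AXIS], a[signals.PUNCH_AXIS] + 5.0)

    @pytest.mark.parametrize("q,r", [(0.0, 1.0), (1.0, 0.0), (-1.0, 1.0)])
    def test_rejects_nonpositive_variances(self, q, r):
        seg = _segment(np.zeros((6, 10)))
        with pytest.raises(ValueError):
            kalman_smooth(seg, q, r)


class TestDetectPunches:
    def test_flat_curve_yields_nothing(self):
        assert detect_punches(ForceCurve(rate=500, force=np.zeros(100))) == []
        assert detect_punches(ForceCurve(rate=500, force=np.zeros(0))) == []

    def test_two_pulses_two_ordered_events(self):
        t = np.arange(2000) / 500.0
        f = 800 * np.exp(-0.5 * ((t - 1.0) / 0.05) ** 2) + 900 * np.exp(
            -0.5 * ((t - 3.0) / 0.05) ** 2
        )
        events = detect_punches(ForceCurve(rate=500, force=f))
        assert len(events) == 2
        assert events[0].peak_time < events[1].peak_time
        assert events[0].F == pytest.approx(800, rel=0.01)

    def test_rejects_bad_fractions(self):
        curve = ForceCurve(rate=500, force=np.ones(10))
        with pytest.raises(ValueError):
            detect_punches(curve, onset_frac=0.6, impact_frac=0.5)

    def test_session_recall_under_noise(self, elite_profile):
        """On a concatenated 500-punch stream with 5 % force noise every punch
        is found once and nothing spurious appears between pulses."""
        from punchlab import synthetic

        ds = synthetic.simulate_session(
            elite_profile, 500, seed=9, force_noise_frac=0.05
        )
        _, force = synthetic.session_stream(ds)
        events = detect_punches(force)
        assert len(events) == 500


class TestImpactVelocity:
    def test_zero_acceleration_zero_speed(self):
        seg = _segment(np.zeros((6, 500)))
        assert estimate_impact_velocity(seg, 0.1, 0.5) == 0.0

    def test_half_sine_closed_form(self):
        """Integral of A*sin(pi*tau/T) over [0, T] is 2AT/pi."""
        rate, T, A = 500.0, 0.2, 50.0  # A in m/s^2
        n = int(T * rate) + 1
        tau = np.arange(n) / rate
        accel_g = (A / signals.G_TO_MS2) * np.sin(np.pi * tau / T)
        seg = _segment(_six(accel_g, n))
        v = estimate_impact_velocity(seg, 0.0, T)
        assert v == pytest.approx(2 * A * T / np.pi, rel=1e-4)

    def test_window_outside_segment_raises(self):
        seg = _segment(np.zeros((6, 100)))
        with pytest.raises(ValueError):
            estimate_impact_velocity(seg, 0.1, 5.0)
        with pytest.raises(ValueError):
            estimate_impact_velocity(seg, 0.15, 0.1)


class TestExtractWindow:
    def test_length_and_constant_blocks(self):
        chans = np.arange(6)[:, None] * np.ones((6, 300))
        seg = _segment(chans)
        w = extract_window(seg, impact_time=0.5)
        assert w.shape == (600,)
        for c in range(6):
            assert np.all(w[100 * c : 100 * (c + 1)] == c)

    def test_shift_property(self):
        rng = np.random.default_rng(3)
        seg = _segment(rng.normal(0, 1, (6, 400)))
        w0 = extract_window(seg, impact_time=0.5)
        w5 = extract_window(seg, impact_time=0.5 + 5 / 500.0)
        for c in range(6):
            assert np.array_equal(
                w0[100 * c + 5 : 100 * (c + 1)], w5[100 * c : 100 * (c + 1) - 5]
            )

    def test_edge_padding(self):
        seg = _segment(np.arange(50)[None, :] * np.ones((6, 1)))
        w = extract_window(seg, impact_time=0.05)  # only 26 samples available
        block = w[:100]
        assert np.all(block[:74] == block[0])
        assert block[-1] == 25

    def test_pure_function(self):
        rng = np.random.default_rng(4)
        seg = _segment(rng.normal(0, 1, (6, 300)))
        assert np.array_equal(
            extract_window(seg, 0.4), extract_window(seg, 0.4)
        )

    def test_impact_before_start_raises(self):
        seg = _segment(np.zeros((6, 100)), start=1.0)
        with pytest.raises(ValueError):
            extract_window(seg, impact_time=0.5)

    @given(st.integers(min_value=1, max_value=120))
    def test_requested_width_respected(self, spc):
        seg = _segment(np.ones((6, 200)))
        assert extract_window(seg, 0.3, samples_per_channel=spc).size == 6 * spc
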