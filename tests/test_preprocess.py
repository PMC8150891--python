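"""Filter chain: mains rejection, detrending, clipping, label smoothing."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp
from scipy import signal as sps

from eegyaw.preprocess import (
    FilterSpec,
    amplify_and_clip,
    preprocess_recording,
    remove_line_noise,
    remove_trend,
    smooth_labels,
    trailing_mean,
)
from eegyaw.synth import LabelTrace

from .conftest import make_recording


def rms(x):
    return np.sqrt(np.mean(np.square(x)))


def filtfilt_gain(spec: FilterSpec, btype: str, freq: float, fs: float) -> float:
    """Independent oracle: squared magnitude response of the chosen design."""
    edges = spec.stop_band if btype == "bandstop" else spec.highpass_cut
    b, a = sps.iirfilter(spec.order, edges, btype=btype, ftype=spec.family, fs=fs)
    _, h = sps.freqz(b, a, worN=[freq], fs=fs)
    return abs(h[0]) ** 2  # forward-backward application squares the response


class TestRemoveLineNoise:
    def test_50hz_tone_suppressed(self, sine_recording):
        rec = sine_recording(50.0, amplitude=1.0)
        out = remove_line_noise(rec)
        assert rms(out.data[0]) <= 0.1 * rms(rec.data[0])

    def test_10hz_tone_preserved(self, sine_recording):
        rec = sine_recording(10.0)
        out = remove_line_noise(rec)
        measured = rms(out.data[0]) / rms(rec.data[0])
        assert abs(measured - 1.0) < 0.12
        oracle = filtfilt_gain(FilterSpec(), "bandstop", 10.0, 500.0)
        assert abs(measured - oracle) < 0.02

    def test_passband_flat_within_1db(self):
        spec = FilterSpec()
        for f in (5.0, 20.0, 40.0):
            g = filtfilt_gain(spec, "bandstop", f, 500.0)
            assert abs(10 * np.log10(g)) < 1.0

    def test_zero_in_zero_out(self):
        rec = make_recording(np.zeros((3, 5000)))
        assert not remove_line_noise(rec).data.any()

    def test_low_rate_rejected(self):
        rec = make_recording(np.zeros((3, 500)), fs=100.0)
        with pytest.raises(ValueError, match="too low"):
            remove_line_noise(rec)


class TestRemoveTrend:
    def test_dc_offset_removed(self):
        rec = make_recording(np.full((3, 10000), 5e-6))
        out = remove_trend(rec)
        assert np.abs(out.data).mean() < 0.01 * 5e-6

    def test_slow_oscillation_attenuated_20db(self, sine_recording):
        rec = sine_recording(0.1, dur=60.0)
        out = remove_trend(rec)
        assert rms(out.data[0]) < 0.1 * rms(rec.data[0])

    def test_10hz_preserved_and_matches_response_oracle(self, sine_recording):
        rec = sine_recording(10.0)
        out = remove_trend(rec)
        measured = rms(out.data[0]) / rms(rec.data[0])
        oracle = filtfilt_gain(FilterSpec(), "highpass", 10.0, 500.0)
        assert abs(10 * np.log10(measured**2)) < 1.0
        assert abs(measured**2 - oracle) < 0.02


class TestAmplifyAndClip:
    @pytest.mark.parametrize(
        "value,expected",
        [(2e-5, 1.0), (-3e-5, -1.0), (5e-6, 0.5)],
    )
    def test_gain_and_clip_bounds(self, value, expected):
        rec = make_recording(np.full((3, 10), value))
        out = amplify_and_clip(rec, gain=1e5)
        assert np.allclose(out.data, expected)

    @settings(max_examples=100, deadline=None)
    @given(
        hnp.arrays(
            float,
            (3, 20),
            elements=st.floats(-1e-3, 1e-3, allow_nan=False),
        )
    )
    def test_output_always_within_unit_interval(self, data):
        out = amplify_and_clip(make_recording(data), gain=1e5)
        assert (out.data >= -1.0).all() and (out.data <= 1.0).all()

    def test_gain_one_idempotent_after_clipping(self, rng):
        rec = make_recording(rng.normal(0, 2, (3, 100)))
        once = amplify_and_clip(rec, gain=1.0)
        twice = amplify_and_clip(once, gain=1.0)
        np.testing.assert_array_equal(once.data, twice.data)

    def test_nonpositive_gain_rejected(self):
        with pytest.raises(ValueError):
            amplify_and_clip(make_recording(np.zeros((3, 4))), gain=0.0)


class TestTrailingMean:
    @settings(max_examples=150, deadline=None)
    @given(
        x=hnp.arrays(float, st.integers(1, 120), elements=st.floats(-5, 5)),
        window=st.integers(1, 500),
    )
    def test_matches_bruteforce_oracle(self, x, window):
        got = trailing_mean(x, window)
        expect = [
            np.mean(x[max(t - window + 1, 0) : t + 1]) for t in range(x.size)
        ]
        np.testing.assert_allclose(got, expect, rtol=0, atol=1e-12)

    def test_window_one_is_identity(self, rng):
        x = rng.normal(size=50)
        np.testing.assert_array_equal(trailing_mean(x, 1), x)

    def test_invalid_window_rejected(self):
        with pytest.raises(ValueError):
            trailing_mean(np.zeros(5), 0)


class TestSmoothLabels:
    def test_constant_trace_unchanged(self):
        labels = LabelTrace(y=np.ones(1000), fs=500.0)
        np.testing.assert_array_equal(smooth_labels(labels).y, labels.y)

    def test_step_reaches_half_after_150_samples(self):
        """A 0->1 step at sample s averages to 0.5 at sample s+149."""
        s = 400
        y = np.zeros(1200)
        y[s:] = 1.0
        out = smooth_labels(LabelTrace(y=y, fs=500.0), window=300).y
        assert out[s + 149] == pytest.approx(0.5)

    def test_default_window_spans_0p6_seconds(self):
        labels = LabelTrace(y=np.zeros(100), fs=500.0)
        smoothed = smooth_labels(labels)  # default 300 samples
        assert 300 / labels.fs == pytest.approx(0.6)
        assert smoothed.y.size == labels.y.size

    def test_output_within_input_range(self, rng):
        y = rng.choice([-1.0, 0.0, 1.0], size=2000)
        out = smooth_labels(LabelTrace(y=y, fs=500.0), window=77).y
        assert out.min() >= y.min() and out.max() <= y.max()


class TestFullChain:
    def test_shape_channels_and_determinism_preserved(self, rng):
        data = rng.normal(0, 1e-5, (3, 4000))
        rec = make_recording(data)
        out1 = preprocess_recording(rec)
        out2 = preprocess_recording(rec)
        assert out1.data.shape == rec.data.shape
        assert out1.channels == rec.channels
        np.testing.assert_array_equal(out1.data, out2.data)
        assert (np.abs(out1.data) <= 1.0).all()

    def test_channels_filtered_independently(self, rng):
        data = np.zeros((3, 4000))
        data[1] = rng.normal(0, 1e-5, 4000)
        out = preprocess_recording(make_recording(data))
        assert not out.data[0].any() and not out.data[2].any()
        assert out.data[1].any()

    def test_filter_spec_validation(self):
        with pytest.raises(ValueError):
            FilterSpec(highpass_cut=60.0).validate(500.0)
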