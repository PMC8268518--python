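"""Conditioning chain: clipping, validity test, filtering, conversion."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import signal

from smbjid.preprocess import (
    G0,
    PreprocessConfig,
    clip_current,
    cutoff_frequency,
    fit_exponential,
    lowpass_filter,
    preprocess_dataset,
    r2_filter,
    resample,
    to_conductance,
)
from smbjid.trace_io import TraceIOError, CurrentTrace

from conftest import make_trace


def log_ols_r2_oracle(samples, fs, clip_low=1e-11):
    """Independent normal-equations least squares of ln(I) on t."""
    y = np.log(np.maximum(np.asarray(samples, float), clip_low))
    t = np.arange(y.size) / fs
    n = y.size
    sxx = np.sum(t * t) - np.sum(t) ** 2 / n
    sxy = np.sum(t * y) - np.sum(t) * np.sum(y) / n
    syy = np.sum(y * y) - np.sum(y) ** 2 / n
    if syy == 0:
        return 0.0
    slope = sxy / sxx
    intercept = (np.sum(y) - slope * np.sum(t)) / n
    ss_res = np.sum((y - slope * t - intercept) ** 2)
    return min(1.0, max(0.0, 1.0 - ss_res / syy))


class TestClip:
    def test_clamps_to_preamp_window(self):
        trace = make_trace([5e-12, 5e-8, 2e-7])
        out = clip_current(trace)
        np.testing.assert_array_equal(out.samples, [1e-11, 5e-8, 1e-7])

    def test_inside_window_unchanged(self):
        trace = make_trace([1e-10, 5e-9, 9e-8])
        np.testing.assert_array_equal(clip_current(trace).samples, trace.samples)

    def test_all_below_floor(self):
        out = clip_current(make_trace([1e-12] * 4))
        np.testing.assert_array_equal(out.samples, [1e-11] * 4)

    @settings(max_examples=30, deadline=None)
    @given(st.integers(min_value=0, max_value=2**16))
    def test_idempotent(self, seed):
        rng = np.random.default_rng(seed)
        trace = make_trace(10 ** rng.uniform(-13, -5, size=50))
        once = clip_current(trace)
        twice = clip_current(once)
        np.testing.assert_array_equal(once.samples, twice.samples)


class TestExponentialFit:
    def test_pure_decay_scores_one(self):
        # 150 samples: the decay stays above the 10 pA clip floor throughout
        t = np.arange(150) / 30000.0
        trace = make_trace(1e-8 * np.exp(-t / 1e-3))
        report = fit_exponential(trace)
        assert report.r_squared == pytest.approx(1.0, abs=1e-9)
        assert report.tau == pytest.approx(1e-3, rel=1e-6)
        assert report.amplitude == pytest.approx(1e-8, rel=1e-6)

    def test_flat_trace_scores_zero(self):
        report = fit_exponential(make_trace([5e-9] * 100))
        assert report.r_squared == 0.0
        assert report.accepted  # 0 <= beta always

    def test_plateau_trace_matches_oracle(self):
        t = np.arange(3000) / 30000.0
        samples = 1e-8 * np.exp(-t / 0.02)
        samples[1000:1900] = 2e-9  # 30 % flat plateau
        trace = make_trace(samples)
        report = fit_exponential(trace)
        expected = log_ols_r2_oracle(samples, 30000.0)
        assert report.r_squared < 1.0
        assert report.r_squared == pytest.approx(expected, abs=1e-12)

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError, match="10 samples"):
            fit_exponential(make_trace([1e-9] * 5))

    def test_r_squared_bounded_in_unit_interval(self, rng):
        for _ in range(20):
            trace = make_trace(10 ** rng.uniform(-11, -7, size=200))
            r2 = fit_exponential(trace).r_squared
            assert 0.0 <= r2 <= 1.0


class TestR2Filter:
    def test_threshold_rule(self):
        t = np.arange(3000) / 30000.0
        decay = make_trace(1e-8 * np.exp(-t / 0.02), trace_id="d")  # R2 ~ 1, no clipping
        flat = make_trace(np.full(3000, 5e-9), trace_id="f")  # R2 = 0
        accepted, reports = r2_filter([decay, flat], PreprocessConfig(beta=0.95))
        assert [t_.trace_id for t_ in accepted] == ["f"]
        assert [r.trace_id for r in reports] == ["d", "f"]
        for r in reports:
            assert r.accepted == (r.r_squared <= 0.95)

    def test_beta_one_accepts_everything(self, rng):
        traces = [make_trace(10 ** rng.uniform(-11, -7, size=100)) for _ in range(10)]
        accepted, _ = r2_filter(traces, PreprocessConfig(beta=1.0))
        assert len(accepted) == len(traces)

    def test_empty_input(self):
        accepted, reports = r2_filter([], PreprocessConfig())
        assert accepted == [] and reports == []

    def test_lower_beta_never_accepts_more(self, rng):
        t = np.arange(500) / 30000.0
        traces = []
        for i in range(30):
            s = 1e-8 * np.exp(-t / rng.uniform(1e-3, 1e-2))
            s *= np.exp(rng.normal(0, rng.uniform(0, 1.0), size=t.size))
            traces.append(make_trace(np.clip(s, 1e-11, 1e-7), trace_id=f"x:{i}"))
        counts = []
        for beta in [1.0, 0.95, 0.9, 0.7, 0.5, 0.2]:
            accepted, _ = r2_filter(traces, PreprocessConfig(beta=beta))
            counts.append(len(accepted))
        assert counts == sorted(counts, reverse=True)


class TestLowpass:
    def test_cutoff_follows_folding_rule(self):
        assert cutoff_frequency(30000.0) == pytest.approx(9000.0)
        assert cutoff_frequency(10000.0) == pytest.approx(3000.0)

    def test_dc_gain_is_unity(self):
        trace = make_trace(np.full(2000, 3e-9))
        out = lowpass_filter(trace)
        np.testing.assert_allclose(out.samples, trace.samples, rtol=1e-9)
        assert len(out) == len(trace)

    def test_attenuation_matches_frequency_response(self):
        fs = 30000.0
        t = np.arange(30000) / fs
        for freq in [100.0, 14000.0]:
            trace = make_trace(1e-9 + 1e-10 * np.sin(2 * np.pi * freq * t), fs=fs)
            out = lowpass_filter(trace)
            core = slice(2000, -2000)  # exclude filter edge transients
            gain = np.std(out.samples[core] - 1e-9) / np.std(trace.samples[core] - 1e-9)
            sos = signal.butter(4, cutoff_frequency(fs), btype="low", fs=fs, output="sos")
            _, h = signal.sosfreqz(sos, worN=[freq], fs=fs)
            expected = np.abs(h[0]) ** 2  # forward-backward pass squares |H|
            assert gain == pytest.approx(expected, rel=0.05, abs=1e-4)


class TestResample:
    def test_factor_one_is_identity(self):
        trace = make_trace([1e-9, 2e-9, 3e-9])
        out = resample(trace, PreprocessConfig(interp_factor=1))
        np.testing.assert_array_equal(out.samples, trace.samples)
        assert out.sampling_rate == trace.sampling_rate

    def test_linear_interpolation_closed_form(self):
        trace = make_trace([1.0, 3.0], fs=10000.0)
        out = resample(trace, PreprocessConfig(interp_factor=3))
        np.testing.assert_allclose(out.samples, [1.0, 5 / 3, 7 / 3, 3.0])
        assert out.sampling_rate == pytest.approx(30000.0)

    def test_original_samples_preserved_at_stride(self, rng):
        samples = rng.uniform(1e-11, 1e-7, size=100)
        out = resample(make_trace(samples), PreprocessConfig(interp_factor=4))
        assert len(out) == 4 * 99 + 1
        np.testing.assert_allclose(out.samples[::4], samples, rtol=1e-12)


class TestConductance:
    def test_definition_of_quantum(self):
        trace = make_trace([7.748e-6], bias=0.1)
        assert to_conductance(trace).values[0] == pytest.approx(1.0, rel=1e-12)

    def test_direct_arithmetic(self):
        trace = make_trace([1e-11], bias=0.01)
        expected = 1e-11 / (0.01 * G0)
        assert to_conductance(trace).values[0] == pytest.approx(expected, rel=1e-9)
        assert expected == pytest.approx(1.2907e-5, rel=1e-4)

    def test_nonpositive_bias_impossible(self):
        with pytest.raises(TraceIOError):
            make_trace([1e-9], bias=0.0)

    @settings(max_examples=20, deadline=None)
    @given(scale=st.floats(min_value=0.1, max_value=10.0),
           seed=st.integers(min_value=0, max_value=2**16))
    def test_linearity(self, scale, seed):
        rng = np.random.default_rng(seed)
        samples = rng.uniform(1e-11, 1e-7, size=30)
        base = to_conductance(make_trace(samples)).values
        scaled = to_conductance(make_trace(samples * scale)).values
        np.testing.assert_allclose(scaled, base * scale, rtol=1e-12)


class TestPipeline:
    def _pool(self, rng, n=20):
        t = np.arange(1500) / 30000.0
        traces = []
        for i in range(n):
            s = 1e-8 * np.exp(-t / 5e-3)
            if i % 2 == 0:  # half get a strong plateau
                s[400:1000] = 3e-9
            s = s * np.exp(rng.normal(0, 0.1, size=t.size))
            traces.append(make_trace(s, trace_id=f"S1:{i}"))
        return traces

    def test_output_count_equals_acceptance_count(self, rng):
        traces = self._pool(rng)
        cfg = PreprocessConfig(beta=0.95)
        cond, reports = preprocess_dataset(traces, cfg)
        assert len(cond) == sum(r.accepted for r in reports)
        assert len(reports) == len(traces)

    def test_beta_one_keeps_all(self, rng):
        traces = self._pool(rng)
        cond, _ = preprocess_dataset(traces, PreprocessConfig(beta=1.0))
        assert len(cond) == len(traces)

    def test_deterministic(self, rng):
        traces = self._pool(rng)
        a, _ = preprocess_dataset(traces, PreprocessConfig())
        b, _ = preprocess_dataset(traces, PreprocessConfig())
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.values, y.values)

    def test_interpolation_applied_after_filter(self, rng):
        traces = [make_trace(np.full(1200, 5e-9), fs=10000.0)]
        cond, _ = preprocess_dataset(traces, PreprocessConfig(interp_factor=3))
        assert len(cond[0]) == 3 * (1200 - 1) + 1
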