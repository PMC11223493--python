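"""Signal processing: filter, decimation, detection, tensors, fits."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import signal as scipy_signal

from nanocoa import sigproc as sp
from nanocoa.trace import CurrentTrace


def make_trace(samples, fs=500e3, trace_id=None):
    return CurrentTrace(samples=np.asarray(samples, dtype=float), sampling_rate=fs, trace_id=trace_id)


def brute_force_detect(samples, fs, open_pore, threshold_frac=0.65, min_event_samples=2):
    """Independent per-sample threshold scan (the detection oracle)."""
    threshold = threshold_frac * open_pore
    runs, start = [], None
    for i, v in enumerate(samples):
        if v < threshold:
            if start is None:
                start = i
        elif start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(samples)))
    out = []
    for s, e in runs:
        if e - s < min_event_samples:
            continue
        seg = samples[s:e]
        out.append((s, e, (e - s) / fs, open_pore - np.mean(seg)))
    return out


class TestLowpassFilter:
    def test_dc_gain_is_one(self):
        trace = make_trace(np.full(5000, 1000.0))
        out = sp.lowpass_filter(trace, 80e3)
        np.testing.assert_allclose(out.samples, 1000.0, rtol=1e-9)

    def test_sinusoid_attenuation_matches_frequency_response(self):
        fs, cutoff, f0 = 500e3, 80e3, 160e3
        t = np.arange(50000) / fs
        trace = make_trace(1000.0 + 100.0 * np.sin(2 * np.pi * f0 * t), fs=fs)
        out = sp.lowpass_filter(trace, cutoff)
        # oracle: evaluate the filter's squared magnitude response (filtfilt)
        sos = sp.bessel_sos(cutoff, fs)
        _, h = scipy_signal.sosfreqz(sos, worN=[f0], fs=fs)
        expected_amp = 100.0 * np.abs(h[0]) ** 2
        mid = out.samples[10000:40000] - 1000.0
        measured_amp = np.sqrt(2) * mid.std()
        assert measured_amp == pytest.approx(expected_amp, rel=0.02)

    def test_white_noise_variance_reduced(self, rng):
        trace = make_trace(rng.normal(0, 1, 20000))
        out = sp.lowpass_filter(trace, 80e3)
        assert out.samples.var() < trace.samples.var()

    def test_cutoff_at_or_above_nyquist_rejected(self):
        trace = make_trace(np.zeros(100), fs=100e3)
        with pytest.raises(ValueError):
            sp.lowpass_filter(trace, 50e3)


class TestDecimateMedian:
    def test_500_to_80_khz_window_pattern(self):
        # ratio 6.25 -> repeating [6, 6, 6, 7]; output length floor(n / 6.25)
        n = 1003
        trace = make_trace(np.arange(n, dtype=float), fs=500e3)
        out = sp.decimate_median(trace, 80e3)
        assert out.n_samples == int(n / 6.25)
        assert out.sampling_rate == pytest.approx(80e3)
        # first windows: medians of [0:6], [6:12], [12:18], [18:25]
        np.testing.assert_allclose(out.samples[:4], [2.5, 8.5, 14.5, 21.0])

    def test_matches_brute_force_window_medians(self, rng):
        samples = rng.normal(0, 1, 2000)
        out = sp.decimate_median(make_trace(samples, fs=500e3), 80e3)
        bounds = (np.arange(out.n_samples + 1) * 25) // 4
        expected = [np.median(samples[a:b]) for a, b in zip(bounds, bounds[1:])]
        np.testing.assert_allclose(out.samples, expected)

    def test_constant_trace_stays_constant(self):
        out = sp.decimate_median(make_trace(np.full(625, 7.0), fs=500e3), 80e3)
        assert out.n_samples == 100
        np.testing.assert_allclose(out.samples, 7.0)

    def test_single_outlier_suppressed(self):
        samples = np.full(625, 100.0)
        samples[3] = 1e6
        out = sp.decimate_median(make_trace(samples, fs=500e3), 80e3)
        np.testing.assert_allclose(out.samples, 100.0)

    @pytest.mark.parametrize("bad_rate", [0.0, -5.0, 500e3, 600e3])
    def test_invalid_target_rate_rejected(self, bad_rate):
        with pytest.raises(ValueError):
            sp.decimate_median(make_trace(np.zeros(100), fs=500e3), bad_rate)


class TestEstimateOpenPore:
    def test_pure_baseline(self, rng):
        trace = make_trace(1000.0 + rng.normal(0, 10, 50000))
        assert sp.estimate_open_pore(trace) == pytest.approx(1000.0, abs=1.0)

    def test_robust_to_sparse_blockades(self, rng):
        samples = 1000.0 + rng.normal(0, 10, 50000)
        samples[: len(samples) // 100] = 600.0  # 1% blocked
        estimate = sp.estimate_open_pore(make_trace(samples))
        # oracle: median of the constructed baseline-only portion
        baseline_median = np.median(samples[len(samples) // 100 :])
        assert estimate == pytest.approx(baseline_median, abs=1.0)

    def test_all_zero_trace_rejected(self):
        with pytest.raises(ValueError):
            sp.estimate_open_pore(make_trace(np.zeros(1000)))

    def test_blockade_dominated_trace_rejected(self):
        samples = np.concatenate([np.full(600, 100.0), np.full(400, 1000.0)])
        # median is 100 -> >50% of samples sit at/below 80% of ... construct:
        samples = np.where(np.arange(1000) % 3 == 0, 1000.0, 100.0)
        with pytest.raises(ValueError, match="dominated"):
            sp.estimate_open_pore(make_trace(samples))


class TestDetectEvents:
    def test_constant_baseline_has_no_events(self):
        trace = make_trace(np.full(1000, 1000.0))
        assert sp.detect_events(trace, 1000.0) == []

    def test_threshold_rule_at_65_percent(self):
        samples = np.full(200, 1000.0)
        samples[50:60] = 600.0  # 60% of open pore: below threshold
        assert len(sp.detect_events(make_trace(samples), 1000.0)) == 1
        samples[50:60] = 700.0  # 70%: above threshold
        assert len(sp.detect_events(make_trace(samples), 1000.0)) == 0

    def test_sample_exactly_at_threshold_counts_as_baseline(self):
        samples = np.full(100, 1000.0)
        samples[10:20] = 650.0
        assert sp.detect_events(make_trace(samples), 1000.0) == []

    def test_short_runs_discarded(self):
        samples = np.full(100, 1000.0)
        samples[10] = 100.0
        assert sp.detect_events(make_trace(samples), 1000.0, min_event_samples=2) == []
        assert len(sp.detect_events(make_trace(samples), 1000.0, min_event_samples=1)) == 1

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_scan(self, seed):
        rng = np.random.default_rng(seed)
        samples = 1000.0 + rng.normal(0, 250, 500)  # heavy noise: many crossings
        trace = make_trace(samples, fs=80e3)
        events = sp.detect_events(trace, 1000.0)
        oracle = brute_force_detect(samples, 80e3, 1000.0)
        assert [(e.start, e.end) for e in events] == [(s, e) for s, e, _, _ in oracle]
        for ev, (_, _, dur, di) in zip(events, oracle):
            assert ev.duration == pytest.approx(dur)
            assert ev.delta_i == pytest.approx(di)

    @given(st.integers(0, 10_000))
    @settings(max_examples=50, deadline=None)
    def test_events_disjoint_sorted_and_deep(self, seed):
        rng = np.random.default_rng(seed)
        samples = 1000.0 + rng.normal(0, 300, 300)
        events = sp.detect_events(make_trace(samples, fs=80e3), 1000.0)
        prev_end = -1
        for ev in events:
            assert ev.start >= prev_end
            prev_end = ev.end
            assert ev.rel_blockade > 1 - 0.65  # forced by the threshold rule

    def test_no_false_positives_on_default_noise_baseline(self, rng):
        # 10 s of pure baseline at the default SNR after full processing
        from nanocoa.simulate import ClassParams, SimulationConfig, simulate_trace

        cfg = SimulationConfig(
            classes={"x": ClassParams(0.0, 0.1, 1e-4, 1e-5, 400.0, 30.0)},
            sampling_rate=500e3, duration=10.0, seed=99,
        )
        trace, _ = simulate_trace(cfg)
        filtered = sp.lowpass_filter(trace, 80e3)
        decimated = sp.decimate_median(filtered, 80e3)
        events = sp.detect_events(decimated, sp.estimate_open_pore(decimated))
        assert events == []


class TestEventTensor:
    def make_event_trace(self, event_len, rng, n=2000, start=500, depth=400.0):
        samples = 580.0 + rng.normal(0, 5, n)
        samples[start : start + event_len] -= depth
        trace = make_trace(samples, fs=80e3)
        ev = sp.detect_events(trace, 580.0)
        assert len(ev) == 1
        return trace, ev[0]

    def test_full_capacity_event_has_no_padding(self, rng):
        trace, ev = self.make_event_trace(156, rng)
        t = sp.to_event_tensor(trace, ev)
        assert t.shape == (251,)
        assert np.all(t[:250] != 0)  # 47 + 156 + 47 = 250: no pad left

    def test_shape_padding_and_flank_normalization(self, rng):
        trace, ev = self.make_event_trace(40, rng)
        t = sp.to_event_tensor(trace, ev)
        assert t.shape == (251,)
        seg_len = 47 + 40 + 47
        np.testing.assert_array_equal(t[seg_len:250], 0.0)
        flank_values = np.concatenate([t[:47], t[seg_len - 47 : seg_len]])
        assert abs(flank_values.mean()) < 1e-9  # centered on the flank mean
        assert t[60] < -1.0  # event region well below the flanks

    def test_duration_feature_z_scoring(self, rng):
        trace, ev = self.make_event_trace(40, rng)
        stats = (np.log10(ev.duration), 0.5)
        t = sp.to_event_tensor(trace, ev, duration_stats=stats)
        assert t[-1] == pytest.approx(0.0)

    def test_edge_event_skipped(self, rng):
        samples = 580.0 + rng.normal(0, 5, 300)
        samples[10:60] -= 400.0  # closer than 47 samples to the left edge
        trace = make_trace(samples, fs=80e3)
        ev = sp.detect_events(trace, 580.0)[0]
        assert sp.to_event_tensor(trace, ev) is None

    def test_too_long_event_skipped_and_counted(self, rng):
        trace, ev = self.make_event_trace(200, rng)  # > 250 - 94
        x, kept, n_skipped = sp.events_to_tensors(trace, [ev])
        assert n_skipped == 1 and kept == [] and x.shape == (0, 251)


class TestDistributionFits:
    def test_lognormal_recovers_printed_dwell_moments(self, rng):
        mean, sd = 315e-6, 26e-6
        sigma2 = np.log1p((sd / mean) ** 2)
        mu = np.log(mean) - sigma2 / 2
        draws = rng.lognormal(mu, np.sqrt(sigma2), 10_000)
        fit = sp.fit_duration_lognormal(draws)
        assert fit.mean == pytest.approx(mean, rel=0.01)
        assert fit.sd == pytest.approx(sd, rel=0.05)

    def test_normal_recovers_printed_blockade_moments(self, rng):
        fit = sp.fit_blockade_normal(rng.normal(400.0, 30.0, 10_000))
        assert fit.mean == pytest.approx(400.0, rel=0.01)
        assert fit.sd == pytest.approx(30.0, rel=0.05)

    def test_degenerate_and_invalid_inputs_rejected(self):
        with pytest.raises(ValueError, match="zero variance|all values equal"):
            sp.fit_duration_lognormal(np.full(20, 1e-4))
        with pytest.raises(ValueError):
            sp.fit_duration_lognormal(np.linspace(-1, 1, 20))
        with pytest.raises(ValueError, match="at least"):
            sp.fit_blockade_normal(np.arange(5.0))


class TestBootstrapDuration:
    def test_recovers_shifted_exponential_parameters(self, rng):
        t0, tau = 50e-6, 300e-6
        draws = t0 + rng.exponential(tau, 5000)
        result = sp.bootstrap_duration(draws, n_resamples=200, seed=0)
        assert result.tau == pytest.approx(tau, rel=0.05)
        assert result.t0 == pytest.approx(t0, rel=0.15)
        assert result.n_resamples == 200

    def test_default_is_1000_resamples(self, rng):
        draws = 50e-6 + rng.exponential(300e-6, 100)
        result = sp.bootstrap_duration(draws, seed=1)
        assert result.n_resamples == 1000
        assert result.n_failed <= 100

    def test_uncertainty_scales_with_sample_size(self, rng):
        tau = 300e-6
        small = 50e-6 + rng.exponential(tau, 500)
        large = 50e-6 + rng.exponential(tau, 2000)  # 4x -> SD halves
        r_small = sp.bootstrap_duration(small, n_resamples=300, seed=2)
        r_large = sp.bootstrap_duration(large, n_resamples=300, seed=2)
        ratio = r_small.tau_sd / r_large.tau_sd
        assert 1.4 < ratio < 2.9  # ~2 expected

    def test_too_few_durations_rejected(self):
        with pytest.raises(ValueError):
            sp.bootstrap_duration(np.full(10, 1e-4))
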