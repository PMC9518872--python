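"""EtCO2 extraction: preprocessing, both peak detectors, envelope assembly."""

import numpy as np
import pytest

from cvrkit import CapnogramError, Co2Trace, EtCo2Curve, PhantomSpec, check_co2_switching, \
    combine_envelopes, extract_etco2, preprocess_trace, regularize_peaks, \
    scale_space_peaks, simulate_capnogram, smooth_cross_peaks
from cvrkit.capnogram import PeakSet, _median_filter_clipped


def sine_trace(period_s=4.0, duration_s=60.0, amp=20.0, offset=30.0, fs=10.0):
    """Sinusoidal 'capnogram' with troughs at both ends (crests at period/2 + k*period)."""
    t = np.arange(int(duration_s * fs) + 1) / fs
    return Co2Trace(t=t, p=offset - amp * np.cos(2 * np.pi * t / period_s), fs_native=fs)


def brute_force_period_argmax(trace, period_s):
    """Oracle: the argmax of each full period of a noiseless periodic trace."""
    fs = trace.fs_native
    n_per = int(round(period_s * fs))
    times, values = [], []
    for start in range(0, trace.t.size - n_per + 1, n_per):
        seg = trace.p[start:start + n_per]
        i = start + int(np.argmax(seg))
        times.append(trace.t[i])
        values.append(trace.p[i])
    return np.asarray(times), np.asarray(values)


class TestPreprocess:
    def test_constant_preserved(self):
        t = np.arange(0, 2000) / 100.0
        out = preprocess_trace(Co2Trace(t=t, p=np.full(t.size, 40.0), fs_native=100.0))
        assert out.fs_native == 10.0
        np.testing.assert_allclose(out.p, 40.0)
        np.testing.assert_allclose(np.diff(out.t), 0.1)

    def test_linear_ramp_preserved_interior(self):
        t = np.arange(0, 6000) / 100.0
        ramp = t / 60.0 * 60.0  # 0 -> 60 mmHg over 60 s
        out = preprocess_trace(Co2Trace(t=t, p=ramp, fs_native=100.0))
        interior = slice(5, -5)
        np.testing.assert_allclose(out.p[interior], out.t[interior], atol=0.01)

    def test_sine_matches_attenuated_analytic(self):
        # 200 Hz sine, period 4 s: the 100 ms boxcar attenuates by sinc(0.1/4)
        fs, period = 200.0, 4.0
        t = np.arange(int(60 * fs) + 1) / fs
        p = 30.0 + 20.0 * np.sin(2 * np.pi * t / period)
        out = preprocess_trace(Co2Trace(t=t, p=p, fs_native=fs))
        gain = np.sinc(0.1 / period)
        expect = 30.0 + 20.0 * gain * np.sin(2 * np.pi * out.t / period)
        np.testing.assert_allclose(out.p[20:-20], expect[20:-20], atol=0.2)

    def test_short_trace_rejected(self):
        t = np.arange(50) / 10.0
        with pytest.raises(CapnogramError, match="short"):
            preprocess_trace(Co2Trace(t=t, p=np.full(50, 40.0), fs_native=10.0))


class TestPeakDetectors:
    @pytest.mark.parametrize("detector", [scale_space_peaks, smooth_cross_peaks])
    def test_constant_trace_empty(self, detector):
        t = np.arange(601) / 10.0
        peaks = detector(Co2Trace(t=t, p=np.full(t.size, 40.0), fs_native=10.0))
        assert len(peaks) == 0

    @pytest.mark.parametrize("detector", [scale_space_peaks, smooth_cross_peaks])
    def test_sine_matches_brute_force_oracle(self, detector):
        trace = sine_trace()
        times, values = brute_force_period_argmax(trace, 4.0)
        peaks = detector(trace)
        np.testing.assert_array_equal(peaks.times, times)
        np.testing.assert_allclose(peaks.values, values, atol=0.1)
        assert len(peaks) == 15

    def test_scale_space_rejects_single_sample_spike(self):
        trace = sine_trace()
        p = trace.p.copy()
        trough = 320  # trough sample (t = 32 s, a multiple of the 4 s period)
        assert p[trough] < 15
        p[trough] += 5.0
        peaks = scale_space_peaks(Co2Trace(t=trace.t, p=p, fs_native=10.0))
        assert trace.t[trough] not in peaks.times
        assert len(peaks) == 15

    def test_smooth_cross_step_trace_levels(self):
        # 60 mmHg crests in the first minute, 75 mmHg crests in the second
        t = np.arange(1201) / 10.0
        p = np.where(t < 60, 20.0 * (1 - np.cos(2 * np.pi * t / 4.0)) + 20.0,
                     25.0 * (1 - np.cos(2 * np.pi * t / 4.0)) + 25.0)
        peaks = smooth_cross_peaks(Co2Trace(t=t, p=p, fs_native=10.0))
        first = peaks.values[peaks.times < 55]
        second = peaks.values[peaks.times > 70]
        assert np.all(np.abs(first - 60.0) < 1.0)
        assert np.all(np.abs(second - 75.0) < 1.0)

    def test_requires_10hz(self):
        t = np.arange(0, 1200) / 20.0
        with pytest.raises(CapnogramError, match="10 Hz"):
            scale_space_peaks(Co2Trace(t=t, p=np.sin(t), fs_native=20.0))


class TestRegularize:
    def test_median_filter_removes_partial_breath(self):
        out = _median_filter_clipped(np.array([40.0, 40.0, 12.0, 40.0, 40.0]))
        np.testing.assert_array_equal(out, 40.0)

    def test_median_filter_preserves_monotone(self):
        vals = np.array([40.0, 42.0, 44.0, 46.0, 48.0, 50.0])
        np.testing.assert_array_equal(_median_filter_clipped(vals), vals)

    def test_single_peak_held_constant(self):
        peaks = PeakSet(times=np.array([30.0]), values=np.array([40.0]), source="t")
        t, v = regularize_peaks(peaks, t_end=60.0)
        np.testing.assert_array_equal(t, np.arange(61.0))
        np.testing.assert_array_equal(v, 40.0)

    def test_linear_interpolation_between_peaks(self):
        peaks = PeakSet(times=np.array([0.0, 4.0, 8.0]),
                        values=np.array([40.0, 44.0, 48.0]), source="t")
        t, v = regularize_peaks(peaks, t_end=8.0)
        assert v[2] == pytest.approx(42.0)
        assert v[6] == pytest.approx(46.0)

    def test_empty_peaks_rejected(self):
        with pytest.raises(CapnogramError):
            regularize_peaks(PeakSet(times=np.array([]), values=np.array([]), source="t"), 60.0)


class TestCombine:
    def test_idempotent(self):
        t = np.arange(10.0)
        v = 40.0 + np.sin(t)
        out = combine_envelopes((t, v), (t, v.copy()))
        np.testing.assert_array_equal(out.v, v)

    def test_elementwise_max(self):
        t = np.array([0.0, 1.0])
        out = combine_envelopes((t, np.array([38.0, 40.0])), (t, np.array([40.0, 38.0])))
        np.testing.assert_array_equal(out.v, [40.0, 40.0])

    def test_summary_statistics(self):
        v = np.array([30.0, 30.0, 30.0, 40.0, 40.0, 40.0, 40.0, 40.0])
        curve = EtCo2Curve(t=np.arange(8.0), v=v)
        assert curve.baseline_etco2 == pytest.approx(30.0)  # ceil(0.25*8) = 2 smallest
        assert curve.mean_etco2 == pytest.approx(36.25)

    def test_grid_mismatch_rejected(self):
        with pytest.raises(CapnogramError):
            combine_envelopes((np.arange(5.0), np.ones(5)), (np.arange(4.0), np.ones(4)))


def block_means(curve, truth, block_s=60.0, margin_s=5.0):
    """Mean extracted-vs-truth error per block, excluding transition margins."""
    n_blocks = int(curve.t[-1] // block_s)
    errs = []
    for b in range(n_blocks):
        sel = (curve.t >= b * block_s + margin_s) & (curve.t < (b + 1) * block_s - margin_s)
        tsel = (truth.t >= b * block_s + margin_s) & (truth.t < (b + 1) * block_s - margin_s)
        errs.append(curve.v[sel].mean() - truth.v[tsel].mean())
    return np.asarray(errs)


class TestExtraction:
    def test_standard_capnogram_block_recovery(self, standard_capnogram, standard_etco2):
        _, _, truth = standard_capnogram
        curve, qc = standard_etco2
        assert np.all(np.abs(block_means(curve, truth)) < 0.5)
        assert qc["n_peaks_scale_space"] >= 80
        assert qc["n_peaks_smooth_cross"] >= 80
        assert not qc["co2_switching_flag"]

    def test_partial_breaths_absorbed(self):
        spec = PhantomSpec(breath_period_sd=0.0, partial_breath_rate=0.10,
                           capno_duration_s=420.0, seed=7)
        trace, truth = simulate_capnogram(spec)
        curve, _ = extract_etco2(trace)
        assert np.all(np.abs(block_means(curve, truth)) < 1.0)

    def test_variable_breathing(self):
        spec = PhantomSpec(breath_period_sd=0.8, capno_duration_s=420.0, seed=11)
        trace, truth = simulate_capnogram(spec)
        curve, _ = extract_etco2(trace)
        assert np.all(np.abs(block_means(curve, truth)) < 1.0)

    def test_pure_noise_flagged_or_rejected(self, rng):
        t = np.arange(3501) / 10.0
        trace = Co2Trace(t=t, p=40.0 + rng.normal(0, 3, t.size), fs_native=10.0)
        try:
            _, qc = extract_etco2(trace)
        except CapnogramError:
            return  # unusable capnogram is an acceptable outcome
        # otherwise the QC disagreement between detectors must reveal the problem
        assert qc["disagreement_fraction"] > 0.05 or np.isnan(qc["disagreement_fraction"])

    def test_envelope_properties(self, standard_capnogram, standard_etco2):
        """Envelope within trace range, >= the 10 s moving average at >= 95% of points."""
        from scipy.ndimage import uniform_filter1d
        _, trace, _ = standard_capnogram
        curve, _ = standard_etco2
        pre = preprocess_trace(trace)
        assert curve.v.min() >= pre.p.min() - 1e-9
        assert curve.v.max() <= pre.p.max() + 1e-9
        ma = uniform_filter1d(pre.p, size=101, mode="nearest")
        ma_at_grid = np.interp(curve.t, pre.t, ma)
        assert np.mean(curve.v >= ma_at_grid - 1e-9) >= 0.95

    def test_max_combination_dominates_each_detector(self, standard_capnogram):
        _, trace, _ = standard_capnogram
        pre = preprocess_trace(trace)
        t_end = pre.t[-1]
        a = regularize_peaks(scale_space_peaks(pre), t_end)
        b = regularize_peaks(smooth_cross_peaks(pre), t_end)
        combined = combine_envelopes(a, b)
        assert np.all(combined.v >= a[1] - 1e-12)
        assert np.all(combined.v >= b[1] - 1e-12)

    def test_too_short_rejected(self):
        t = np.arange(200) / 10.0
        with pytest.raises(CapnogramError):
            extract_etco2(Co2Trace(t=t, p=40 - 20 * np.cos(2 * np.pi * t / 4), fs_native=10.0))


class TestSwitchingCheck:
    @pytest.mark.parametrize("baseline, expected", [(40.0, False), (24.9, True), (25.0, False)])
    def test_threshold_boundary(self, baseline, expected):
        # curve whose bottom-25% average equals `baseline` exactly
        v = np.concatenate([np.full(25, baseline), np.full(75, baseline + 8.0)])
        flag, msg = check_co2_switching(EtCo2Curve(t=np.arange(100.0), v=v))
        assert flag is expected
        assert (msg != "") is expected
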