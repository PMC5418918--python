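import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fecg.errors import EstimationError, ParameterError, SegmentationError
from fecg.sbmm import (
    build_template,
    modulate_segment,
    sbmm_denoise,
    segment_beats,
)
from fecg.signal_model import RPeakSeries, Trace
from fecg.synthgen import BeatShape, _render_beats
from tests.conftest import make_periodic_ecg

FS = 1000.0


def beats_trace(r_times_s, duration_s, fs=FS, shape=None, amplitude=100.0):
    """Render beats at explicit R times (deterministic, no noise)."""
    r_times = np.asarray(r_times_s, dtype=float)
    rr = np.append(np.diff(r_times), np.median(np.diff(r_times)))
    t = np.arange(int(duration_s * fs)) / fs
    shape = shape or BeatShape.maternal()
    x = _render_beats(r_times, rr, shape, t, fs, float(np.median(rr))) * amplitude
    peaks = RPeakSeries(np.round(r_times * fs).astype(int), fs,
                        source="synthetic_truth")
    return Trace(x, fs), peaks


class TestSegmentBeats:
    def test_constant_rr_arithmetic(self):
        tr = Trace(np.zeros(3000), FS)
        pk = RPeakSeries([500, 1500, 2500], FS)
        seg = segment_beats(tr, pk, qrs_pre_ms=100, qrs_post_ms=100)
        assert seg.n_beats == 2
        assert seg.qrs_len == 200
        np.testing.assert_array_equal(seg.tu_len, [800, 800])
        np.testing.assert_array_equal(seg.qrs_start, [400, 1400])
        np.testing.assert_array_equal(seg.tu_end, [1400, 2400])

    def test_varying_rr_tu_lengths(self):
        tr = Trace(np.zeros(3000), FS)
        pk = RPeakSeries([500, 1300, 2500], FS)
        seg = segment_beats(tr, pk, qrs_pre_ms=100, qrs_post_ms=100)
        np.testing.assert_array_equal(seg.tu_len, [600, 1000])

    def test_rr_shorter_than_window_rejected(self):
        tr = Trace(np.zeros(1000), FS)
        pk = RPeakSeries([500, 650], FS)
        with pytest.raises(SegmentationError):
            segment_beats(tr, pk, qrs_pre_ms=100, qrs_post_ms=100)

    def test_needs_two_peaks(self):
        tr = Trace(np.zeros(1000), FS)
        with pytest.raises(SegmentationError):
            segment_beats(tr, RPeakSeries([500], FS))

    def test_edge_beats_dropped(self):
        tr = Trace(np.zeros(1200), FS)
        # first beat would start at -50, last would end at 1250
        pk = RPeakSeries([50, 500, 900, 1300 - 50], FS)
        with pytest.raises(Exception):
            pk.validate_for(tr)
        pk = RPeakSeries([50, 500, 900, 1150], FS)
        seg = segment_beats(tr, pk, qrs_pre_ms=100, qrs_post_ms=100)
        # only the middle beats fit entirely inside the trace
        assert np.all(seg.qrs_start >= 0)
        assert np.all(seg.tu_end <= 1200)
        assert seg.n_beats == 2


class TestModulateSegment:
    def test_linear_ramp_exact(self):
        out = modulate_segment(np.array([0.0, 1.0, 2.0, 3.0, 4.0]), 9,
                               interpolation="linear")
        np.testing.assert_allclose(out, np.arange(9) * 0.5, atol=1e-12)

    def test_identity_when_same_length(self, rng):
        seg = rng.standard_normal(50)
        np.testing.assert_array_equal(modulate_segment(seg, 50), seg)

    def test_endpoints_preserved(self, rng):
        seg = rng.standard_normal(37)
        out = modulate_segment(seg, 64)
        assert out[0] == seg[0]
        assert out[-1] == seg[-1]

    @pytest.mark.parametrize("target", [50, 75, 120, 200])
    def test_round_trip_band_limited(self, target):
        # smooth band-limited wave; oracle is the dense analytic resampling
        L = 100
        x = np.linspace(0.0, 1.0, L)
        seg = np.sin(2 * np.pi * 2 * x) + 0.5 * np.cos(2 * np.pi * 3 * x)
        back = modulate_segment(modulate_segment(seg, target), L)
        ptp = np.ptp(seg)
        assert np.max(np.abs(back - seg)) < 0.01 * ptp

    def test_degenerate_lengths(self):
        with pytest.raises(ParameterError):
            modulate_segment(np.array([1.0]), 10)
        with pytest.raises(ParameterError):
            modulate_segment(np.array([1.0, 2.0]), 1)

    def test_short_segment_linear_fallback(self):
        out = modulate_segment(np.array([0.0, 3.0, 6.0]), 5)
        np.testing.assert_allclose(out, [0.0, 1.5, 3.0, 4.5, 6.0])

    @given(
        st.integers(min_value=2, max_value=60),
        st.integers(min_value=2, max_value=60),
        st.integers(min_value=0, max_value=2**16),
    )
    @settings(max_examples=60, deadline=None)
    def test_length_and_endpoint_contract(self, n, m, seed):
        seg = np.random.default_rng(seed).standard_normal(n)
        out = modulate_segment(seg, m)
        assert out.size == m
        assert out[0] == seg[0] and out[-1] == seg[-1]


class TestBuildTemplate:
    def test_identical_beats_recovered(self):
        trace, peaks = make_periodic_ecg(n_beats=10, rr_s=0.8, fs=FS)
        seg = segment_beats(trace, peaks, 100, 100)
        tpl = build_template(trace, seg)
        # interior beats are identical, so the median template equals any
        # one of them (the two edge beats lack a neighbour's wave tails)
        i = 2
        qrs_i = trace.samples[seg.qrs_start[i]: seg.qrs_end[i]]
        tu_i = trace.samples[seg.tu_start[i]: seg.tu_end[i]]
        np.testing.assert_allclose(tpl.qrs_template, qrs_i, atol=1e-9)
        np.testing.assert_allclose(tpl.tu_template, tu_i, atol=1e-9)

    def test_reference_tu_len_default_is_median(self):
        tr = Trace(np.zeros(4000), FS)
        pk = RPeakSeries([300, 1000, 1800, 2800], FS)  # TU lens 500, 600, 800
        seg = segment_beats(tr, pk, 100, 100)
        tpl = build_template(tr, seg)
        assert tpl.reference_tu_len == 600

    def test_fewer_than_two_beats(self):
        tr = Trace(np.zeros(2000), FS)
        pk = RPeakSeries([500, 1500], FS)
        seg = segment_beats(tr, pk, 100, 100)
        with pytest.raises(EstimationError):
            build_template(tr, seg)

    def test_mean_template_noise_reduction_scaling(self):
        # Monte-Carlo oracle: pointwise error SD of the mean template over
        # N noisy copies of a clean beat concentrates at noise_sd/sqrt(N)
        n_beats, rr, sigma = 16, 0.5, 5.0
        clean, peaks = make_periodic_ecg(n_beats=n_beats, rr_s=rr, fs=FS)
        errors = []
        master = np.random.default_rng(2024)
        for _ in range(300):
            noisy = clean.with_samples(
                clean.samples + sigma * master.standard_normal(len(clean))
            )
            seg = segment_beats(noisy, peaks, 100, 100)
            tpl = build_template(noisy, seg, stat="mean")
            cseg = segment_beats(clean, peaks, 100, 100)
            ctpl = build_template(clean, cseg, stat="mean")
            errors.append(tpl.qrs_template - ctpl.qrs_template)
        err_sd = np.std(np.concatenate(errors))
        expected = sigma / np.sqrt(seg.n_beats)
        assert err_sd == pytest.approx(expected, rel=0.10)

    def test_stretched_tu_recovered(self):
        # 3 beats with the same smooth TU wave stretched to different lengths
        qrs_len, lengths, ref = 40, (700, 800, 900), 800
        base = np.linspace(0.0, 1.0, ref)
        wave = np.sin(np.pi * base) + 0.3 * np.sin(2 * np.pi * base)
        beats = []
        for L in lengths:
            tu = modulate_segment(wave, L)
            beats.append(np.concatenate([np.zeros(qrs_len), tu]))
        samples = np.concatenate(beats + [np.zeros(qrs_len + 10)])
        starts = np.cumsum([0] + [qrs_len + L for L in lengths])
        r_idx = starts + qrs_len // 2
        trace = Trace(samples, FS)
        peaks = RPeakSeries(r_idx, FS)
        seg = segment_beats(trace, peaks, qrs_pre_ms=qrs_len / 2, qrs_post_ms=qrs_len / 2)
        tpl = build_template(trace, seg, reference_tu_len=ref)
        err = np.max(np.abs(tpl.tu_template - wave))
        assert err < 0.01 * np.ptp(wave)

    def test_bad_stat(self):
        tr, pk = make_periodic_ecg(n_beats=5)
        seg = segment_beats(tr, pk, 100, 100)
        with pytest.raises(ParameterError):
            build_template(tr, seg, stat="mode")


class TestDenoise:
    def test_periodic_identity(self):
        trace, peaks = make_periodic_ecg(n_beats=30, rr_s=0.75, fs=FS)
        clean, residual = sbmm_denoise(trace, peaks)
        seg = segment_beats(trace, peaks, 100, 100)
        lo, hi = seg.qrs_start[0], seg.tu_end[-1]
        ptp = np.ptp(trace.samples)
        assert np.max(np.abs(residual.samples[lo:hi])) < 0.01 * ptp

    def test_conservation_bit_level(self, rng):
        trace, peaks = make_periodic_ecg(n_beats=15)
        noisy = trace.with_samples(trace.samples + rng.standard_normal(len(trace)))
        clean, residual = sbmm_denoise(noisy, peaks)
        np.testing.assert_allclose(clean.samples + residual.samples,
                                   noisy.samples, rtol=0, atol=1e-9)

    def test_white_noise_recovery(self):
        sigma = 8.0
        trace, peaks = make_periodic_ecg(n_beats=60, rr_s=0.75, fs=FS)
        noise = np.random.default_rng(99).standard_normal(len(trace)) * sigma
        noisy = trace.with_samples(trace.samples + noise)
        clean, residual = sbmm_denoise(noisy, peaks)
        seg = segment_beats(trace, peaks, 100, 100)
        lo, hi = seg.qrs_start[0], seg.tu_end[-1]
        resid_sd = np.std(residual.samples[lo:hi])
        assert resid_sd == pytest.approx(sigma, rel=0.10)
        r = np.corrcoef(clean.samples[lo:hi], trace.samples[lo:hi])[0, 1]
        assert r >= 0.99

    def test_edges_passed_through(self, rng):
        trace, peaks = make_periodic_ecg(n_beats=10)
        noisy = trace.with_samples(trace.samples + rng.standard_normal(len(trace)))
        clean, residual = sbmm_denoise(noisy, peaks)
        seg = segment_beats(noisy, peaks, 100, 100)
        lo, hi = seg.qrs_start[0], seg.tu_end[-1]
        np.testing.assert_array_equal(clean.samples[:lo], noisy.samples[:lo])
        np.testing.assert_array_equal(clean.samples[hi:], noisy.samples[hi:])
        assert np.all(residual.samples[:lo] == 0)
        assert np.all(residual.samples[hi:] == 0)

    def test_identity_limit_monotone_in_noise(self):
        trace, peaks = make_periodic_ecg(n_beats=30, rr_s=0.75, fs=FS)
        seg = segment_beats(trace, peaks, 100, 100)
        lo, hi = seg.qrs_start[0], seg.tu_end[-1]
        rms = []
        for sigma in (10.0, 1.0, 0.1):
            noise = np.random.default_rng(5).standard_normal(len(trace)) * sigma
            noisy = trace.with_samples(trace.samples + noise)
            clean, _ = sbmm_denoise(noisy, peaks)
            rms.append(np.sqrt(np.mean(
                (clean.samples[lo:hi] - trace.samples[lo:hi]) ** 2)))
        assert rms[0] > rms[1] > rms[2]

    def test_hrv_tracking_beats_fixed_template(self):
        # TU length varies ±15% beat to beat; the modulated template must
        # beat an ablation that pastes one unmodulated average beat per R peak
        rr0 = 0.75
        n_beats = 24
        rr = rr0 * (1.0 + 0.15 * np.where(np.arange(n_beats) % 2 == 0, 1.0, -1.0))
        r_times = 0.5 + np.concatenate([[0.0], np.cumsum(rr[:-1])])
        duration = r_times[-1] + 1.0
        trace, peaks = beats_trace(r_times, duration)
        clean, residual = sbmm_denoise(trace, peaks)
        seg = segment_beats(trace, peaks, 100, 100)
        lo, hi = seg.qrs_start[0], seg.tu_end[-1]
        sbmm_rms = np.sqrt(np.mean(residual.samples[lo:hi] ** 2))

        # ablation: average beat at fixed length, pasted unmodulated
        beat_len = int(np.median(np.diff(peaks.indices)))
        stack = []
        for a in seg.qrs_start:
            if a + beat_len <= len(trace):
                stack.append(trace.samples[a: a + beat_len])
        avg_beat = np.mean(stack, axis=0)
        fixed = trace.samples.copy()
        for a, b in zip(seg.qrs_start, seg.tu_end):
            span = min(beat_len, b - a)
            fixed[a: a + span] = avg_beat[:span]
        fixed_rms = np.sqrt(np.mean((trace.samples[lo:hi] - fixed[lo:hi]) ** 2))
        assert sbmm_rms < fixed_rms

    def test_artifact_robust_median(self):
        trace, peaks = make_periodic_ecg(n_beats=9, rr_s=0.8, fs=FS)
        spike_amp = 10.0 * np.ptp(trace.samples)
        corrupted = trace.samples.copy()
        k = peaks.indices[4]
        corrupted[k + 150: k + 170] += spike_amp
        bad = trace.with_samples(corrupted)

        seg = segment_beats(trace, peaks, 100, 100)
        tpl_clean = build_template(trace, seg, stat="median")
        tpl_bad = build_template(bad, segment_beats(bad, peaks, 100, 100),
                                 stat="median")
        assert np.max(np.abs(tpl_bad.tu_template - tpl_clean.tu_template)) \
            < spike_amp / 2
        assert np.max(np.abs(tpl_bad.qrs_template - tpl_clean.qrs_template)) \
            < spike_amp / 2

        # beats other than the corrupted one are reconstructed unchanged
        clean_ref, _ = sbmm_denoise(trace, peaks)
        clean_bad, _ = sbmm_denoise(bad, peaks)
        for i in range(seg.n_beats):
            if i == 4:
                continue
            a, b = seg.qrs_start[i], seg.tu_end[i]
            assert np.max(np.abs(clean_bad.samples[a:b] - clean_ref.samples[a:b])) \
                < 1e-6 * spike_amp
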