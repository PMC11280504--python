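"""Repetition extraction: valley detection, QC rules, standardisation."""

import numpy as np
import pytest

from fallscore import segmentation as seg
from fallscore.skeleton_io import AngleSeries, canonical_channels


def brute_force_extrema(trace):
    """Oracle: strict local minima/maxima by direct neighbour comparison."""
    minima, maxima = [], []
    for i in range(1, len(trace) - 1):
        if trace[i] < trace[i - 1] and trace[i] < trace[i + 1]:
            minima.append(i)
        if trace[i] > trace[i - 1] and trace[i] > trace[i + 1]:
            maxima.append(i)
    return minima, maxima


def series_from_trace(trace, channel="KNEERIGHT_a_SP"):
    return AngleSeries([channel], np.asarray(trace, dtype=float)[:, None])


def multi_cycle_trace(k, period=90, amp=40.0, base=130.0, n_pad=30):
    """k raised-cosine valleys with standing plateaus clipped off the ends."""
    t = np.arange(k * period + 1)
    trace = base - amp * (1 - np.cos(2 * np.pi * t / period)) / 2
    lead = np.full(n_pad, base)
    return np.concatenate((lead, trace, lead))


class TestDetectValleys:
    def test_monotone_trace_has_no_valleys(self):
        assert seg.detect_valleys(np.linspace(0, 100, 200)) == []

    def test_five_cycle_trace_yields_five_windows(self):
        windows = seg.detect_valleys(multi_cycle_trace(5))
        assert len(windows) == 5
        starts = [w.start_frame for w in windows]
        assert starts == sorted(starts)
        for w1, w2 in zip(windows, windows[1:]):
            assert w1.end_frame <= w2.start_frame  # interiors disjoint

    def test_sinusoid_boundaries_match_analytic_extrema(self):
        # 3 periods of a sinusoid: maxima at 1/4 + j, minima at 3/4 + j
        n_per = 120
        t = np.arange(3 * n_per)
        trace = 100 + 50 * np.sin(2 * np.pi * t / n_per)
        windows = seg.detect_valleys(trace, smoothing_window=1, order=20)
        expected_max = [n_per / 4 + j * n_per for j in range(3)]
        assert len(windows) == 3
        for w, left, right in zip(windows[:2], expected_max[:-1], expected_max[1:]):
            assert abs(w.start_frame - left) <= 1
            assert abs(w.end_frame - right) <= 1
        # last valley has no flanking maximum on the right: boundary fallback
        assert abs(windows[2].start_frame - expected_max[2]) <= 1
        assert windows[2].end_frame == len(trace) - 1

    @pytest.mark.parametrize("k", range(1, 9))
    def test_valley_count_matches_brute_force_for_k_cycles(self, k):
        trace = multi_cycle_trace(k)
        windows = seg.detect_valleys(trace)
        smoothed = seg._smooth(trace, 15)
        minima, _ = brute_force_extrema(smoothed)
        assert len(windows) == len(minima) == k

    def test_too_short_trace_rejected(self):
        with pytest.raises(ValueError):
            seg.detect_valleys(np.zeros(30), order=20)


class TestSnip:
    def test_window_length_arithmetic(self, rng):
        series = AngleSeries(["KNEERIGHT_a_SP"], rng.uniform(0, 180, (300, 1)))
        out = seg.snip_repetition(series, seg.RepetitionWindow(10, 89))
        assert out.n_frames == 80
        np.testing.assert_array_equal(out.values, series.values[10:90])

    def test_full_span_is_identity(self, rng):
        series = AngleSeries(["KNEERIGHT_a_SP"], rng.uniform(0, 180, (50, 1)))
        out = seg.snip_repetition(series, seg.RepetitionWindow(0, 49))
        np.testing.assert_array_equal(out.values, series.values)

    def test_snip_composition(self, rng):
        series = AngleSeries(["KNEERIGHT_a_SP"], rng.uniform(0, 180, (100, 1)))
        once = seg.snip_repetition(series, seg.RepetitionWindow(20, 79))
        twice = seg.snip_repetition(once, seg.RepetitionWindow(5, 30))
        composed = seg.snip_repetition(series, seg.RepetitionWindow(25, 50))
        np.testing.assert_array_equal(twice.values, composed.values)

    def test_out_of_range_window(self, rng):
        series = AngleSeries(["KNEERIGHT_a_SP"], rng.uniform(0, 180, (50, 1)))
        with pytest.raises(IndexError):
            seg.snip_repetition(series, seg.RepetitionWindow(10, 50))


class TestValidate:
    @pytest.mark.parametrize("first,last,accepted", [
        (170.0, 170.0, True),    # zero difference
        (100.0, 135.0, False),   # 35 > 30 rejected
        (150.0, 120.0, True),    # exactly 30: rule rejects strictly "more than"
    ])
    def test_start_end_angle_rule(self, first, last, accepted):
        trace = np.linspace(first, last, 40)
        ok, reason = seg.validate_repetition(
            series_from_trace(trace), "KNEERIGHT_a_SP")
        assert ok is accepted
        if not accepted:
            assert "30" in reason

    def test_missing_channel_is_configuration_error(self):
        with pytest.raises(KeyError):
            seg.validate_repetition(
                series_from_trace(np.zeros(10)), "HIPLEFT_a_SP")


class TestResample:
    def test_same_length_resample_is_identity(self, rng):
        series = series_from_trace(rng.uniform(0, 180, 80))
        out = seg.resample_repetition(series, 80)
        np.testing.assert_allclose(out.values, series.values, atol=1e-6)

    def test_band_limited_signal_matches_analytic_values(self):
        # one period of sin over 100 frames resampled onto an 80-frame grid
        n_in, n_out = 100, 80
        t_in = np.arange(n_in) / n_in
        series = series_from_trace(90 + 30 * np.sin(2 * np.pi * t_in))
        out = seg.resample_repetition(series, n_out)
        t_out = np.arange(n_out) / n_out
        np.testing.assert_allclose(
            out.values[:, 0], 90 + 30 * np.sin(2 * np.pi * t_out), atol=1e-6)

    def test_output_length_and_mean_preservation(self, rng):
        # Fourier resampling preserves the DC component exactly
        trace = 100 + 20 * np.sin(2 * np.pi * np.arange(64) / 64)
        out = seg.resample_repetition(series_from_trace(trace), 80)
        assert out.n_frames == 80
        assert out.values.mean() == pytest.approx(trace.mean(), abs=1e-6)

    def test_bad_target_rejected(self):
        with pytest.raises(ValueError):
            seg.resample_repetition(series_from_trace(np.zeros(10)), 3)


class TestPadNormalizeSelect:
    def test_pad_replicates_edges_to_200_frames(self, rng):
        series = AngleSeries(["A_a_SP".replace("A", "KNEERIGHT")],
                             rng.uniform(0, 180, (80, 1)))
        out = seg.pad_repetition(series, 60)
        assert out.n_frames == 200
        assert (out.values[:60] == series.values[0]).all()
        assert (out.values[140:] == series.values[-1]).all()
        np.testing.assert_array_equal(out.values[60:140], series.values)

    def test_constant_channel_normalises_to_inverse_sqrt_n(self):
        series = AngleSeries(["KNEERIGHT_a_SP"], np.full((200, 1), 5.0))
        out = seg.normalize_repetition(series)
        np.testing.assert_allclose(out.values, 1 / np.sqrt(200), atol=1e-12)

    def test_unit_norm_and_scale_invariance(self, rng):
        values = rng.normal(size=(200, 4))
        channels = ["SPINEMID_a_SP", "SPINEMID_a_FP", "NECK_a_SP", "NECK_a_FP"]
        out = seg.normalize_repetition(AngleSeries(channels, values))
        np.testing.assert_allclose(np.linalg.norm(out.values, axis=0), 1.0,
                                   atol=1e-9)
        doubled = seg.normalize_repetition(AngleSeries(channels, 2 * values))
        np.testing.assert_allclose(doubled.values, out.values, atol=1e-12)

    def test_zero_channel_passes_through(self):
        series = AngleSeries(["KNEERIGHT_a_SP"], np.zeros((200, 1)))
        out = seg.normalize_repetition(series)
        assert (out.values == 0).all()

    def test_normalisation_matches_sklearn(self, rng):
        sklearn_prep = pytest.importorskip("sklearn.preprocessing")
        values = rng.normal(size=(200, 6))
        channels = [f"HIPLEFT_a_{p}" for p in ("SP", "FP", "TP")] + \
                   [f"HIPRIGHT_a_{p}" for p in ("SP", "FP", "TP")]
        ours = seg.normalize_repetition(AngleSeries(channels, values))
        theirs = sklearn_prep.normalize(values.T, norm="l2").T
        np.testing.assert_allclose(ours.values, theirs, atol=1e-12)

    def test_select_16_of_75_and_idempotence(self, rng):
        series = AngleSeries(canonical_channels(), rng.uniform(0, 180, (10, 75)))
        out = seg.select_channels(series)
        assert out.channels == list(seg.SELECTED_CHANNELS)
        assert out.values.shape == (10, 16)
        again = seg.select_channels(out)
        np.testing.assert_array_equal(again.values, out.values)

    def test_select_all_in_canonical_order_is_identity(self, rng):
        series = AngleSeries(canonical_channels(), rng.uniform(0, 180, (5, 75)))
        out = seg.select_channels(series, tuple(canonical_channels()))
        np.testing.assert_array_equal(out.values, series.values)

    def test_absent_channel_named_in_error(self, rng):
        series = AngleSeries(["KNEERIGHT_a_SP"], rng.uniform(0, 180, (5, 1)))
        with pytest.raises(KeyError, match="SPINEMID_a_SP"):
            seg.select_channels(series)


class TestExtractRepetitions:
    def test_clean_synthetic_sts5_gives_five_standard_reps(self, noise_free_series):
        reps = seg.extract_repetitions(noise_free_series, subject_id="S1")
        assert len(reps) == 5
        for rep in reps:
            assert rep.values.shape == (200, 16)
            assert rep.channels == list(seg.SELECTED_CHANNELS)

    def test_final_cycle_ending_40_deg_short_is_detected_but_rejected(self):
        # 4 well-formed valleys plus a fifth whose recovery stalls 40 deg low
        period, amp, base = 90, 40.0, 130.0
        clean = multi_cycle_trace(4)[:-30]  # keep lead-in, drop tail plateau
        u = np.arange(period + 1) / period
        bad = base - 40.0 * u - amp * (1 - np.cos(2 * np.pi * u)) / 2
        tail = np.full(30, bad[-1])
        full = np.concatenate((clean, bad[1:], tail))
        values = np.tile(full[:, None], (1, 75))
        series = AngleSeries(canonical_channels(), np.clip(values, 0, 180))
        result = seg.segment_recording(series, subject_id="S1")
        assert len(result.repetitions) + len(result.rejected) == 5
        assert len(result.repetitions) == 4
        assert any("mismatch" in reason for _, reason in result.rejected)

    def test_monotone_series_yields_empty_list(self):
        values = np.tile(np.linspace(10, 170, 300)[:, None], (1, 75))
        series = AngleSeries(canonical_channels(), values)
        assert seg.extract_repetitions(series) == []

    def test_accepted_reps_obey_start_end_rule_on_source_data(
            self, noise_free_series):
        cfg = seg.SegmentationConfig()
        result = seg.segment_recording(noise_free_series, cfg, subject_id="S1")
        trace = noise_free_series.channel(cfg.driving_channel)
        for rep in result.repetitions:
            start, end = rep.source_span
            assert abs(trace[start] - trace[end]) <= cfg.max_delta_deg
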