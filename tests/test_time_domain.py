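"""Segmentation, PPG noise model and the four time-domain SDNN estimators."""

import numpy as np
import pytest

from wearhrv.io_formats import BeatSeries, ValidationError
from wearhrv.time_domain import (
    classify_sdnn,
    inject_hr_noise,
    ppg_noise_bias,
    ppg_noise_sigma,
    sdann24,
    sdannhr24,
    sdnn24,
    sdnn_estimates,
    sdnni24,
    segment,
)

from conftest import make_series


class TestSegment:
    def test_constant_rate(self):
        series = make_series([1000.0] * 3600)  # 1 h of metronomic beats
        seg = segment(series, 5.0)
        assert seg.n_segments == 12
        np.testing.assert_allclose(seg.ann_ms, 1000.0)
        np.testing.assert_allclose(seg.hr_bpm, 60.0)
        assert np.all(seg.coverage > 0.99)

    def test_gap_window_dropped_by_coverage(self):
        nn = np.full(7200, 1000.0)
        t = np.cumsum(nn) / 1000.0
        # remove beats in [1800, 3600): a 30-min hole in a 2-h record
        keep = (t < 1800) | (t >= 3600)
        series = BeatSeries(subject_id="gap", t=t[keep], nn=nn[keep])
        seg = segment(series, 30.0, min_coverage=0.5)
        assert seg.n_excluded == 1
        assert seg.n_segments == 3

    def test_matches_bruteforce_grouping(self, short_clean_series):
        series = short_clean_series
        w = 5.0
        seg = segment(series, w, min_coverage=0.0)
        # oracle: per-beat python grouping
        edges = {}
        for t, nn in zip(series.t, series.nn):
            k = int((t - series.t[0]) // (w * 60.0))
            edges.setdefault(k, []).append(nn)
        expected = np.array([np.mean(edges[k]) for k in sorted(edges)])
        np.testing.assert_allclose(seg.ann_ms, expected, rtol=1e-12)

    def test_offset_invariance(self, short_clean_series):
        s = short_clean_series
        shifted = BeatSeries(subject_id=s.subject_id, t=s.t + 12345.0, nn=s.nn)
        np.testing.assert_allclose(
            segment(s, 5.0).ann_ms, segment(shifted, 5.0).ann_ms
        )

    def test_short_record_rejected(self):
        with pytest.raises(ValidationError):
            segment(make_series([800.0] * 10), 5.0)


class TestPpgNoiseModel:
    @pytest.mark.parametrize("window, sigma", [(1, 5.91), (5, 5.09), (10, 4.71),
                                               (30, 4.01), (60, 3.95)])
    def test_calibrated_sigmas(self, window, sigma):
        assert ppg_noise_sigma(window) == sigma

    def test_bias_exposed_separately(self):
        assert ppg_noise_bias(1) == 0.03
        assert ppg_noise_bias(60) == -0.35

    def test_interpolation_between_windows(self):
        sig = ppg_noise_sigma(3)
        assert 5.09 < sig < 5.91

    def test_nonpositive_window_rejected(self):
        with pytest.raises(ValidationError):
            ppg_noise_sigma(0)


@pytest.fixture(scope="module")
def segments():
    series = make_series(800.0 + 100.0 * np.sin(np.arange(20000) / 900.0))
    return segment(series, 1.0)


class TestInjectHrNoise:

    def test_zero_sigma_is_identity(self, segments):
        assert inject_hr_noise(segments, 0.0, seed=3) is segments

    def test_deterministic_given_seed(self, segments):
        a = inject_hr_noise(segments, 5.91, seed=42)
        b = inject_hr_noise(segments, 5.91, seed=42)
        np.testing.assert_array_equal(a.hr_bpm, b.hr_bpm)

    def test_injected_error_sd_matches_request(self):
        # law of large numbers: 10^4 segments recover sigma within 2%
        series = make_series(np.full(700000, 850.0))
        seg = segment(series, 1.0, min_coverage=0.9)
        assert seg.n_segments >= 9900
        noisy = inject_hr_noise(seg, 5.91, seed=0)
        eps = noisy.hr_bpm - seg.hr_bpm
        assert abs(np.std(eps) - 5.91) / 5.91 < 0.02

    def test_noiseless_ann_retained(self, segments):
        noisy = inject_hr_noise(segments, 5.0, seed=1)
        np.testing.assert_array_equal(noisy.ann_noiseless_ms, segments.ann_ms)


class TestEstimators:
    def test_sdnn24_constant_zero(self):
        assert sdnn24(make_series([900.0] * 100)) == 0.0

    def test_sdnn24_alternating(self):
        series = make_series([800.0, 1000.0] * 50)
        assert sdnn24(series) == pytest.approx(100.0)

    def test_sdnn24_needs_two_beats(self):
        with pytest.raises(ValidationError):
            sdnn24(make_series([900.0]))

    def test_sdnni24_mean_of_window_sds(self):
        # two 1-min windows engineered with per-window population SDs 10 and 30
        # (second window leads with its longer interval so the boundary beat
        # falls past the window edge)
        w1 = np.tile([990.0, 1010.0], 30)  # SD 10, spans 60 s
        w2 = np.tile([1030.0, 970.0], 30)  # SD 30
        series = make_series(np.concatenate([w1, w2]))
        val = sdnni24(series, 1.0, min_coverage=0.0)
        assert val == pytest.approx(20.0)

    def test_sdnni24_matches_bruteforce(self, short_clean_series):
        series = short_clean_series
        w = 5.0
        val = sdnni24(series, w, min_coverage=0.0)
        groups = {}
        for t, nn in zip(series.t, series.nn):
            groups.setdefault(int((t - series.t[0]) // 300.0), []).append(nn)
        expected = np.mean([np.std(v) for v in groups.values() if len(v) >= 2])
        assert val == pytest.approx(expected, rel=1e-9)

    def test_sdann24_two_levels(self):
        nn = np.concatenate([np.full(100, 900.0), np.full(100, 1100.0)])
        series = make_series(nn)
        seg = segment(series, 1.5, min_coverage=0.0)
        # engineered so windows are pure-level: SD of [900, 1100] means = 100
        assert 60.0 < sdann24(seg) <= 100.0

    def test_law_of_total_variance_equal_count_chunks(self):
        # population variance decomposes exactly over equal-count groups
        rng = np.random.default_rng(17)
        nn = rng.uniform(700, 1100, 1200)
        series = make_series(nn)
        chunks = nn.reshape(40, 30)
        within = np.mean(np.var(chunks, axis=1))
        between = np.var(chunks.mean(axis=1))
        total = sdnn24(series) ** 2
        assert total == pytest.approx(within + between, rel=1e-9)

    def test_sdannhr24_equals_sdann24_without_noise(self, short_clean_series):
        seg = segment(short_clean_series, 5.0)
        assert sdannhr24(seg) == sdann24(seg)

    def test_sdannhr24_constant_hr(self):
        seg = segment(make_series([1000.0] * 3600), 5.0)
        assert sdannhr24(seg) == 0.0

    def test_low_pass_ordering_across_windows(self, clean_series):
        # window averaging discards power: SDANN <= SDNN, decreasing in window
        sdnn = sdnn24(clean_series)
        values = [sdann24(segment(clean_series, w)) for w in (1, 5, 10, 30, 60)]
        assert all(v <= sdnn for v in values)
        assert all(a >= b - 1e-9 for a, b in zip(values, values[1:]))

    def test_estimates_bundle_consistent(self, short_clean_series):
        est = sdnn_estimates(short_clean_series, 5.0)
        assert est.sdannhr24_ms == est.sdann24_ms  # noiseless
        assert est.sdnn24_ms >= est.sdann24_ms


class TestClassifySdnn:
    @pytest.mark.parametrize(
        "value, label",
        [
            (49.9, "unhealthy"),
            (50.0, "compromised"),
            (75.0, "compromised"),
            (100.0, "compromised"),
            (100.1, "healthy"),
            (133.73, "healthy"),
        ],
    )
    def test_thresholds(self, value, label):
        assert classify_sdnn(value) == label

    def test_negative_rejected(self):
        with pytest.raises(ValidationError):
            classify_sdnn(-1.0)
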