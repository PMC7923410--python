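"""Lomb-Scargle PSD normalisation, band powers and the bias corrections."""

import numpy as np
import pytest
import scipy.signal

from wearhrv.io_formats import BeatSeries, ValidationError
from wearhrv.spectral import (
    AprioriSpectrum,
    _lombscargle_chunked,
    adj_mean,
    adj_w,
    band_powers,
    build_apriori_spectrum,
    cutoff_frequency,
    lomb_scargle_psd,
)
from wearhrv.synthetic import GeneratorProfile, generate_beats

from conftest import make_series


def _sinusoid_series(freq_hz, amp_ms, duration_s=7200.0, mean_ms=1000.0):
    n = int(duration_s / (mean_ms / 1000.0))
    t = np.arange(1, n + 1) * (mean_ms / 1000.0)
    nn = mean_ms + amp_ms * np.sin(2 * np.pi * freq_hz * t)
    return BeatSeries(subject_id="sin", t=t, nn=np.maximum(nn, 1.0))


class TestLombScarglePsd:
    def test_periodogram_matches_scipy_reference(self):
        # the vectorised kernel against scipy's implementation
        rng = np.random.default_rng(0)
        t = np.sort(rng.uniform(0, 300, 500))
        y = 2.0 * np.sin(2 * np.pi * 0.07 * t) + rng.normal(0, 1, t.size)
        y -= y.mean()
        om = 2 * np.pi * np.linspace(0.01, 0.45, 300)
        ours = _lombscargle_chunked(t, y, om)
        ref = scipy.signal.lombscargle(t, y, om)
        np.testing.assert_allclose(ours, ref, rtol=1e-9, atol=1e-9)

    def test_sinusoid_total_power(self):
        # a 50 ms amplitude tone carries A^2/2 = 1250 ms^2 of variance
        psd = lomb_scargle_psd(_sinusoid_series(0.01, 50.0))
        assert psd.total_power_ms2 == pytest.approx(1250.0, rel=0.05)

    def test_white_noise_parseval(self):
        rng = np.random.default_rng(1)
        nn = 1000.0 + rng.normal(0, 30.0, 4000)
        series = make_series(nn)
        psd = lomb_scargle_psd(series)
        var = np.var(series.nn)
        assert abs(psd.total_power_ms2 - var) / var < 0.10

    def test_constant_series_zero_spectrum(self):
        psd = lomb_scargle_psd(make_series([900.0] * 100), f_min=1e-3, f_max=0.4)
        assert np.all(psd.power_ms2_per_hz == 0.0)

    def test_too_few_beats_rejected(self):
        with pytest.raises(ValidationError):
            lomb_scargle_psd(make_series([800.0] * 10))


class TestBandPowers:
    @pytest.mark.parametrize("freq, band", [(0.001, "ulf_ms2"), (0.1, "lf_ms2"),
                                            (0.25, "hf_ms2")])
    def test_pure_tone_lands_in_band(self, freq, band):
        duration = max(7200.0, 20.0 / freq)
        psd = lomb_scargle_psd(_sinusoid_series(freq, 40.0, duration))
        bp = band_powers(psd)
        assert getattr(bp, band) >= 0.95 * psd.total_power_ms2

    def test_band_sum_matches_union_integral(self, short_clean_series):
        psd = lomb_scargle_psd(short_clean_series)
        bp = band_powers(psd)
        # oracle: single integral over the union of the four contiguous bands
        lo = max(1.0 / 86400.0, psd.freqs_hz[0])
        hi = min(0.5, psd.freqs_hz[-1])
        inner = (psd.freqs_hz > lo) & (psd.freqs_hz < hi)
        f = np.concatenate([[lo], psd.freqs_hz[inner], [hi]])
        p = np.interp(f, psd.freqs_hz, psd.power_ms2_per_hz)
        union = np.trapezoid(p, f)
        total_bands = bp.ulf_ms2 + bp.vlf_ms2 + bp.lf_ms2 + bp.hf_ms2
        assert total_bands == pytest.approx(union, rel=1e-9)
        assert total_bands <= bp.total_ms2 * (1 + 1e-9)

    def test_edges_outside_grid_rejected(self, short_clean_series):
        psd = lomb_scargle_psd(short_clean_series)
        from wearhrv.spectral import _band_integral

        with pytest.raises(ValidationError):
            _band_integral(psd.freqs_hz, psd.power_ms2_per_hz, 0.1, 10.0)


class TestCutoffFrequency:
    @pytest.mark.parametrize(
        "window, expected",
        [(1, 1.0 / 60.0), (5, 1.0 / 300.0), (10, 1.0 / 600.0),
         (30, 1.0 / 1800.0), (60, 1.0 / 3600.0)],
    )
    def test_inverse_window_length(self, window, expected):
        assert cutoff_frequency(window) == pytest.approx(expected, rel=1e-12)

    def test_printed_rounded_values(self):
        # 1 min -> 1.67e-2 Hz; 5 min -> 0.0033; 60 min -> 2.78e-4
        assert round(cutoff_frequency(1), 4) == 0.0167
        assert round(cutoff_frequency(5), 4) == 0.0033
        assert cutoff_frequency(60) == pytest.approx(2.78e-4, rel=0.01)


class TestAprioriSpectrum:
    def test_mean_of_identical_subjects(self, short_clean_series):
        spec = build_apriori_spectrum([short_clean_series] * 3, n_freqs=300)
        single = lomb_scargle_psd(short_clean_series, freqs_hz=spec.freqs_hz)
        np.testing.assert_allclose(
            spec.mean_power_ms2_per_hz, single.power_ms2_per_hz, rtol=1e-12
        )

    def test_pointwise_mean(self):
        freqs = np.logspace(-4, -1, 50)
        a = AprioriSpectrum(freqs_hz=freqs, mean_power_ms2_per_hz=np.full(50, 4.0))
        assert a.cumulative_power(freqs[-1]) == pytest.approx(a.total_power_ms2)
        # cumulative is monotone
        cums = [a.cumulative_power(f) for f in freqs]
        assert all(x <= y + 1e-12 for x, y in zip(cums, cums[1:]))

    def test_one_over_f_slope_recovered(self):
        # cohort of 1/f subjects: log-log slope of the apriori in the ULF/VLF
        # decade range should sit near -1
        cohort = [
            generate_beats(
                GeneratorProfile(seed=s, duration_h=8.0, circadian_amp_ms=0.0,
                                 lf_amp_ms=0.0, hf_amp_ms=0.0,
                                 ectopic_rate=0.0, gap_rate_per_h=0.0)
            ).truth
            for s in (1, 2, 3)
        ]
        spec = build_apriori_spectrum(cohort, f_min=1 / (8 * 3600.0), n_freqs=400)
        band = (spec.freqs_hz >= 1e-4) & (spec.freqs_hz <= 1e-2)
        slope = np.polyfit(
            np.log10(spec.freqs_hz[band]),
            np.log10(spec.mean_power_ms2_per_hz[band]), 1
        )[0]
        assert -1.5 <= slope <= -0.5

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValidationError):
            build_apriori_spectrum([])


@pytest.fixture(scope="module")
def flat_apriori():
    freqs = np.linspace(1e-4, 0.5, 2000)
    return AprioriSpectrum(freqs_hz=freqs, mean_power_ms2_per_hz=np.full(2000, 100.0))


class TestCorrections:

    def test_adj_mean_arithmetic(self):
        # sqrt(100 + 44) with an apriori holding exactly 44 ms^2 above cutoff
        fc = cutoff_frequency(5)
        freqs = np.array([1e-4, fc, 0.5])
        dens = 44.0 / (0.5 - fc)
        spec = AprioriSpectrum(
            freqs_hz=freqs, mean_power_ms2_per_hz=np.array([0.0, dens, dens])
        )
        assert spec.power_above(fc) == pytest.approx(44.0, rel=1e-12)
        assert adj_mean(100.0, 5, spec) == pytest.approx(12.0, rel=1e-6)

    def test_adj_mean_identity_when_nothing_missing(self, flat_apriori):
        # cutoff beyond grid top would error; at the top the missing power ~ 0
        val = adj_mean(100.0, 1.0 / 30.0, flat_apriori)  # 2-s window, fc = 0.5
        assert val == pytest.approx(10.0, rel=1e-6)

    def test_adj_w_ratio_arithmetic(self):
        # hand-built spectrum: exactly 20 below and 80 above the 5-min cutoff,
        # so a measured variance of 100 rescales to 100 * (1 + 80/20) = 500
        fc = cutoff_frequency(5)
        dens_low, dens_high = 20.0 / 0.001, 80.0 / (0.5 - fc)
        f = np.array([fc - 0.001, fc - 1e-9, fc, 0.5])
        d = np.array([dens_low, dens_low, dens_high, dens_high])
        spec = AprioriSpectrum(freqs_hz=f, mean_power_ms2_per_hz=d)
        assert spec.cumulative_power(fc) == pytest.approx(20.0, rel=1e-3)
        assert spec.power_above(fc) == pytest.approx(80.0, rel=1e-3)
        assert adj_w(100.0, 5, spec) == pytest.approx(np.sqrt(500.0), rel=1e-3)

    def test_adj_w_no_correction_when_high_power_zero(self):
        fc = cutoff_frequency(5)
        f = np.array([1e-4, fc, fc + 1e-9, 0.5])
        d = np.array([100.0, 100.0, 0.0, 0.0])
        spec = AprioriSpectrum(freqs_hz=f, mean_power_ms2_per_hz=d)
        # all apriori power below cutoff: no correction
        assert adj_w(100.0, 5, spec) == pytest.approx(10.0, rel=1e-6)

    def test_corrections_never_reduce(self, flat_apriori):
        for w in (1, 5, 10, 30, 60):
            assert adj_mean(50.0, w, flat_apriori) >= np.sqrt(50.0)
            assert adj_w(50.0, w, flat_apriori) >= np.sqrt(50.0)

    def test_adj_w_scale_equivariance(self, short_clean_series):
        s = short_clean_series
        c = 1.7
        scaled = BeatSeries(subject_id="sc", t=s.t * c, nn=s.nn * c)
        spec = build_apriori_spectrum(
            [s], f_min=1.0 / s.t[-1], f_max=0.4, n_freqs=300
        )
        spec_sc = build_apriori_spectrum(
            [scaled], f_min=1.0 / scaled.t[-1], f_max=0.4 / c, n_freqs=300
        )
        var = float(np.var(s.nn))
        # time axis scales too, so compare at window pairs (w, c*w)
        a = adj_w(var, 5.0, spec)
        b = adj_w(var * c**2, 5.0 * c, spec_sc)
        assert b == pytest.approx(c * a, rel=1e-2)

    def test_cutoff_above_grid_rejected(self, flat_apriori):
        with pytest.raises(ValidationError):
            adj_mean(10.0, 1.0 / 100.0, flat_apriori)  # fc = 1.67 Hz > 0.5
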