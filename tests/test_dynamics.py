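import numpy as np
import pytest

from rcdomains.detection import RCD
from rcdomains.dynamics import (FWHM_FACTOR, fit_flat_topped_gaussian,
                                fit_gaussian, fit_optimal_wavelet,
                                growth_stats, select_isolated)

from conftest import make_track


def rcd_at(pos, W=500e3, height=10.0):
    return RCD("chr1", pos, W, height)


def gaussian_track(amp, centre, sigma, baseline=0.0, bin_size=10_000, n=1200):
    x = (np.arange(n) + 0.5) * bin_size
    return make_track(amp * np.exp(-((x - centre) ** 2) / (2 * sigma ** 2))
                      + baseline, bin_size=bin_size)


def flat_top_track(amp, centre, plateau_half, sigma, bin_size=10_000, n=1200):
    x = (np.arange(n) + 0.5) * bin_size
    d = np.maximum(np.abs(x - centre) - plateau_half, 0.0)
    return make_track(amp * np.exp(-(d ** 2) / (2 * sigma ** 2)),
                      bin_size=bin_size)


class TestIsolation:
    def _track_with(self, under, left, right):
        # peak extent bins 100..149, flanks 50..99 and 150..199 (10 kb bins)
        v = np.zeros(300)
        v[100:150] = under / 50.0
        v[50:100] = left / 50.0
        v[150:200] = right / 50.0
        return make_track(v, bin_size=10_000)

    def test_ratio_below_threshold_accepted(self):
        S = self._track_with(100, 10, 10)
        iso = select_isolated([rcd_at(1_250_000)], S)
        assert len(iso) == 1
        assert iso[0].isolation_ratio == pytest.approx(0.2)

    def test_ratio_above_threshold_rejected(self):
        S = self._track_with(100, 20, 10)
        assert select_isolated([rcd_at(1_250_000)], S) == []

    def test_per_side_variant(self):
        # combined 26 % fails the default rule but each side is under 25 %
        S = self._track_with(100, 24, 2)
        assert select_isolated([rcd_at(1_250_000)], S) == []
        assert len(select_isolated([rcd_at(1_250_000)], S, per_side=True)) == 1
        S = self._track_with(100, 30, 2)          # one side over 25 %
        assert select_isolated([rcd_at(1_250_000)], S, per_side=True) == []

    def test_chromosome_edge_excluded(self):
        S = self._track_with(100, 0, 0)
        assert select_isolated([rcd_at(400_000)], S) == []   # flank underflows


class TestGaussianFit:
    def test_noise_free_self_fit(self):
        S = gaussian_track(10.0, 5_000_000, 100e3, n=1000)
        fit = fit_gaussian(rcd_at(5_000_000), S)
        assert fit.amplitude == pytest.approx(10.0, rel=0.01)
        assert fit.centre == pytest.approx(5_000_000, abs=2_000)
        assert fit.sigma == pytest.approx(100e3, rel=0.01)
        assert fit.fwhm == pytest.approx(235.48e3, rel=0.01)
        assert fit.fwhm == FWHM_FACTOR * fit.sigma            # exact identity

    def test_constant_offset_goes_to_baseline(self):
        S0 = gaussian_track(10.0, 5_000_000, 100e3, n=1000)
        Sc = S0.with_values(S0.values + 3.0)
        f0 = fit_gaussian(rcd_at(5_000_000), S0)
        fc = fit_gaussian(rcd_at(5_000_000), Sc)
        assert fc.baseline - f0.baseline == pytest.approx(3.0, abs=0.1)
        assert fc.sigma == pytest.approx(f0.sigma, rel=0.02)

    def test_sigma_recovery_under_poisson_noise(self):
        # SNR ~ 10 at the peak; recovery within 10 % across replicates
        rng = np.random.default_rng(42)
        errs = []
        for _ in range(100):
            S = gaussian_track(100.0, 5_000_000, 100e3, n=600)
            noisy = S.with_values(rng.poisson(np.clip(S.values, 0, None)))
            fit = fit_gaussian(rcd_at(5_000_000), noisy)
            errs.append(abs(fit.sigma - 100e3) / 100e3)
        assert np.mean(errs) < 0.10


class TestFlatTopFit:
    def test_reduces_to_gaussian_with_zero_plateau(self):
        S = gaussian_track(10.0, 5_000_000, 100e3, n=1000)
        g = fit_gaussian(rcd_at(5_000_000), S)
        ft = fit_flat_topped_gaussian(rcd_at(5_000_000), S,
                                      fix_plateau_zero=True)
        assert ft.plateau_halfwidth == 0.0
        assert ft.sigma == pytest.approx(g.sigma, rel=1e-6)

    def test_plateau_recovery(self):
        S = flat_top_track(10.0, 5_000_000, 200e3, 80e3, n=1000)
        ft = fit_flat_topped_gaussian(rcd_at(5_000_000), S)
        assert ft.plateau_halfwidth == pytest.approx(200e3, rel=0.1)
        assert ft.sigma == pytest.approx(80e3, rel=0.1)

    def test_total_width_at_least_fwhm(self):
        S = flat_top_track(10.0, 5_000_000, 150e3, 80e3, n=1000)
        ft = fit_flat_topped_gaussian(rcd_at(5_000_000), S)
        assert ft.total_width_at_half_max >= ft.fwhm


class TestOptimalWavelet:
    def test_flat_top_width_recovered_every_timepoint(self):
        S = flat_top_track(10.0, 6_000_000, 215e3, 30e3, n=1400)
        # half-max width = 2*215k + fwhm(30k) ~ 500 kb
        series = fit_optimal_wavelet(rcd_at(6_000_000), [S, S, S])
        assert not series.rejected
        for w in series.widths_bp:
            assert w == pytest.approx(500e3, abs=50e3)

    def test_grid_extreme_rejected(self):
        S = flat_top_track(10.0, 6_000_000, 900e3, 100e3, n=1400)  # ~2 Mb wide
        series = fit_optimal_wavelet(rcd_at(6_000_000), [S])
        assert series.rejected and "extreme" in series.reason

    def test_monotone_in_true_width(self):
        tracks = [flat_top_track(10.0, 6_000_000, ph, 30e3, n=1400)
                  for ph in (150e3, 250e3, 350e3)]
        series = fit_optimal_wavelet(rcd_at(6_000_000), tracks)
        w = series.widths_bp
        assert w[0] < w[1] < w[2]


class TestGrowthStats:
    def test_textbook_t(self):
        widths = np.array([[100.0, 102.0], [100.0, 104.0], [100.0, 106.0]])
        gs = growth_stats(widths)
        assert gs.overall_mean_bp == pytest.approx(4.0)
        assert gs.overall_se_bp == pytest.approx(1.1547, rel=1e-3)
        assert gs.overall_t == pytest.approx(3.4641, rel=1e-3)
        assert gs.overall_p == pytest.approx(0.0742, abs=0.002)

    def test_zero_deltas_degenerate(self):
        widths = np.tile([500.0, 500.0, 500.0], (4, 1))
        gs = growth_stats(widths)
        assert gs.degenerate
        assert gs.overall_p == 1.0

    def test_synthetic_gaussian_series_rate(self):
        # noise-free Gaussian bumps whose FWHM widens by 90 kb per pulse:
        # the Gaussian fit recovers the 2 v dt kinetic rate exactly
        fwhms = 400e3 + 90e3 * np.arange(4)
        tracks = [gaussian_track(10.0, 6_000_000, f / FWHM_FACTOR, n=1400)
                  for f in fwhms]
        rows = [fit_gaussian(rcd_at(6_000_000), t).fwhm for t in tracks]
        widths = np.tile(rows, (2, 1))
        gs = growth_stats(widths)
        assert gs.overall_mean_bp == pytest.approx(90e3, rel=0.02)
        assert gs.growth_rate_kb_min == pytest.approx(3.0, rel=0.02)

    def test_too_few_peaks(self):
        with pytest.raises(ValueError):
            growth_stats(np.array([[1.0, 2.0]]))
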