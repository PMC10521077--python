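import numpy as np
import pytest

from rcdomains.tracks_io import RegionSet
from rcdomains.wavelet import (convolve_track, multiscale_transform,
                               multiscale_widths, ricker_kernel, width_scan)

from conftest import make_track


def box_track(width_bp, bin_size=10_000, n=1200, amplitude=10.0, centre=None):
    """Flat-topped feature of the given width on an otherwise flat track."""
    centre = centre if centre is not None else n // 2 * bin_size
    x = (np.arange(n) + 0.5) * bin_size
    v = np.where(np.abs(x - centre) < width_bp / 2, amplitude, 0.0)
    return make_track(v, bin_size=bin_size)


class TestKernel:
    @pytest.mark.parametrize("W,bin_size", [(500e3, 50_000), (500e3, 10_000),
                                            (120e3, 10_000)])
    def test_shape(self, W, bin_size):
        k = ricker_kernel(W, bin_size, norm="max")
        taps = k.taps
        assert len(taps) % 2 == 1
        np.testing.assert_allclose(taps, taps[::-1])          # symmetric
        assert np.argmax(taps) == len(taps) // 2              # centre max
        assert abs(taps.sum()) < 1e-12                        # exact zero mean
        # near-zero crossings at +-sigma
        i_sigma = len(taps) // 2 + int(round(k.sigma / bin_size))
        assert abs(taps[i_sigma]) < 0.05 * taps.max()

    def test_tap_count_from_truncation_rule(self):
        # sigma = W/2 = 250 kb; +-4 sigma = +-1000 kb = +-20 bins of 50 kb
        assert len(ricker_kernel(500e3, 50_000).taps) == 41

    def test_unresolvable_width_rejected(self):
        with pytest.raises(ValueError):
            ricker_kernel(80e3, 50_000)


class TestConvolve:
    def test_constant_input_zero_response_in_interior(self):
        # exact zero away from the zero-padded chromosome ends (the ends
        # carry a documented edge bias within the kernel support)
        t = make_track(np.full(300, 7.5))
        k = ricker_kernel(500e3, 50_000)
        out = convolve_track(t, k)
        h = k.half_support
        np.testing.assert_allclose(out.values[h:-h], 0.0, atol=1e-9)

    def test_linearity(self, rng):
        k = ricker_kernel(300e3, 50_000)
        x, y = rng.normal(size=200), rng.normal(size=200)
        lhs = convolve_track(make_track(2 * x + 3 * y), k).values
        rhs = (2 * convolve_track(make_track(x), k).values
               + 3 * convolve_track(make_track(y), k).values)
        np.testing.assert_allclose(lhs, rhs, atol=1e-9)

    def test_reversal_symmetry(self, rng):
        k = ricker_kernel(300e3, 50_000)
        x = rng.normal(size=257)
        fwd = convolve_track(make_track(x), k).values
        rev = convolve_track(make_track(x[::-1]), k).values
        np.testing.assert_allclose(fwd, rev[::-1], atol=1e-9)

    def test_masked_centre_masked_in_output(self):
        mask = np.ones(100, dtype=bool)
        mask[40:45] = False
        t = make_track(np.ones(100), mask=mask)
        out = convolve_track(t, ricker_kernel(200e3, 50_000))
        assert not out.mask[40:45].any()

    def test_box_matched_width_closed_form(self):
        # peak response of the scale-normalized Ricker to a flat top of
        # width F is (F/sigma)exp(-F^2/8 sigma^2), maximal at W = F
        F = 500e3
        t = box_track(F)
        grid = np.arange(200e3, 1200e3 + 1, 25e3)
        resp = [convolve_track(t, ricker_kernel(w, t.bin_size)).values.max()
                for w in grid]
        assert grid[int(np.argmax(resp))] == pytest.approx(F, abs=25e3)


class TestMultiscale:
    def test_root2_ladder_count(self):
        widths = multiscale_widths(50.0, 51200.0)
        assert len(widths) == 21                 # 50 kb * 2^10 over sqrt(2) steps
        assert widths[0] == pytest.approx(50e3)
        assert widths[-1] == pytest.approx(51.2e6)
        np.testing.assert_allclose(widths[1:] / widths[:-1], np.sqrt(2))

    def test_rows_equal_single_convolutions(self, rng):
        t = make_track(rng.normal(size=400))
        widths, mat = multiscale_transform(t, widths=[200e3, 400e3])
        for w, row in zip(widths, mat):
            np.testing.assert_array_equal(
                row, convolve_track(t, ricker_kernel(w, t.bin_size)).values)

    def test_zero_input_zero_matrix(self):
        t = make_track(np.zeros(300))
        _, mat = multiscale_transform(t, widths=[200e3, 400e3, 800e3])
        assert not mat.any()


class TestWidthScan:
    def test_matched_filter_tracks_bump_width(self):
        # three isolated flat-top features: the scan optimum follows the
        # feature width monotonically and hits the 500 kb feature exactly
        bin_size, n = 10_000, 1500
        region = RegionSet("chr1", [(0, n * bin_size)])
        optima = {}
        for F in (300e3, 500e3, 800e3):
            res = width_scan(box_track(F, bin_size, n), region)
            optima[F] = res.optimal_width()
        assert optima[300e3] < optima[500e3] < optima[800e3]
        assert optima[500e3] == pytest.approx(500e3, abs=50e3)

    def test_amplitude_scaling(self):
        t = box_track(500e3)
        region = RegionSet("chr1", [(0, t.length)])
        r1 = width_scan(t, region)
        t2 = t.with_values(2 * t.values)
        r2 = width_scan(t2, region)
        np.testing.assert_allclose(r2.metric_sum, 2 * r1.metric_sum, rtol=1e-9)
        assert r1.optimal_width() == r2.optimal_width()

    def test_cutoff_never_increases_peak_count(self, rng):
        t = make_track(rng.normal(size=3000), bin_size=50_000)
        half = t.length // 2
        early = RegionSet("chr1", [(0, half)])
        late = RegionSet("chr1", [(half, t.length)])
        free = width_scan(t, early, widths=[300e3, 500e3])
        cut = width_scan(t, early, widths=[300e3, 500e3],
                         cutoff_percentile=70, late_region=late)
        assert (cut.n_peaks <= free.n_peaks).all()

    def test_empty_region_rejected(self):
        with pytest.raises(ValueError):
            width_scan(box_track(300e3), RegionSet("chr1", []))
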