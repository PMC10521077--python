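"""Ricker ("Mexican hat") wavelet construction, convolution, and scale scans.

The wavelet is parameterised by its **peak width** W, the distance between
the zero crossings of the central positive lobe: ``sigma = W / 2``.  Taps
are sampled on the bin grid from ``(1 − t²/σ²)·exp(−t²/2σ²)``, truncated
at ±4σ, and mean-subtracted so that they sum to zero exactly — the
response to any constant track is identically zero despite truncation.

Amplitude normalization ("scale", the default) divides the taps by
σ/bin_size.  Under this convention the peak response to a flat-topped
feature of width F is ``(F/σ)·exp(−F²/8σ²)``, maximised exactly at
σ = F/2, i.e. at W = F: a width scan recovers the feature width.  The
"max" convention (unit central tap) is available for shape inspection but
is not comparable across widths.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .tracks_io import BinnedTrack, RegionSet

__all__ = [
    "RickerKernel",
    "ScaleScanResult",
    "ricker_kernel",
    "convolve_track",
    "multiscale_widths",
    "multiscale_transform",
    "width_scan",
    "FIG_SCAN_WIDTHS_KB",
]

# Closely spaced scan widths (kb) used for locating the dominant scale.
FIG_SCAN_WIDTHS_KB = (100, 150, 200, 250, 300, 350, 400, 450, 500, 550,
                      600, 650, 700, 750, 800, 1000, 1500, 3000)


@dataclass
class RickerKernel:
    peak_width_W: float          # bp, distance between zero crossings
    sigma: float                 # bp, = W/2
    bin_size: int
    taps: np.ndarray             # symmetric, odd length, sum == 0
    norm: str = "scale"

    @property
    def half_support(self) -> int:
        return (len(self.taps) - 1) // 2


def ricker_kernel(peak_width_W: float, bin_size: int, norm: str = "scale") -> RickerKernel:
    """Build a Ricker kernel of the given peak width on a bin grid.

    Raises if ``W < 2·bin_size`` (the scale cannot be resolved).
    """
    if peak_width_W < 2 * bin_size:
        raise ValueError(
            f"peak width {peak_width_W} bp is unresolvable at {bin_size}-bp bins")
    sigma = peak_width_W / 2.0
    half = int(round(4.0 * sigma / bin_size))
    t = np.arange(-half, half + 1) * float(bin_size)
    taps = (1.0 - (t / sigma) ** 2) * np.exp(-(t ** 2) / (2.0 * sigma ** 2))
    if norm == "scale":
        taps = taps * (bin_size / sigma)
    elif norm != "max":
        raise ValueError(f"unknown norm {norm!r}")
    taps = taps - taps.mean()          # exact zero sum despite truncation
    return RickerKernel(peak_width_W=float(peak_width_W), sigma=sigma,
                        bin_size=int(bin_size), taps=taps, norm=norm)


def convolve_track(track: BinnedTrack, kernel: RickerKernel) -> BinnedTrack:
    """Convolve a signal track with a Ricker kernel (same-length output).

    Chromosome ends are zero-padded; masked bins enter the convolution as
    zero but the output is masked wherever the kernel centre sits on a
    masked bin.
    """
    if kernel.bin_size != track.bin_size:
        raise ValueError("kernel and track bin sizes differ")
    vals = np.where(track.mask, track.values, 0.0)
    # full convolution then centre slice: unlike mode="same" this stays
    # aligned when the kernel support exceeds the track length
    full = np.convolve(vals, kernel.taps, mode="full")
    half = (len(kernel.taps) - 1) // 2
    conv = full[half:half + vals.size]
    out = track.with_values(conv, role="signal")
    out.mask = track.mask.copy()
    return out


def multiscale_widths(min_kb: float = 50.0, max_kb: float = 51200.0) -> np.ndarray:
    """Geometric ladder of peak widths (bp) increasing by √2 per step."""
    widths = [min_kb]
    while widths[-1] * np.sqrt(2.0) <= max_kb * 1.0001:
        widths.append(widths[-1] * np.sqrt(2.0))
    return np.asarray(widths) * 1e3


def multiscale_transform(track: BinnedTrack, widths=None,
                         rescale_for_display: bool = False) -> tuple[np.ndarray, np.ndarray]:
    """Convolve one track at a ladder of widths.

    Returns ``(widths_bp, matrix)`` where row k is the convolution at
    ``widths[k]``.  With ``rescale_for_display`` each row is divided by its
    maximum positive value and clamped to [0, 1] — display only; analysis
    uses the raw rows.
    """
    if widths is None:
        widths = multiscale_widths()
    widths = np.asarray(sorted(float(w) for w in widths))
    # widths below two bins are unresolvable on this grid (the finest
    # scales need finer bins) and are dropped from the ladder
    widths = widths[widths >= 2 * track.bin_size]
    rows = []
    for w in widths:
        conv = convolve_track(track, ricker_kernel(w, track.bin_size))
        row = conv.values.copy()
        if rescale_for_display:
            top = row.max()
            row = np.clip(row / top, 0.0, 1.0) if top > 0 else np.zeros_like(row)
        rows.append(row)
    return widths, np.vstack(rows)


@dataclass
class ScaleScanResult:
    widths: np.ndarray                      # bp
    metric_sum: np.ndarray                  # per-width sum of peak heights
    metric_mean: np.ndarray                 # per-width mean of peak heights
    n_peaks: np.ndarray = field(default=None)
    with_cutoff: bool = False

    def optimal_width(self, metric: str = "mean") -> float:
        vals = self.metric_mean if metric == "mean" else self.metric_sum
        return float(self.widths[int(np.argmax(vals))])


def width_scan(track: BinnedTrack, region: RegionSet, widths=None,
               cutoff_percentile: float | None = None,
               late_region: RegionSet | None = None) -> ScaleScanResult:
    """Scan wavelet widths, recording called-peak height sums and means.

    The track is clipped to ``region`` for peak calling.  If
    ``cutoff_percentile`` is given together with ``late_region``, peaks at
    each width are filtered by the nearest-rank percentile of peak heights
    in the late region at the same width before the metrics are recorded.
    """
    from .detection import call_peaks, calibrate_cutoff  # cyclic at import time

    if region.total_span() <= 0:
        raise ValueError("empty region for width scan")
    if widths is None:
        widths = [w * 1e3 for w in FIG_SCAN_WIDTHS_KB]
    widths = np.asarray(sorted(float(w) for w in widths))
    sums, means, counts = [], [], []
    for w in widths:
        conv = convolve_track(track, ricker_kernel(w, track.bin_size))
        peaks = call_peaks(conv, region, width_W=w)
        if cutoff_percentile is not None and late_region is not None:
            late_peaks = call_peaks(conv, late_region, width_W=w)
            if len(late_peaks) >= 10:
                cut = calibrate_cutoff(late_peaks, percentile=cutoff_percentile)
                peaks = [p for p in peaks if p.wavelet_height > cut.threshold_value]
        heights = np.array([p.wavelet_height for p in peaks])
        sums.append(float(heights.sum()))
        means.append(float(heights.mean()) if heights.size else 0.0)
        counts.append(heights.size)
    return ScaleScanResult(widths=widths, metric_sum=np.asarray(sums),
                           metric_mean=np.asarray(means),
                           n_peaks=np.asarray(counts),
                           with_cutoff=cutoff_percentile is not None)
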