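"""Width dynamics of isolated RCDs across the EdU pulse timecourse.

Isolated peaks (flanking signal ≤ 25% of under-peak signal) are followed
through the four pulses and their widths quantified two ways: the best-
matching Ricker peak width on a fine grid (200–1200 kb in 25-kb steps),
and the FWHM of a least-squares Gaussian fitted by Nelder-Mead.  Peaks
whose fit hits the grid extremes at any timepoint are rejected.  Per-
interval width increases are summarised with a one-sample t-test against
zero and converted to a fork-rate-style growth in kb/min.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .detection import RCD
from .tracks_io import BinnedTrack
from .wavelet import convolve_track, ricker_kernel

__all__ = [
    "IsolatedPeak",
    "WidthFitSeries",
    "GaussianFit",
    "FlatToppedGaussianFit",
    "GrowthStats",
    "select_isolated",
    "fit_optimal_wavelet",
    "fit_gaussian",
    "fit_flat_topped_gaussian",
    "growth_stats",
    "default_width_grid",
]

FWHM_FACTOR = 2.0 * np.sqrt(2.0 * np.log(2.0))


def default_width_grid(lo_kb: float = 200.0, hi_kb: float = 1200.0,
                       step_kb: float = 25.0) -> np.ndarray:
    """Fine wavelet width grid (bp), 200–1200 kb in 25-kb steps."""
    return np.arange(lo_kb, hi_kb + step_kb / 2, step_kb) * 1e3


@dataclass
class IsolatedPeak:
    rcd: RCD
    under_peak_signal: float
    flanking_signal: float

    @property
    def isolation_ratio(self) -> float:
        return self.flanking_signal / self.under_peak_signal


@dataclass
class WidthFitSeries:
    peak_id: int
    widths_bp: list[float]
    rejected: bool = False
    reason: str = ""


@dataclass
class GaussianFit:
    amplitude: float
    centre: float
    sigma: float
    baseline: float
    converged: bool

    @property
    def fwhm(self) -> float:
        return FWHM_FACTOR * self.sigma


@dataclass
class FlatToppedGaussianFit(GaussianFit):
    plateau_halfwidth: float = 0.0

    @property
    def total_width_at_half_max(self) -> float:
        return 2.0 * self.plateau_halfwidth + self.fwhm


def _window_sum(S: BinnedTrack, lo: float, hi: float) -> float:
    centres = S.bin_centres()
    sel = (centres >= lo) & (centres < hi) & S.mask
    return float(S.values[sel].sum())


def select_isolated(rcds: list[RCD], S_track: BinnedTrack,
                    flank: float = 500e3, max_ratio: float = 0.25,
                    per_side: bool = False) -> list[IsolatedPeak]:
    """Keep RCDs whose flanking signal is ≤ ``max_ratio`` of the signal
    under the wavelet peak.

    ``flank`` is the width of each window abutting the extent; by default
    the two flanks are combined before comparing against
    ``max_ratio × under-peak signal`` (``per_side=True`` applies the test
    to each flank separately).  Peaks whose extent or flanks cross a
    chromosome end are excluded.
    """
    out: list[IsolatedPeak] = []
    for r in rcds:
        lo, hi = r.extent
        if lo - flank < 0 or hi + flank > S_track.length:
            continue
        under = _window_sum(S_track, lo, hi)
        if under <= 0:
            continue
        left = _window_sum(S_track, lo - flank, lo)
        right = _window_sum(S_track, hi, hi + flank)
        if per_side:
            ok = left <= max_ratio * under and right <= max_ratio * under
        else:
            ok = (left + right) <= max_ratio * under
        if ok:
            out.append(IsolatedPeak(rcd=r, under_peak_signal=under,
                                    flanking_signal=left + right))
    return out


def fit_optimal_wavelet(peak: RCD | IsolatedPeak,
                        S_tracks: list[BinnedTrack],
                        grid: np.ndarray | None = None,
                        peak_id: int = 0) -> WidthFitSeries:
    """Best-matching Ricker width per timepoint for one isolated peak.

    For each timepoint track the grid width maximizing the convolved
    response within ±W/2 of the peak position is recorded; the series is
    rejected when any timepoint's optimum falls on the first or last grid
    value (the fit ran off the grid).
    """
    if grid is None:
        grid = default_width_grid()
    grid = np.asarray(sorted(float(g) for g in grid))
    pos = peak.rcd.position if isinstance(peak, IsolatedPeak) else peak.position
    widths: list[float] = []
    for S in S_tracks:
        centres = S.bin_centres()
        best_w, best_resp = grid[0], -np.inf
        for w in grid:
            conv = convolve_track(S, ricker_kernel(w, S.bin_size))
            sel = (np.abs(centres - pos) <= w / 2.0) & S.mask
            if not sel.any():
                continue
            resp = float(conv.values[sel].max())
            if resp > best_resp:
                best_resp, best_w = resp, float(w)
        widths.append(best_w)
    rejected = any(w in (grid[0], grid[-1]) for w in widths)
    reason = "optimum at grid extreme" if rejected else ""
    return WidthFitSeries(peak_id=peak_id, widths_bp=widths,
                          rejected=rejected, reason=reason)


def fit_optimal_wavelet_batch(peaks, S_tracks, grid=None) -> list[WidthFitSeries]:
    """Grid fit for many peaks, convolving each track once per width."""
    if grid is None:
        grid = default_width_grid()
    grid = np.asarray(sorted(float(g) for g in grid))
    positions = np.array([
        (p.rcd.position if isinstance(p, IsolatedPeak) else p.position)
        for p in peaks])
    best = np.zeros((len(peaks), len(S_tracks)))
    for tp, S in enumerate(S_tracks):
        centres = S.bin_centres()
        best_resp = np.full(len(peaks), -np.inf)
        for w in grid:
            conv = convolve_track(S, ricker_kernel(w, S.bin_size)).values
            for k, pos in enumerate(positions):
                sel = (np.abs(centres - pos) <= w / 2.0) & S.mask
                if not sel.any():
                    continue
                resp = conv[sel].max()
                if resp > best_resp[k]:
                    best_resp[k] = resp
                    best[k, tp] = w
    out = []
    for k in range(len(peaks)):
        widths = list(best[k])
        rejected = any(w in (grid[0], grid[-1]) for w in widths)
        out.append(WidthFitSeries(peak_id=k, widths_bp=widths, rejected=rejected,
                                  reason="optimum at grid extreme" if rejected else ""))
    return out


def _nelder_mead(objective, x0, max_iter: int = 2000):
    res = optimize.minimize(objective, x0, method="Nelder-Mead",
                            options={"xatol": 1e-6 * max(1.0, np.max(np.abs(x0))),
                                     "fatol": 1e-10, "maxiter": max_iter,
                                     "maxfev": 2 * max_iter})
    return res


def fit_gaussian(peak: RCD | IsolatedPeak, S_track: BinnedTrack,
                 pad: float = 500e3, rng: np.random.Generator | None = None) -> GaussianFit:
    """Least-squares Gaussian + baseline fit over the padded peak extent.

    Model: ``A·exp(−(x−c)²/2σ²) + b`` fitted with Nelder-Mead from
    c = peak position, σ = W/4, A = max S in window, b = 0.  On
    non-convergence the fit restarts once from a perturbed initial point.
    """
    r = peak.rcd if isinstance(peak, IsolatedPeak) else peak
    lo, hi = r.extent[0] - pad, r.extent[1] + pad
    centres = S_track.bin_centres()
    sel = (centres >= lo) & (centres < hi) & S_track.mask
    x, y = centres[sel], S_track.values[sel]
    if x.size < 5:
        return GaussianFit(np.nan, np.nan, np.nan, np.nan, converged=False)

    def obj(p):
        a, c, s, b = p
        if s <= 0 or a <= 0:
            return 1e30
        return float(((a * np.exp(-((x - c) ** 2) / (2 * s ** 2)) + b - y) ** 2).sum())

    x0 = np.array([max(y.max(), 1e-9), r.position, r.width_W / 4.0, 0.0])
    res = _nelder_mead(obj, x0)
    if not res.success:
        rng = rng or np.random.default_rng(0)
        res2 = _nelder_mead(obj, x0 * (1 + 0.1 * rng.standard_normal(4)))
        if res2.fun < res.fun:
            res = res2
    a, c, s, b = res.x
    return GaussianFit(amplitude=float(a), centre=float(c), sigma=float(abs(s)),
                       baseline=float(b), converged=bool(res.success))


def fit_flat_topped_gaussian(peak: RCD | IsolatedPeak, S_track: BinnedTrack,
                             pad: float = 500e3,
                             fix_plateau_zero: bool = False) -> FlatToppedGaussianFit:
    """Gaussian with a flat central section: inside ±plateau the model is
    A + b; outside, Gaussian shoulders of width σ.  Diagnostic companion
    to :func:`fit_gaussian`; reduces to it when the plateau is constrained
    to zero."""
    r = peak.rcd if isinstance(peak, IsolatedPeak) else peak
    lo, hi = r.extent[0] - pad, r.extent[1] + pad
    centres = S_track.bin_centres()
    sel = (centres >= lo) & (centres < hi) & S_track.mask
    x, y = centres[sel], S_track.values[sel]
    if x.size < 5:
        return FlatToppedGaussianFit(np.nan, np.nan, np.nan, np.nan, False, np.nan)

    def model(p):
        a, c, s, b, plat = p
        d = np.maximum(np.abs(x - c) - abs(plat), 0.0)
        return a * np.exp(-(d ** 2) / (2 * s ** 2)) + b

    def obj(p):
        if p[2] <= 0 or p[0] <= 0:
            return 1e30
        if fix_plateau_zero and abs(p[4]) > 0:
            return 1e30
        return float(((model(p) - y) ** 2).sum())

    plat0 = 0.0 if fix_plateau_zero else r.width_W / 4.0
    x0 = np.array([max(y.max(), 1e-9), r.position, r.width_W / 4.0, 0.0, plat0])
    if fix_plateau_zero:
        g = fit_gaussian(peak, S_track, pad=pad)
        return FlatToppedGaussianFit(g.amplitude, g.centre, g.sigma, g.baseline,
                                     g.converged, plateau_halfwidth=0.0)
    res = _nelder_mead(obj, x0, max_iter=4000)
    a, c, s, b, plat = res.x
    return FlatToppedGaussianFit(amplitude=float(a), centre=float(c),
                                 sigma=float(abs(s)), baseline=float(b),
                                 converged=bool(res.success),
                                 plateau_halfwidth=float(abs(plat)))


@dataclass
class GrowthStats:
    deltas_bp: np.ndarray            # (n_peaks, n_intervals)
    mean_bp: np.ndarray              # per interval
    se_bp: np.ndarray
    ci95_bp: list[tuple[float, float]]
    p_values: np.ndarray             # per-interval one-sample t vs 0
    overall_mean_bp: float
    overall_se_bp: float
    overall_ci95_bp: tuple[float, float]
    overall_t: float
    overall_p: float
    growth_rate_kb_min: float
    interval_min: float = 30.0
    degenerate: bool = False


def _one_sample(vals: np.ndarray) -> tuple[float, float, tuple[float, float], float, float]:
    vals = np.asarray(vals, dtype=float)
    mean = float(vals.mean())
    if vals.size < 2 or np.allclose(vals, vals[0]):
        return mean, 0.0, (mean, mean), float("nan"), 1.0
    se = float(vals.std(ddof=1) / np.sqrt(vals.size))
    t, p = stats.ttest_1samp(vals, 0.0)
    half = stats.t.ppf(0.975, vals.size - 1) * se
    return mean, se, (mean - half, mean + half), float(t), float(p)


def growth_stats(series: list[WidthFitSeries] | np.ndarray,
                 interval_min: float = 30.0,
                 include_rejected: bool = False) -> GrowthStats:
    """Per-interval width increases across accepted peaks.

    Accepts either grid-fit series or an (n_peaks, n_timepoints) width
    array (e.g. Gaussian FWHMs).  The growth rate in kb/min is the pooled
    mean per-interval increase divided by the inter-pulse interval.  With
    all deltas equal the t statistic is undefined and p is reported as 1.
    """
    if isinstance(series, np.ndarray):
        widths = np.asarray(series, dtype=float)
    else:
        kept = [s for s in series if include_rejected or not s.rejected]
        widths = np.array([s.widths_bp for s in kept], dtype=float)
    if widths.shape[0] < 2:
        raise ValueError("need at least 2 accepted peaks for growth statistics")
    deltas = np.diff(widths, axis=1)
    means, ses, cis, ps = [], [], [], []
    for k in range(deltas.shape[1]):
        m, se, ci, _, p = _one_sample(deltas[:, k])
        means.append(m); ses.append(se); cis.append(ci); ps.append(p)
    om, ose, oci, ot, op = _one_sample(deltas.ravel())
    degenerate = np.isnan(ot)
    return GrowthStats(
        deltas_bp=deltas, mean_bp=np.asarray(means), se_bp=np.asarray(ses),
        ci95_bp=cis, p_values=np.asarray(ps),
        overall_mean_bp=om, overall_se_bp=ose, overall_ci95_bp=oci,
        overall_t=ot, overall_p=op,
        growth_rate_kb_min=om / 1e3 / interval_min,
        interval_min=interval_min, degenerate=bool(degenerate))
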