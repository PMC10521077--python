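"""Inter-peak valleys: definition, tracking across pulses, and filling.

A valley is the gap between two adjacent wavelet peaks (called without a
height cutoff) inside one early timing domain, trimmed inward by 180 kb on
each side — the distance a fork moving at 1.5 kb/min covers in the two
hours between the first and last pulse — so that passive fork movement out
of the flanking peaks cannot masquerade as valley replication.  Valley
signal is expressed per timepoint as a percentage of the mean replication
peak height of the two flanks, making timepoints with different library
depths comparable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .detection import WaveletPeak, _max_signal_in_extent
from .tracks_io import BinnedTrack, TimingDomainSet

__all__ = [
    "Valley",
    "ValleyTimecourse",
    "FORK_RATE_KB_MIN",
    "TRIM_BP",
    "define_valleys",
    "track_valleys",
    "valley_signal",
    "filling_stats",
]

FORK_RATE_KB_MIN = 1.5
TRACKING_SPAN_MIN = 120.0
# fork travel over the 120 min separating the first and last pulse starts
TRIM_BP = FORK_RATE_KB_MIN * TRACKING_SPAN_MIN * 1e3


@dataclass
class Valley:
    chrom: str
    left_peak: WaveletPeak
    right_peak: WaveletPeak
    interval: tuple[float, float]
    timing_domain_id: int | None = None


@dataclass
class ValleyTimecourse:
    valley: Valley
    mean_pct: list[float] = field(default_factory=list)
    min_pct: list[float] = field(default_factory=list)
    tracked: bool = True


def define_valleys(peaks_t1: list[WaveletPeak], domains: TimingDomainSet,
                   trim: float = TRIM_BP, label: str = "early") -> list[Valley]:
    """One valley per adjacent peak pair within a single early domain.

    ``peaks_t1`` should be called without any height cutoff.  The valley
    interval is ``(left extent end + trim, right extent start − trim)``;
    pairs whose trimmed gap is empty produce no valley.
    """
    by_chrom: dict[str, list[WaveletPeak]] = {}
    for p in peaks_t1:
        by_chrom.setdefault(p.chrom, []).append(p)
    valleys: list[Valley] = []
    for chrom, plist in sorted(by_chrom.items()):
        plist.sort(key=lambda p: p.position)
        for a, b in zip(plist, plist[1:]):
            dom_a = domains.domain_of(chrom, a.position, label=label)
            dom_b = domains.domain_of(chrom, b.position, label=label)
            if dom_a is None or dom_a != dom_b:
                continue
            lo = a.extent[1] + trim
            hi = b.extent[0] - trim
            if hi <= lo:
                continue
            valleys.append(Valley(chrom=chrom, left_peak=a, right_peak=b,
                                  interval=(lo, hi), timing_domain_id=dom_a))
    return valleys


def _nearest_peak(peaks: list[WaveletPeak], pos: float) -> WaveletPeak | None:
    if not peaks:
        return None
    best, best_d = None, np.inf
    for p in peaks:
        d = abs(p.position - pos)
        if d < best_d - 1e-9 or (abs(d - best_d) <= 1e-9 and best is not None
                                 and p.wavelet_height > best.wavelet_height):
            best, best_d = p, d
    return best


def track_valleys(valleys: list[Valley],
                  later_peaks: list[list[WaveletPeak]],
                  tolerance: float = 100e3) -> list[Valley]:
    """Keep valleys whose flanking peaks persist at every later timepoint.

    A flank persists when the nearest peak (same chromosome) at each later
    timepoint lies within ±``tolerance`` of its first-timepoint position;
    ties in distance are broken toward the higher wavelet peak.
    """
    tracked: list[Valley] = []
    for v in valleys:
        ok = True
        for peaks in later_peaks:
            chrom_peaks = [p for p in peaks if p.chrom == v.chrom]
            for flank in (v.left_peak, v.right_peak):
                near = _nearest_peak(chrom_peaks, flank.position)
                if near is None or abs(near.position - flank.position) > tolerance:
                    ok = False
                    break
            if not ok:
                break
        if ok:
            tracked.append(v)
    return tracked


def valley_signal(valley: Valley, S_track: BinnedTrack,
                  flanking_heights: tuple[float, float] | None = None
                  ) -> tuple[float, float] | None:
    """(mean_pct, min_pct) of valley signal relative to the flanks.

    Flanking heights default to the replication peak heights (max S over
    each flank extent) in the same track.  Returns ``None`` when the mean
    flanking height is not positive (the valley is excluded).
    """
    if flanking_heights is None:
        flanking_heights = (_max_signal_in_extent(S_track, valley.left_peak.extent),
                            _max_signal_in_extent(S_track, valley.right_peak.extent))
    ref = float(np.mean(flanking_heights))
    if not ref > 0:
        return None
    centres = S_track.bin_centres()
    lo, hi = valley.interval
    sel = (centres >= lo) & (centres < hi) & S_track.mask
    if not sel.any():
        return None
    vals = S_track.values[sel]
    return (float(vals.mean() / ref * 100.0), float(vals.min() / ref * 100.0))


def build_timecourses(valleys: list[Valley], S_tracks: list[BinnedTrack]
                      ) -> list[ValleyTimecourse]:
    """Per-timepoint valley percentages for already-tracked valleys."""
    out: list[ValleyTimecourse] = []
    for v in valleys:
        tc = ValleyTimecourse(valley=v)
        ok = True
        for S in S_tracks:
            res = valley_signal(v, S)
            if res is None:
                ok = False
                break
            tc.mean_pct.append(res[0])
            tc.min_pct.append(res[1])
        if ok:
            out.append(tc)
    return out


def filling_stats(timecourses: list[ValleyTimecourse],
                  pulse_mid_times_min: tuple[float, ...] = (25.0, 55.0, 85.0, 115.0),
                  rate_mode: str = "slope",
                  min_pct_threshold: float = 10.0) -> dict:
    """Valley-filling summary: rates in %/min and a one-sample t-test.

    Per-valley rates are the least-squares slope of mean_pct against the
    pulse midpoint times (``rate_mode="slope"``), or the mean successive
    difference divided by the interval (``rate_mode="diff"``).  Also
    reports the count of valleys whose final min_pct exceeds
    ``min_pct_threshold`` % of the flanking peak height.
    """
    if len(timecourses) < 2:
        raise ValueError("need at least 2 tracked valleys")
    t = np.asarray(pulse_mid_times_min, dtype=float)
    mean_mat = np.array([tc.mean_pct for tc in timecourses], dtype=float)
    min_mat = np.array([tc.min_pct for tc in timecourses], dtype=float)
    if rate_mode == "slope":
        tc_ = t - t.mean()
        rates = (mean_mat - mean_mat.mean(axis=1, keepdims=True)) @ tc_ / (tc_ @ tc_)
    elif rate_mode == "diff":
        rates = np.diff(mean_mat, axis=1).mean(axis=1) / np.diff(t).mean()
    else:
        raise ValueError(f"unknown rate_mode {rate_mode!r}")

    mean = float(rates.mean())
    if rates.size > 1 and not np.allclose(rates, rates[0]):
        se = float(rates.std(ddof=1) / np.sqrt(rates.size))
        tstat, p = stats.ttest_1samp(rates, 0.0)
        half = stats.t.ppf(0.975, rates.size - 1) * se
        ci = (mean - half, mean + half)
        degenerate = False
    else:
        se, tstat, p, ci, degenerate = 0.0, float("nan"), 1.0, (mean, mean), True
    final_min = min_mat[:, -1]
    return {
        "rates_pct_per_min": rates,
        "mean_rate": mean, "se_rate": se, "ci95_rate": ci,
        "t": float(tstat), "p": float(p), "degenerate": degenerate,
        "mean_pct_by_timepoint": mean_mat.mean(axis=0),
        "min_pct_by_timepoint": min_mat.mean(axis=0),
        "n_valleys": len(timecourses),
        "n_final_min_above_threshold": int((final_min > min_pct_threshold).sum()),
        "min_pct_threshold": min_pct_threshold,
    }
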