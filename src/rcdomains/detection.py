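"""Wavelet peak calling, late-domain cutoff calibration, and RCD tables.

A Replicon Cluster Domain (RCD) is a positive local maximum of the
wavelet-convolved early replication signal whose height exceeds a cutoff
calibrated on peaks in *late* timing domains — late domains carry
essentially no first-pulse signal, so their wavelet peaks estimate the
noise floor.  The cutoff is the nearest-rank percentile (default 70th) of
late peak heights.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tracks_io import BinnedTrack, RegionSet, TimingDomainSet

__all__ = [
    "WaveletPeak",
    "RCD",
    "CutoffCalibration",
    "call_peaks",
    "calibrate_cutoff",
    "filter_rcds",
    "rcd_stats",
    "rcds_to_table",
]


@dataclass
class WaveletPeak:
    chrom: str
    position: float           # bp (bin centre of the local maximum)
    width_W: float            # bp, wavelet peak width used
    wavelet_height: float

    @property
    def extent(self) -> tuple[float, float]:
        return (self.position - self.width_W / 2.0, self.position + self.width_W / 2.0)


@dataclass
class RCD(WaveletPeak):
    timing_domain_id: int | None = None
    replication_peak_height: float = float("nan")
    timepoint_id: int | None = None


@dataclass
class CutoffCalibration:
    percentile: float
    threshold_value: float
    n_late_peaks: int


def call_peaks(convolved: BinnedTrack, region: RegionSet | None = None,
               width_W: float | None = None) -> list[WaveletPeak]:
    """Call positive strict local maxima of a convolved track.

    A peak bin has a positive value strictly greater than both nearest
    differing unmasked neighbours; a plateau of equal values yields one
    peak at its centre bin (leftmost of the two central bins when the
    plateau length is even).  Peaks whose bin centre lies outside
    ``region`` are dropped.  Array ends cannot be peaks.
    """
    v = convolved.values
    mask = convolved.mask
    n = v.size
    centres = convolved.bin_centres()
    peaks: list[WaveletPeak] = []
    W = float(width_W) if width_W is not None else float("nan")

    # contiguous unmasked runs are scanned independently: a peak cannot
    # span a masked gap, and run ends cannot be peaks
    runs = []
    start = None
    for b in range(n + 1):
        if b < n and mask[b]:
            if start is None:
                start = b
        elif start is not None:
            runs.append((start, b))
            start = None
    for r0, r1 in runs:
        vv = v[r0:r1]
        m = vv.size
        i = 1
        while i < m - 1:
            if vv[i] <= 0 or vv[i] <= vv[i - 1]:
                i += 1
                continue
            j = i
            while j < m - 1 and vv[j + 1] == vv[i]:
                j += 1
            if j >= m - 1 or vv[j + 1] >= vv[i]:
                i = j + 1
                continue
            b = r0 + (i + j) // 2       # leftmost of two central plateau bins
            pos = float(centres[b])
            if region is None or region.contains(pos):
                peaks.append(WaveletPeak(chrom=convolved.chrom, position=pos,
                                         width_W=W, wavelet_height=float(vv[i])))
            i = j + 1
    return peaks


def calibrate_cutoff(late_peaks: list[WaveletPeak], percentile: float = 70.0,
                     min_peaks: int = 10) -> CutoffCalibration:
    """Nearest-rank percentile of late-domain wavelet peak heights.

    The threshold is the ceil(p/100·n)-th smallest height; keeping only
    peaks strictly above it removes ⌊p/100·n⌋ of the late peaks themselves
    when p/100·n is integral.
    """
    n = len(late_peaks)
    if n < min_peaks:
        raise ValueError(
            f"only {n} late-domain peaks (need >= {min_peaks}); consider a "
            "fallback percentile computed over all peaks")
    if not 0 <= percentile <= 100:
        raise ValueError("percentile must lie in [0, 100]")
    heights = np.sort([p.wavelet_height for p in late_peaks])
    if percentile == 0:
        thr = float(heights[0])
    else:
        rank = math.ceil(percentile / 100.0 * n)    # 1-based nearest rank
        thr = float(heights[rank - 1])
    return CutoffCalibration(percentile=float(percentile), threshold_value=thr,
                             n_late_peaks=n)


def _max_signal_in_extent(S: BinnedTrack, extent: tuple[float, float]) -> float:
    centres = S.bin_centres()
    sel = (centres >= extent[0]) & (centres < extent[1]) & S.mask
    if not sel.any():
        return float("nan")
    return float(S.values[sel].max())


def filter_rcds(early_peaks: list[WaveletPeak], cutoff: CutoffCalibration | None,
                S_track: BinnedTrack, domains: TimingDomainSet | None = None,
                timepoint_id: int | None = None) -> list[RCD]:
    """Keep early peaks above the cutoff and annotate them as RCDs.

    ``replication_peak_height`` is the maximum of the background-subtracted
    signal S over unmasked bins of the peak extent (position ± W/2);
    domain membership is decided by the peak position.
    """
    thr = cutoff.threshold_value if cutoff is not None else -np.inf
    rcds: list[RCD] = []
    for p in early_peaks:
        if not p.wavelet_height > thr:
            continue
        dom = domains.domain_of(p.chrom, p.position) if domains is not None else None
        rcds.append(RCD(chrom=p.chrom, position=p.position, width_W=p.width_W,
                        wavelet_height=p.wavelet_height,
                        timing_domain_id=dom,
                        replication_peak_height=_max_signal_in_extent(S_track, p.extent),
                        timepoint_id=timepoint_id))
    return rcds


def rcd_stats(rcds: list[RCD]) -> dict:
    """Within-domain adjacent separations and per-domain counts.

    Separations are centre-to-centre distances between neighbouring RCDs
    sharing a timing domain; single-RCD domains contribute none.
    """
    by_domain: dict[tuple[str, int | None], list[RCD]] = {}
    for r in rcds:
        by_domain.setdefault((r.chrom, r.timing_domain_id), []).append(r)
    seps: list[float] = []
    counts: list[tuple[str, int | None, int]] = []
    for (chrom, dom), members in sorted(by_domain.items(), key=lambda kv: str(kv[0])):
        members.sort(key=lambda r: r.position)
        counts.append((chrom, dom, len(members)))
        for a, b in zip(members, members[1:]):
            seps.append(b.position - a.position)
    seps_arr = np.asarray(seps)
    return {
        "separations_bp": seps_arr,
        "mean_separation_bp": float(seps_arr.mean()) if seps_arr.size else float("nan"),
        "sd_separation_bp": float(seps_arr.std(ddof=1)) if seps_arr.size > 1 else float("nan"),
        "per_domain_counts": counts,
        "n_rcds": len(rcds),
    }


def rcds_to_table(rcds: list[RCD]) -> pd.DataFrame:
    """RCDs as a BED6+ style table (extent, id, height, extras)."""
    rows = []
    for k, r in enumerate(rcds):
        s, e = r.extent
        rows.append({
            "chrom": r.chrom, "start": int(max(0, s)), "end": int(e),
            "name": f"rcd_{k}", "score": r.wavelet_height, "strand": ".",
            "position": r.position,
            "replication_peak_height": r.replication_peak_height,
            "domain_id": r.timing_domain_id, "timepoint": r.timepoint_id,
        })
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score",
                                       "strand", "position",
                                       "replication_peak_height", "domain_id",
                                       "timepoint"])
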