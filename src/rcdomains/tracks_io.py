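"""Binned genomic tracks, timing-domain annotations, and their file formats.

All coordinates are **0-based, half-open** (native bedGraph convention).
A :class:`BinnedTrack` holds one value per fixed-width bin on a single
chromosome.  Masked bins are carried as an explicit boolean mask (never as
zeros), so sums, percentiles and peak calls can exclude them.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BinnedTrack",
    "RegionSet",
    "TimingDomainSet",
    "TrackFormatError",
    "read_bedgraph",
    "write_bedgraph",
    "bin_intervals",
    "load_timing_domains",
    "clip_track",
]


class TrackFormatError(ValueError):
    """Raised when an input file violates the declared bin grid or format."""


@dataclass
class BinnedTrack:
    """Fixed-width binned values on one chromosome.

    Parameters
    ----------
    chrom:
        Chromosome name.
    bin_size:
        Bin width in bp.
    values:
        One value per bin, starting at coordinate 0.
    role:
        One of ``raw_count``, ``rpm``, ``signal`` (documentation only).
    mask:
        Boolean array, ``True`` where the bin is valid.  Defaults to all
        valid.
    """

    chrom: str
    bin_size: int
    values: np.ndarray
    role: str = "raw_count"
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        self.values = np.asarray(self.values, dtype=float)
        if self.mask is None:
            self.mask = np.ones(self.values.shape, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.values.shape:
                raise ValueError("mask and values must have the same length")

    @property
    def n_bins(self) -> int:
        return int(self.values.size)

    @property
    def length(self) -> int:
        """Covered chromosome extent in bp (last bin may be partial)."""
        return self.n_bins * self.bin_size

    def bin_centres(self) -> np.ndarray:
        """Midpoint coordinate (bp) of every bin."""
        return (np.arange(self.n_bins) + 0.5) * self.bin_size

    def valid_values(self) -> np.ndarray:
        return self.values[self.mask]

    def total(self) -> float:
        """Sum of values over unmasked bins."""
        return float(self.values[self.mask].sum())

    def with_values(self, values: np.ndarray, role: str | None = None) -> "BinnedTrack":
        return BinnedTrack(
            chrom=self.chrom,
            bin_size=self.bin_size,
            values=np.asarray(values, dtype=float),
            role=role if role is not None else self.role,
            mask=self.mask.copy(),
        )

    def copy(self) -> "BinnedTrack":
        return self.with_values(self.values.copy())


@dataclass
class RegionSet:
    """Sorted, merged, half-open intervals on one chromosome."""

    chrom: str
    intervals: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.intervals = _merge_intervals(self.intervals)

    def __len__(self) -> int:
        return len(self.intervals)

    def total_span(self) -> int:
        return sum(e - s for s, e in self.intervals)

    def contains(self, pos: float) -> bool:
        return any(s <= pos < e for s, e in self.intervals)

    def membership(self, positions: np.ndarray) -> np.ndarray:
        """Boolean membership for an array of positions (bp)."""
        positions = np.asarray(positions, dtype=float)
        out = np.zeros(positions.shape, dtype=bool)
        for s, e in self.intervals:
            out |= (positions >= s) & (positions < e)
        return out

    @classmethod
    def from_bed(cls, path, chrom: str) -> "RegionSet":
        df = pd.read_csv(path, sep=r"\s+", header=None, comment="#",
                         usecols=[0, 1, 2], names=["chrom", "start", "end"])
        sub = df[df["chrom"] == chrom]
        return cls(chrom, list(zip(sub["start"].astype(int), sub["end"].astype(int))))

    def to_bed(self, path) -> None:
        with open(path, "w") as fh:
            for s, e in self.intervals:
                fh.write(f"{self.chrom}\t{s}\t{e}\n")


def _merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    ivs = sorted((int(s), int(e)) for s, e in intervals)
    for s, e in ivs:
        if s >= e:
            raise ValueError(f"empty or inverted interval ({s}, {e})")
    merged: list[tuple[int, int]] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


@dataclass
class TimingDomainSet:
    """Early/late replication-timing intervals derived from an RT track.

    ``intervals`` holds ``(chrom, start, end, label)`` rows with label in
    ``{"early", "late"}``; within one label intervals are half-open,
    sorted, and non-overlapping.
    """

    intervals: list[tuple[str, int, int, str]]
    source: str = ""

    def regions(self, label: str, chrom: str) -> RegionSet:
        return RegionSet(chrom, [(s, e) for c, s, e, lab in self.intervals
                                 if c == chrom and lab == label])

    def chroms(self) -> list[str]:
        seen: dict[str, None] = {}
        for c, *_ in self.intervals:
            seen.setdefault(c)
        return list(seen)

    def domain_of(self, chrom: str, pos: float, label: str = "early") -> int | None:
        """Index (within ``intervals``) of the labelled domain containing
        ``pos``, or ``None``."""
        for idx, (c, s, e, lab) in enumerate(self.intervals):
            if c == chrom and lab == label and s <= pos < e:
                return idx
        return None


# ---------------------------------------------------------------------------
# bedGraph I/O

def read_bedgraph(path, bin_size: int,
                  chrom_lengths: Mapping[str, int] | None = None,
                  role: str = "raw_count") -> dict[str, BinnedTrack]:
    """Read a 4-column bedGraph whose intervals lie on the declared bin grid.

    Bins absent from the file are zero-filled (absence means zero coverage).
    Misaligned or overlapping intervals raise :class:`TrackFormatError`
    naming the offending line.
    """
    per_chrom: dict[str, dict[int, float]] = {}
    max_bin: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 4:
                raise TrackFormatError(f"{path}:{lineno}: expected 4 columns")
            chrom, start, end, value = parts[0], int(parts[1]), int(parts[2]), float(parts[3])
            if start % bin_size != 0 or (end % bin_size != 0 and not
                                         (chrom_lengths and end == chrom_lengths.get(chrom))):
                raise TrackFormatError(
                    f"{path}:{lineno}: interval [{start},{end}) not aligned to "
                    f"{bin_size}-bp bins")
            bins = per_chrom.setdefault(chrom, {})
            for b in range(start // bin_size, -(-end // bin_size)):
                if b in bins:
                    raise TrackFormatError(
                        f"{path}:{lineno}: overlapping interval at bin {b} on {chrom}")
                bins[b] = value
                max_bin[chrom] = max(max_bin.get(chrom, -1), b)
    tracks: dict[str, BinnedTrack] = {}
    for chrom, bins in per_chrom.items():
        if chrom_lengths and chrom in chrom_lengths:
            n = -(-chrom_lengths[chrom] // bin_size)
        else:
            n = max_bin[chrom] + 1
        values = np.zeros(n, dtype=float)
        for b, v in bins.items():
            if b < n:
                values[b] = v
        tracks[chrom] = BinnedTrack(chrom, bin_size, values, role=role)
    return tracks


def write_bedgraph(tracks: Mapping[str, BinnedTrack] | BinnedTrack, path,
                   suppress_zero: bool = False) -> None:
    """Write tracks as 4-column bedGraph.  Masked bins are omitted; negative
    values are written verbatim."""
    if isinstance(tracks, BinnedTrack):
        tracks = {tracks.chrom: tracks}
    sizes = {t.bin_size for t in tracks.values()}
    if len(sizes) > 1:
        raise ValueError("tracks must share bin_size")
    with open(path, "w") as fh:
        for chrom in tracks:
            t = tracks[chrom]
            for i, v in enumerate(t.values):
                if not t.mask[i]:
                    continue
                if suppress_zero and v == 0:
                    continue
                s = i * t.bin_size
                fh.write(f"{chrom}\t{s}\t{s + t.bin_size}\t{_fmt(v)}\n")


def _fmt(v: float) -> str:
    if float(v).is_integer():
        return str(int(v))
    return repr(float(v))


# ---------------------------------------------------------------------------
# Binning and annotations

def bin_intervals(read_intervals: Sequence[tuple[str, int, int]], bin_size: int,
                  chrom_lengths: Mapping[str, int]) -> tuple[dict[str, BinnedTrack], int]:
    """Count read intervals into bins by fragment midpoint.

    Each read increments the bin containing its midpoint by one.  Reads
    whose midpoint falls outside the declared chromosome are rejected;
    the count of rejected reads is returned alongside the tracks.
    """
    n_bins = {c: -(-length // bin_size) for c, length in chrom_lengths.items()}
    counts = {c: np.zeros(n, dtype=float) for c, n in n_bins.items()}
    rejected = 0
    for chrom, start, end in read_intervals:
        mid = (start + end) / 2
        if chrom not in counts or mid < 0 or mid >= chrom_lengths[chrom]:
            rejected += 1
            continue
        counts[chrom][int(mid // bin_size)] += 1
    return ({c: BinnedTrack(c, bin_size, v, role="raw_count") for c, v in counts.items()},
            rejected)


def load_timing_domains(path, columns: tuple[int, int, int, int] = (0, 1, 2, 3),
                        source: str | None = None) -> TimingDomainSet:
    """Load a tab-delimited replication-timing table into early/late domains.

    Contiguous runs of bins with RT > 0 are merged into ``early`` intervals
    and runs with RT < 0 into ``late`` intervals; bins with RT == 0 are
    assigned to neither label.  ``columns`` maps (chrom, start, end, RT)
    onto file columns, since deposited RT tables vary in layout.
    """
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#")
        df = df.iloc[:, list(columns)]
    except (ValueError, IndexError) as exc:
        raise TrackFormatError(f"{path}: cannot read RT table: {exc}") from exc
    df.columns = ["chrom", "start", "end", "rt"]
    try:
        rt = df["rt"].astype(float)
    except ValueError as exc:
        raise TrackFormatError(f"{path}: non-numeric RT value: {exc}") from exc
    df = df.assign(rt=rt, start=df["start"].astype(int), end=df["end"].astype(int))

    intervals: list[tuple[str, int, int, str]] = []
    for chrom, sub in df.groupby("chrom", sort=False):
        sub = sub.sort_values("start")
        current: tuple[int, int, str] | None = None
        for _, row in sub.iterrows():
            label = "early" if row.rt > 0 else ("late" if row.rt < 0 else None)
            if label is None:
                if current:
                    intervals.append((chrom, *current[:2], current[2]))
                    current = None
                continue
            if current and current[2] == label and row.start <= current[1]:
                current = (current[0], max(current[1], row.end), label)
            else:
                if current:
                    intervals.append((chrom, *current[:2], current[2]))
                current = (row.start, row.end, label)
        if current:
            intervals.append((chrom, *current[:2], current[2]))
    return TimingDomainSet(intervals=intervals, source=source or str(path))


def clip_track(track: BinnedTrack, regions: RegionSet) -> BinnedTrack:
    """Mask every bin whose midpoint lies outside ``regions``.

    Masked bins are excluded from all downstream sums, peak calls and
    percentiles; complementary clips therefore partition the total signal
    exactly.
    """
    if regions.chrom != track.chrom:
        raise ValueError(f"region chromosome {regions.chrom!r} != track {track.chrom!r}")
    inside = regions.membership(track.bin_centres())
    out = track.copy()
    out.mask = track.mask & inside
    return out
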