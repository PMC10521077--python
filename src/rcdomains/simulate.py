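"""Kinetic EdU-seq simulator: clustered origins, forks, pulses, reads.

The generator embodies the replicon-cluster model of early S phase: cells
enter S phase over a configurable window, each replicon cluster activates
(with some efficiency) at a stochastic time, a random subset of candidate
origins inside the cluster fires near-synchronously, and bidirectional
forks extend at a constant rate, merging on meeting.  An EdU pulse labels
exactly the DNA synthesised during its window — the replicated set at the
pulse end minus the set at the pulse start, per cell.  Pull-down reads are
Poisson-sampled from the population-mean labelled DNA per bin plus a
uniform genomic background; the input control is Poisson-sampled from a
uniform profile.

Defaults follow the biology the analysis targets: fork rate 1.5 kb/min,
clusters of 3–6 origins spanning ~400–800 kb, S-phase entry over 45 min,
and four 30-min pulses at 10–40, 40–70, 70–100 and 100–130 min.

Population-profile geometry used by the presets: when cluster activation
times have a uniform density covering the pulse span, the per-pulse
population profile of an isolated cluster is a plateau over the origin
span with linear shoulders, and its full width at half maximum is
``origin_span + 2·v·(t2 − Δt/2)`` for a pulse ending at t2 of length Δt —
so the half-max width grows by exactly ``2·v·Δt`` per successive pulse.
Presets that plant a nominal *profile* width therefore use an origin span
of ``nominal − 2·v·(t2₁ − Δt/2)`` (75 kb at the defaults).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .tracks_io import BinnedTrack, TimingDomainSet

__all__ = [
    "ClusterSpec",
    "SimulationConfig",
    "CellRealisation",
    "GroundTruth",
    "SimulationResult",
    "simulate_cell",
    "replicated_intervals",
    "label_pulse",
    "aggregate_and_sample",
    "make_benchmark_suite",
    "DEFAULT_PULSES",
]

DEFAULT_PULSES = ((10.0, 40.0), (40.0, 70.0), (70.0, 100.0), (100.0, 130.0))


@dataclass
class ClusterSpec:
    """One replicon cluster: location, origins, and activation law.

    ``activation`` is ``("normal", mean_min, sd_min)`` or
    ``("uniform", lo_min, hi_min)``, measured from the cell's S-entry time.
    """

    chrom: str
    centre: float                 # bp
    width: float                  # bp spanned by candidate origins
    n_origins: int = 4
    activation: tuple = ("normal", 15.0, 8.0)
    efficiency: float = 1.0
    group_id: int | None = None


@dataclass
class SimulationConfig:
    chrom_lengths: dict[str, int]
    clusters: list[ClusterSpec]
    domains: list[tuple[str, int, int, str]] = field(default_factory=list)
    bin_size: int = 50_000
    fork_rate_kb_min: float = 1.5
    firing_jitter_sd_min: float = 2.0
    entry_window_min: float = 45.0          # uniform [0, window]; 0 = synchronous
    pulses: tuple = DEFAULT_PULSES
    n_cells: int = 100
    reads_per_kb: float = 10.0              # pull-down reads per mean labelled kb
    background_rate: float = 2.0            # background pull-down reads per bin
    control_reads_per_bin: float = 50.0
    domino_coupling: tuple | None = None    # ("on", delay_mean_min, delay_sd_min)
    candidate_factor: int = 2               # candidate origins per fired origin
    rng_seed: int = 0

    def timing_domains(self) -> TimingDomainSet:
        return TimingDomainSet(intervals=[(c, int(s), int(e), lab)
                                          for c, s, e, lab in self.domains],
                               source="simulation")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["pulses"] = [list(p) for p in self.pulses]
        return d

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, default=str)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        d["clusters"] = [ClusterSpec(**{**c, "activation": tuple(c["activation"])})
                         if isinstance(c, dict) else c for c in d["clusters"]]
        d["pulses"] = tuple(tuple(p) for p in d["pulses"])
        d["domains"] = [tuple(x) for x in d.get("domains", [])]
        if d.get("domino_coupling") is not None:
            d["domino_coupling"] = tuple(d["domino_coupling"])
        return cls(**d)


@dataclass
class CellRealisation:
    """Fired origins of one cell: per chromosome, (position, firing time)."""

    entry_time: float
    origins: dict[str, np.ndarray]          # (n, 2) arrays [pos_bp, t_fire_min]
    activation_times: np.ndarray            # per cluster; nan = not fired


def _draw_activation(spec: ClusterSpec, rng: np.random.Generator) -> float:
    kind, a, b = spec.activation
    if kind == "normal":
        return max(0.0, float(rng.normal(a, b)))
    if kind == "uniform":
        return float(rng.uniform(a, b))
    raise ValueError(f"unknown activation law {kind!r}")


def simulate_cell(config: SimulationConfig, rng: np.random.Generator) -> CellRealisation:
    """Realise one cell: S entry, cluster activations, fired origins.

    With domino coupling on, clusters sharing a ``group_id`` activate
    sequentially along the chromosome: the first member draws from its own
    activation law and each subsequent member activates a positive random
    delay after its predecessor.
    """
    t0 = float(rng.uniform(0.0, config.entry_window_min)) if config.entry_window_min > 0 else 0.0
    n_clusters = len(config.clusters)
    act = np.full(n_clusters, np.nan)

    coupled_groups: dict[tuple[str, int], list[int]] = {}
    if config.domino_coupling is not None and config.domino_coupling[0] == "on":
        for k, spec in enumerate(config.clusters):
            if spec.group_id is not None:
                coupled_groups.setdefault((spec.chrom, spec.group_id), []).append(k)
    in_coupled = {k for ks in coupled_groups.values() if len(ks) > 1 for k in ks}

    for k, spec in enumerate(config.clusters):
        if k in in_coupled:
            continue
        if spec.efficiency < 1.0 and rng.random() >= spec.efficiency:
            continue
        act[k] = t0 + _draw_activation(spec, rng)

    if coupled_groups:
        _, dmean, dsd = config.domino_coupling
        for ks in coupled_groups.values():
            if len(ks) < 2:
                continue
            ks = sorted(ks, key=lambda k: config.clusters[k].centre)
            prev = None
            for k in ks:
                spec = config.clusters[k]
                if spec.efficiency < 1.0 and rng.random() >= spec.efficiency:
                    prev = None
                    continue
                if prev is None:
                    act[k] = t0 + _draw_activation(spec, rng)
                else:
                    act[k] = act[prev] + max(0.0, float(rng.normal(dmean, dsd)))
                prev = k

    origins: dict[str, list[tuple[float, float]]] = {}
    for k, spec in enumerate(config.clusters):
        if np.isnan(act[k]):
            continue
        n_cand = max(spec.n_origins, config.candidate_factor * spec.n_origins)
        spacing = spec.width / max(1, n_cand - 1)
        cand = (np.linspace(spec.centre - spec.width / 2.0,
                            spec.centre + spec.width / 2.0, n_cand)
                + rng.normal(0.0, spacing / 4.0, n_cand))
        fired = rng.choice(n_cand, size=min(spec.n_origins, n_cand), replace=False)
        for p in cand[fired]:
            t_fire = act[k] + max(0.0, float(rng.normal(0.0, config.firing_jitter_sd_min)))
            origins.setdefault(spec.chrom, []).append((float(p), t_fire))
    return CellRealisation(
        entry_time=t0,
        origins={c: np.array(sorted(v)) for c, v in origins.items()},
        activation_times=act)


def _merge(intervals: np.ndarray) -> np.ndarray:
    """Merge an (n, 2) array of intervals (may be unsorted/overlapping)."""
    if intervals.size == 0:
        return intervals.reshape(0, 2)
    iv = intervals[np.argsort(intervals[:, 0])]
    out = [iv[0].copy()]
    for s, e in iv[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append(np.array([s, e]))
    return np.array(out)


def replicated_intervals(origins: np.ndarray, t: float, fork_rate_kb_min: float,
                         chrom_length: float | None = None) -> np.ndarray:
    """Replicated set at time t: union of bidirectional fork extents.

    ``origins`` is an (n, 2) array of [position, firing time]; forks move
    at ``fork_rate_kb_min`` and merge on meeting (interval union).
    """
    if origins.size == 0:
        return np.zeros((0, 2))
    pos, tf = origins[:, 0], origins[:, 1]
    active = tf < t
    if not active.any():
        return np.zeros((0, 2))
    travel = fork_rate_kb_min * 1e3 * (t - tf[active])
    lo = pos[active] - travel
    hi = pos[active] + travel
    if chrom_length is not None:
        lo = np.clip(lo, 0.0, chrom_length)
        hi = np.clip(hi, 0.0, chrom_length)
    return _merge(np.column_stack([lo, hi]))


def _difference(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Set difference A \\ B of merged, sorted interval arrays."""
    if A.size == 0:
        return A.reshape(0, 2)
    if B.size == 0:
        return A
    out = []
    starts = B[:, 0]
    for a0, a1 in A:
        cur = a0
        j = int(np.searchsorted(B[:, 1], cur, side="right"))
        while j < len(B) and starts[j] < a1:
            if starts[j] > cur:
                out.append((cur, starts[j]))
            cur = max(cur, B[j, 1])
            j += 1
        if cur < a1:
            out.append((cur, a1))
    return np.array(out) if out else np.zeros((0, 2))


def label_pulse(origins: np.ndarray, pulse: tuple[float, float],
                fork_rate_kb_min: float,
                chrom_length: float | None = None) -> np.ndarray:
    """Intervals synthesised during the pulse window (t1, t2) in one cell:
    ``replicated(t2) \\ replicated(t1)``."""
    t1, t2 = pulse
    if not t1 < t2:
        raise ValueError("pulse start must precede pulse end")
    rep2 = replicated_intervals(origins, t2, fork_rate_kb_min, chrom_length)
    rep1 = replicated_intervals(origins, t1, fork_rate_kb_min, chrom_length)
    return _difference(rep2, rep1)


def _add_coverage(acc: np.ndarray, intervals: np.ndarray, bin_size: int) -> None:
    """Add bp of overlap of each interval to each bin (vectorised)."""
    if intervals.size == 0:
        return
    L = float(bin_size)
    n = acc.size
    s = np.clip(intervals[:, 0], 0.0, n * L)
    e = np.clip(intervals[:, 1], 0.0, n * L)
    keep = e > s
    s, e = s[keep], e[keep]
    if s.size == 0:
        return
    i0 = np.minimum((s // L).astype(int), n - 1)
    i1 = np.minimum(((e - 1e-9) // L).astype(int), n - 1)
    same = i0 == i1
    np.add.at(acc, i0[same], e[same] - s[same])
    ms = ~same
    if ms.any():
        np.add.at(acc, i0[ms], (i0[ms] + 1) * L - s[ms])
        np.add.at(acc, i1[ms], e[ms] - i1[ms] * L)
        d = np.zeros(n + 1)
        np.add.at(d, i0[ms] + 1, L)
        np.add.at(d, i1[ms], -L)
        acc += np.cumsum(d)[:-1]


@dataclass
class GroundTruth:
    cluster_table: pd.DataFrame
    entry_times: np.ndarray                       # (n_cells,)
    activation_times: np.ndarray                  # (n_cells, n_clusters)
    expected_labelled_bp: list[dict[str, np.ndarray]]  # per pulse, per chrom
    seed: int = 0


@dataclass
class SimulationResult:
    config: SimulationConfig
    pulldown: list[dict[str, BinnedTrack]]        # per pulse
    control: list[dict[str, BinnedTrack]]
    ground_truth: GroundTruth


def aggregate_and_sample(config: SimulationConfig,
                         rng: np.random.Generator | None = None) -> SimulationResult:
    """Simulate all cells, label every pulse, and sample read counts.

    Expected pull-down reads per bin = ``reads_per_kb`` × (mean labelled
    kb per cell in the bin) + ``background_rate``; counts are Poisson.
    The control is Poisson with a uniform per-bin mean.
    """
    if config.n_cells <= 0:
        raise ValueError("n_cells must be positive")
    rng = rng if rng is not None else np.random.default_rng(config.rng_seed)
    n_bins = {c: -(-length // config.bin_size)
              for c, length in config.chrom_lengths.items()}
    n_pulses = len(config.pulses)
    labelled = [{c: np.zeros(n) for c, n in n_bins.items()} for _ in range(n_pulses)]

    entry_times = np.zeros(config.n_cells)
    act_times = np.zeros((config.n_cells, len(config.clusters)))
    boundaries = sorted({t for p in config.pulses for t in p})
    for ci in range(config.n_cells):
        cell = simulate_cell(config, rng)
        entry_times[ci] = cell.entry_time
        act_times[ci] = cell.activation_times
        for chrom, origins in cell.origins.items():
            length = config.chrom_lengths[chrom]
            reps = {t: replicated_intervals(origins, t, config.fork_rate_kb_min, length)
                    for t in boundaries}
            for pi, (t1, t2) in enumerate(config.pulses):
                lab = _difference(reps[t2], reps[t1])
                _add_coverage(labelled[pi][chrom], lab, config.bin_size)

    pulldown, control, expected = [], [], []
    for pi in range(n_pulses):
        P: dict[str, BinnedTrack] = {}
        C: dict[str, BinnedTrack] = {}
        exp_chrom: dict[str, np.ndarray] = {}
        for chrom, n in n_bins.items():
            mean_kb = labelled[pi][chrom] / config.n_cells / 1e3
            lam = config.reads_per_kb * mean_kb + config.background_rate
            P[chrom] = BinnedTrack(chrom, config.bin_size,
                                   rng.poisson(lam).astype(float), role="raw_count")
            C[chrom] = BinnedTrack(chrom, config.bin_size,
                                   rng.poisson(config.control_reads_per_bin, n).astype(float),
                                   role="raw_count")
            exp_chrom[chrom] = mean_kb * 1e3
        pulldown.append(P)
        control.append(C)
        expected.append(exp_chrom)

    mean_act = np.nanmean(np.where(np.isnan(act_times), np.nan, act_times), axis=0)
    table = pd.DataFrame({
        "chrom": [s.chrom for s in config.clusters],
        "centre_bp": [s.centre for s in config.clusters],
        "origin_span_bp": [s.width for s in config.clusters],
        "n_origins": [s.n_origins for s in config.clusters],
        "group_id": [s.group_id for s in config.clusters],
        "mean_activation_min": mean_act,
    })
    gt = GroundTruth(cluster_table=table, entry_times=entry_times,
                     activation_times=act_times,
                     expected_labelled_bp=expected, seed=config.rng_seed)
    return SimulationResult(config=config, pulldown=pulldown, control=control,
                            ground_truth=gt)


# ---------------------------------------------------------------------------
# Benchmark presets

FORK = 1.5
PULSE_LEN = 30.0
# fork travel to the half-max point of the pulse-1 profile under a uniform
# activation density: v * (t2 - dt/2) per side
PROFILE_PAD_T1 = 2 * FORK * (DEFAULT_PULSES[0][1] - PULSE_LEN / 2.0) * 1e3  # 75 kb


def _cluster_row(chrom, centre, width, activation, n_origins=4, group=None,
                 efficiency=1.0):
    return ClusterSpec(chrom=chrom, centre=float(centre), width=float(width),
                       n_origins=n_origins, activation=activation,
                       efficiency=efficiency, group_id=group)


def _scale_config(target_profile_kb: float, seed: int) -> SimulationConfig:
    width = target_profile_kb * 1e3 - PROFILE_PAD_T1
    clusters, domains = [], []
    spacing, per_domain, n_domains, late_gap = 1.8e6, 6, 5, 3.0e6
    pos = 2.0e6
    for d in range(n_domains):
        start = pos
        for k in range(per_domain):
            clusters.append(_cluster_row("chr1", pos + spacing / 2 + k * spacing,
                                         width, ("uniform", 0.0, 100.0),
                                         n_origins=8))
        end = pos + per_domain * spacing
        domains.append(("chr1", int(start), int(end), "early"))
        domains.append(("chr1", int(end), int(end + late_gap), "late"))
        pos = end + late_gap
    return SimulationConfig(
        chrom_lengths={"chr1": int(pos + 2e6)}, clusters=clusters, domains=domains,
        bin_size=50_000, entry_window_min=0.0, n_cells=100,
        reads_per_kb=10.0, background_rate=2.0, control_reads_per_bin=60.0,
        candidate_factor=1, rng_seed=seed)


def _growth_config(seed: int, entry_window: float) -> SimulationConfig:
    width = 500e3 - PROFILE_PAD_T1
    spacing = 4.0e6
    n_clusters = 30
    clusters, domains = [], []
    for k in range(n_clusters):
        centre = 2.0e6 + k * spacing
        clusters.append(_cluster_row("chr1", centre, width,
                                     ("uniform", 0.0, 140.0), n_origins=8))
        domains.append(("chr1", int(centre - 1.0e6), int(centre + 1.0e6), "early"))
        domains.append(("chr1", int(centre + 1.0e6), int(centre + spacing - 1.0e6),
                        "late"))
    length = int(2.0e6 + n_clusters * spacing)
    return SimulationConfig(
        chrom_lengths={"chr1": length}, clusters=clusters, domains=domains,
        bin_size=10_000, entry_window_min=entry_window, n_cells=200,
        reads_per_kb=40.0, background_rate=1.0, control_reads_per_bin=40.0,
        candidate_factor=1, rng_seed=seed)


def _valleys_config(seed: int) -> SimulationConfig:
    clusters, domains = [], []
    unit, late_gap = 2.8e6, 2.0e6
    pos = 1.5e6
    for d in range(20):
        left = pos + 0.5e6
        right = left + 1.8e6
        clusters.append(_cluster_row("chr1", left, 400e3, ("uniform", 0.0, 140.0),
                                     n_origins=6))
        clusters.append(_cluster_row("chr1", right, 400e3, ("uniform", 0.0, 140.0),
                                     n_origins=6))
        # valley origins activate late, with density still rising at the end
        # of the timecourse, so each successive pulse labels more valley DNA
        clusters.append(_cluster_row("chr1", (left + right) / 2, 1000e3,
                                     ("normal", 130.0, 30.0), n_origins=10,
                                     efficiency=0.45))
        domains.append(("chr1", int(pos), int(pos + unit), "early"))
        domains.append(("chr1", int(pos + unit), int(pos + unit + late_gap), "late"))
        pos += unit + late_gap
    return SimulationConfig(
        chrom_lengths={"chr1": int(pos + 1e6)}, clusters=clusters, domains=domains,
        bin_size=50_000, entry_window_min=0.0, n_cells=120,
        reads_per_kb=10.0, background_rate=2.0, control_reads_per_bin=60.0,
        candidate_factor=1, rng_seed=seed)


def _domino_config(seed: int, coupled: bool, n_groups: int = 200,
                   group_size: int = 5,
                   rng: np.random.Generator | None = None) -> SimulationConfig:
    rng = rng if rng is not None else np.random.default_rng(seed + 7)
    clusters, domains = [], []
    spacing, margin, late_gap = 1.2e6, 0.8e6, 2.5e6
    n_chroms = 8
    per_chrom = -(-n_groups // n_chroms)
    g = 0
    chrom_lengths = {}
    for ch in range(n_chroms):
        chrom = f"chr{ch + 1}"
        pos = 1.5e6
        for _ in range(per_chrom):
            if g >= n_groups:
                break
            start = pos
            for k in range(group_size):
                centre = pos + margin + k * spacing
                if coupled:
                    activation = (("normal", 12.0, 2.0) if k == 0
                                  else ("normal", 12.0, 2.0))  # later members via coupling
                else:
                    activation = ("normal", float(rng.uniform(12.0, 35.0)), 5.0)
                clusters.append(_cluster_row(chrom, centre, 450e3, activation,
                                             group=g))
            end = pos + 2 * margin + (group_size - 1) * spacing
            domains.append((chrom, int(start), int(end), "early"))
            domains.append((chrom, int(end), int(end + late_gap), "late"))
            pos = end + late_gap
            g += 1
        chrom_lengths[chrom] = int(pos + 1e6)
    return SimulationConfig(
        chrom_lengths=chrom_lengths, clusters=clusters, domains=domains,
        bin_size=50_000, entry_window_min=0.0, n_cells=60,
        reads_per_kb=12.0, background_rate=2.0, control_reads_per_bin=60.0,
        domino_coupling=("on", 5.0, 2.0) if coupled else None,
        rng_seed=seed)


def make_benchmark_suite(preset: str, seed: int = 0, **kwargs) -> tuple[SimulationConfig, dict]:
    """Named, seeded simulation configurations with machine-readable
    expectations.

    Presets: ``basic`` (two-chromosome smoke/recall genome),
    ``scale_300`` / ``scale_500`` / ``scale_800`` (planted profile widths
    for the width scan), ``growth`` / ``growth_staggered`` (isolated
    clusters for width-growth kinetics), ``valleys`` (late-activating
    valley clusters), ``domino_null`` / ``domino_coupled`` (independent vs
    sequentially coupled activation).
    """
    if preset == "basic":
        clusters, domains = [], []
        for chrom in ("chr1", "chr2"):
            for dstart, dend in ((2.0e6, 8.0e6), (12.0e6, 18.0e6)):
                domains.append((chrom, int(dstart), int(dend), "early"))
                for k in range(4):
                    clusters.append(_cluster_row(chrom, dstart + 0.75e6 + k * 1.5e6,
                                                 425e3, ("uniform", 0.0, 100.0),
                                                 n_origins=8))
            domains.append((chrom, int(8.0e6), int(12.0e6), "late"))
            domains.append((chrom, 0, int(2.0e6), "late"))
            domains.append((chrom, int(18.0e6), int(20.0e6), "late"))
        config = SimulationConfig(
            chrom_lengths={"chr1": 20_000_000, "chr2": 20_000_000},
            clusters=clusters, domains=domains, bin_size=50_000,
            entry_window_min=0.0, n_cells=100, reads_per_kb=10.0,
            background_rate=2.0, control_reads_per_bin=60.0, rng_seed=seed)
        expect = {"true_profile_width_bp": 500e3, "n_clusters": len(clusters)}
        return config, expect
    if preset.startswith("scale_"):
        target = float(preset.split("_")[1])
        return (_scale_config(target, seed),
                {"true_profile_width_bp": target * 1e3})
    if preset == "growth":
        return (_growth_config(seed, entry_window=0.0),
                {"expected_growth_bp_per_interval": 2 * FORK * PULSE_LEN * 1e3})
    if preset == "growth_staggered":
        return (_growth_config(seed, entry_window=45.0),
                {"expected_growth_bp_per_interval": 2 * FORK * PULSE_LEN * 1e3,
                 "first_interval_suppressed": True})
    if preset == "valleys":
        return (_valleys_config(seed),
                {"min_pct_monotone_increasing": True})
    if preset == "domino_null":
        return (_domino_config(seed, coupled=False, **kwargs),
                {"expected_weighted_metric_mean": 0.0})
    if preset == "domino_coupled":
        return (_domino_config(seed, coupled=True, **kwargs),
                {"expected_weighted_metric_sign": 1})
    raise ValueError(f"unknown preset {preset!r}")
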