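"""End-to-end orchestration of the RCD analysis and tabular/plot outputs.

``run_pipeline`` executes, in order: normalization (RPM + background
subtraction per timepoint) → wavelet convolution at the working width →
RCD calling with the late-domain percentile cutoff → isolated-peak width
dynamics → valley definition/tracking/filling → domino grouping and
ordering statistics.  Any stage can be skipped; all stage tables are
written as TSV under an output directory, and every run records its
configuration so that rerunning with the same inputs and seed reproduces
byte-identical tables.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import detection, domino, dynamics, normalization, valleys, wavelet
from .simulate import SimulationResult
from .tracks_io import BinnedTrack, TimingDomainSet, write_bedgraph

__all__ = ["PipelineConfig", "PipelineRun", "run_pipeline", "export_heatmap"]

STAGES = ("normalize", "rcds", "dynamics", "valleys", "domino")


@dataclass
class PipelineConfig:
    wavelet_width_bp: float = 500e3
    cutoff_percentile: float = 70.0
    isolation_flank_bp: float = 500e3
    isolation_max_ratio: float = 0.25
    valley_trim_bp: float = valleys.TRIM_BP
    valley_tolerance_bp: float = 100e3
    group_max_gap_bp: float = domino.MAX_GROUP_GAP_BP
    dynamics_grid_kb: tuple = (200.0, 1200.0, 25.0)
    skip: tuple = ()
    normalization_method: str = "mode"


@dataclass
class PipelineRun:
    config: PipelineConfig
    log: list[str] = field(default_factory=list)
    norm_report: pd.DataFrame | None = None
    signal_tracks: list[dict[str, BinnedTrack]] | None = None
    peaks_by_timepoint: list[list[detection.WaveletPeak]] | None = None
    rcds_by_timepoint: list[list[detection.RCD]] | None = None
    rcd_table: pd.DataFrame | None = None
    growth: dynamics.GrowthStats | None = None
    valley_report: dict | None = None
    domino_report: dict | None = None

    def info(self, msg: str) -> None:
        self.log.append(msg)


def _call_all_peaks(S: dict[str, BinnedTrack], width: float,
                    domains: TimingDomainSet, label: str) -> list[detection.WaveletPeak]:
    out: list[detection.WaveletPeak] = []
    kernel_cache: dict[int, wavelet.RickerKernel] = {}
    for chrom, track in S.items():
        kern = kernel_cache.setdefault(track.bin_size,
                                       wavelet.ricker_kernel(width, track.bin_size))
        conv = wavelet.convolve_track(track, kern)
        region = domains.regions(label, chrom)
        if len(region) == 0:
            continue
        out.extend(detection.call_peaks(conv, region, width_W=width))
    return out


def run_pipeline(sim: SimulationResult, config: PipelineConfig | None = None,
                 out_dir: str | Path | None = None) -> PipelineRun:
    """Run the analysis stages over a simulated (or equivalently loaded)
    four-pulse dataset."""
    config = config or PipelineConfig()
    run = PipelineRun(config=config)
    domains = sim.config.timing_domains()
    n_tp = len(sim.pulldown)
    if n_tp != 4:
        run.info(f"warning: expected 4 pulses, got {n_tp}")

    # --- normalization ------------------------------------------------
    if "normalize" in config.skip:
        run.info("normalize: skipped")
        return run
    S_tracks, rows = [], []
    for tp in range(n_tp):
        S, fit = normalization.normalize_timepoint(
            sim.pulldown[tp], sim.control[tp], method=config.normalization_method)
        S_tracks.append(S)
        rows.append({"timepoint": tp + 1, **fit.report_row()})
    run.signal_tracks = S_tracks
    run.norm_report = pd.DataFrame(rows)
    run.info(f"normalize: {n_tp} timepoints, chosen_r = "
             + ", ".join(f"{r['chosen_r']:.3f}" for r in rows))

    # --- RCD calling --------------------------------------------------
    if "rcds" in config.skip:
        run.info("rcds: skipped")
        return run
    W = config.wavelet_width_bp
    peaks_by_tp, rcds_by_tp = [], []
    for tp in range(n_tp):
        early = _call_all_peaks(S_tracks[tp], W, domains, "early")
        late = _call_all_peaks(S_tracks[tp], W, domains, "late")
        cutoff = detection.calibrate_cutoff(late, percentile=config.cutoff_percentile)
        rcds: list[detection.RCD] = []
        for chrom in S_tracks[tp]:
            chrom_early = [p for p in early if p.chrom == chrom]
            rcds.extend(detection.filter_rcds(chrom_early, cutoff,
                                              S_tracks[tp][chrom], domains,
                                              timepoint_id=tp + 1))
        peaks_by_tp.append(early)
        rcds_by_tp.append(rcds)
        run.info(f"rcds tp{tp + 1}: {len(early)} early peaks -> {len(rcds)} "
                 f"RCDs above the {config.cutoff_percentile:.0f}th late percentile "
                 f"({cutoff.threshold_value:.3g})")
    run.peaks_by_timepoint = peaks_by_tp
    run.rcds_by_timepoint = rcds_by_tp
    run.rcd_table = pd.concat([detection.rcds_to_table(r) for r in rcds_by_tp],
                              ignore_index=True)

    # --- peak dynamics ------------------------------------------------
    if "dynamics" not in config.skip and n_tp >= 2:
        chroms = list(S_tracks[0])
        fwhm_rows = []
        for chrom in chroms:
            rcds1 = [r for r in rcds_by_tp[0] if r.chrom == chrom]
            iso = dynamics.select_isolated(rcds1, S_tracks[0][chrom],
                                           flank=config.isolation_flank_bp,
                                           max_ratio=config.isolation_max_ratio)
            for peak in iso:
                series = [dynamics.fit_gaussian(peak, S_tracks[tp][chrom])
                          for tp in range(n_tp)]
                if all(f.converged for f in series):
                    fwhm_rows.append([f.fwhm for f in series])
        lo, hi, _ = config.dynamics_grid_kb
        accepted = [row for row in fwhm_rows
                    if all(lo * 1e3 <= w <= hi * 1e3 for w in row)]
        run.info(f"dynamics: {len(fwhm_rows)} isolated fits, "
                 f"{len(accepted)} inside [{lo:.0f}, {hi:.0f}] kb")
        if len(accepted) >= 2:
            run.growth = dynamics.growth_stats(np.asarray(accepted))
    elif "dynamics" in config.skip:
        run.info("dynamics: skipped")

    # --- valleys ------------------------------------------------------
    if "valleys" not in config.skip and n_tp >= 2:
        valley_list = valleys.define_valleys(peaks_by_tp[0], domains,
                                             trim=config.valley_trim_bp)
        tracked = valleys.track_valleys(valley_list, peaks_by_tp[1:],
                                        tolerance=config.valley_tolerance_bp)
        tcs = []
        for v in tracked:
            tc = valleys.ValleyTimecourse(valley=v)
            ok = True
            for tp in range(n_tp):
                res = valleys.valley_signal(v, S_tracks[tp][v.chrom])
                if res is None:
                    ok = False
                    break
                tc.mean_pct.append(res[0])
                tc.min_pct.append(res[1])
            if ok:
                tcs.append(tc)
        run.info(f"valleys: {len(valley_list)} defined, {len(tracked)} tracked, "
                 f"{len(tcs)} with usable flanks")
        if len(tcs) >= 2:
            run.valley_report = valleys.filling_stats(tcs)
    elif "valleys" in config.skip:
        run.info("valleys: skipped")

    # --- domino -------------------------------------------------------
    if "domino" not in config.skip:
        groups_by_tp = [domino.form_groups(r, max_gap=config.group_max_gap_bp)
                        for r in rcds_by_tp]
        try:
            report = domino.weighted_similarity_report(
                [g for gs in groups_by_tp for g in gs])
        except ValueError:
            report = None
        run.domino_report = {
            "groups_by_timepoint": groups_by_tp,
            "freq3": domino.permutation_frequencies(groups_by_tp, 3),
            "freq4": domino.permutation_frequencies(groups_by_tp, 4),
            "similarity": report,
        }
        run.info("domino: "
                 + ", ".join(f"tp{t + 1}:{len(gs)} groups"
                             for t, gs in enumerate(groups_by_tp)))
    else:
        run.info("domino: skipped")

    if out_dir is not None:
        _write_outputs(run, sim, Path(out_dir))
    return run


def _write_outputs(run: PipelineRun, sim: SimulationResult, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "run_config.json", "w") as fh:
        json.dump({"pipeline": run.config.__dict__, "seed": sim.config.rng_seed},
                  fh, indent=1, default=str)
    if run.norm_report is not None:
        run.norm_report.to_csv(out / "normalization_report.tsv", sep="\t", index=False)
    if run.signal_tracks is not None:
        for tp, S in enumerate(run.signal_tracks):
            write_bedgraph(S, out / f"signal_tp{tp + 1}.bedgraph")
    if run.rcd_table is not None:
        run.rcd_table.to_csv(out / "rcd_table.tsv", sep="\t", index=False)
    if run.domino_report is not None:
        run.domino_report["freq3"].to_csv(out / "permutation_freq3.tsv", sep="\t")
        run.domino_report["freq4"].to_csv(out / "permutation_freq4.tsv", sep="\t")
    with open(out / "run_log.txt", "w") as fh:
        fh.write("\n".join(run.log) + "\n")


def export_heatmap(widths: np.ndarray, matrix: np.ndarray, path_prefix: str | Path,
                   bin_size: int | None = None) -> tuple[Path, Path]:
    """Write a multiscale wavelet matrix as raw TSV plus a display image.

    The TSV holds the raw per-scale values; the image is per-scale
    max-normalized and clamped to [0, 1] (values of zero or below map to
    the bottom of the colour scale), with the √2 width ladder on the y
    axis.  Returns (tsv_path, image_path).
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    path_prefix = Path(path_prefix)
    tsv = path_prefix.with_suffix(".tsv")
    img = path_prefix.with_suffix(".png")
    df = pd.DataFrame(matrix, index=[f"{w / 1e3:.0f}kb" for w in widths])
    df.to_csv(tsv, sep="\t")

    disp = np.zeros_like(matrix, dtype=float)
    for i, row in enumerate(matrix):
        top = row.max()
        disp[i] = np.clip(row / top, 0.0, 1.0) if top > 0 else 0.0
    fig, ax = plt.subplots(figsize=(10, 4))
    extent = None
    if bin_size:
        extent = (0, matrix.shape[1] * bin_size / 1e6, 0, len(widths))
    ax.imshow(disp[::-1], aspect="auto", cmap="jet", vmin=0, vmax=1,
              interpolation="nearest", extent=extent)
    ax.set_yticks(np.arange(len(widths)) + 0.5)
    ax.set_yticklabels([f"{w / 1e3:.0f}" for w in widths])
    ax.set_ylabel("wavelet peak width (kb)")
    ax.set_xlabel("position (Mb)" if bin_size else "bin")
    fig.tight_layout()
    fig.savefig(img, dpi=110)
    plt.close(fig)
    return tsv, img
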