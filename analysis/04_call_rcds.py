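"""Call Replicon Cluster Domains on the simulated first-pulse signal.

Reads the signal bedGraphs and timing table produced by scripts 01/02,
convolves the first pulse with a 500-kb Ricker, calibrates the peak-height
cutoff at the 70th percentile of late-domain peaks, and writes the RCD
table with per-domain separation statistics.  Recall against the planted
cluster centres is reported.
"""

import sys
from pathlib import Path

from rcdomains import detection, wavelet
from rcdomains.tracks_io import load_timing_domains, read_bedgraph

BASE = Path(__file__).resolve().parent.parent / "results" / "sim_basic"
W = 500e3
BIN = 50_000


def main():
    if not (BASE / "signal_tp1.bedgraph").exists():
        print("run 01_simulate_tracks.py and 02_normalize_tracks.py first",
              file=sys.stderr)
        return 1
    import json
    with open(BASE / "sim_config.json") as fh:
        chrom_lengths = {k: int(v) for k, v in
                         json.load(fh)["chrom_lengths"].items()}
    S = read_bedgraph(BASE / "signal_tp1.bedgraph", BIN, chrom_lengths,
                      role="signal")
    domains = load_timing_domains(BASE / "timing_domains.rt.txt")

    early_by_chrom, late = {}, []
    for chrom, track in S.items():
        conv = wavelet.convolve_track(track, wavelet.ricker_kernel(W, BIN))
        early_by_chrom[chrom] = detection.call_peaks(
            conv, domains.regions("early", chrom), width_W=W)
        late.extend(detection.call_peaks(conv, domains.regions("late", chrom),
                                         width_W=W))
    cutoff = detection.calibrate_cutoff(late, percentile=70)
    rcds = []
    for chrom, peaks in early_by_chrom.items():
        rcds.extend(detection.filter_rcds(peaks, cutoff, S[chrom], domains,
                                          timepoint_id=1))
    n_early = sum(len(p) for p in early_by_chrom.values())
    print(f"{n_early} early-domain peaks; cutoff = 70th late percentile "
          f"({cutoff.threshold_value:.3g} over {cutoff.n_late_peaks} late "
          f"peaks) -> {len(rcds)} RCDs")

    st = detection.rcd_stats(rcds)
    if st["separations_bp"].size:
        print(f"mean within-domain separation: "
              f"{st['mean_separation_bp'] / 1e6:.3f} "
              f"+/- {st['sd_separation_bp'] / 1e6:.3f} Mb "
              f"({st['separations_bp'].size} pairs)")

    import pandas as pd
    truth = pd.read_csv(BASE / "true_clusters.tsv", sep="\t")
    hits = 0
    for _, row in truth.iterrows():
        if any(r.chrom == row.chrom and abs(r.position - row.centre_bp) <= BIN
               for r in rcds):
            hits += 1
    print(f"recall vs planted clusters: {hits}/{len(truth)}")

    detection.rcds_to_table(rcds).to_csv(BASE / "rcd_table.tsv", sep="\t",
                                         index=False)
    print(f"RCD table -> {BASE / 'rcd_table.tsv'}")


if __name__ == "__main__":
    sys.exit(main())
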