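# rcdomains

Analysis of **Replicon Cluster Domains (RCDs)** in EdU pull-down
sequencing timecourses of early S phase, with a kinetic simulator of
clustered replication origins that makes every stage testable without
external data.

In synchronised cells pulsed with EdU, nascent DNA captured by pull-down
produces a binned coverage track **P** per pulse, alongside a genomic
input control **C**. Early-replicating DNA shows bump-like features at
the ~500-kb scale — the footprint of *replicon clusters*, groups of 3–6
origins firing near-synchronously.  This package implements the
computational chain that locates and characterises those features:

1. **Background normalization.** Modelling `P_i = r·C_i + S_i`, the plot
   of `y = log(P_i/C_i)` against `x = log(P_i + C_i)` is fitted with a
   two-segment broken line; bins left of the breakpoint *b* form the
   background set `G = {i : x_i < b}`. The capture ratio is estimated as
   `r̂ᶜⁱˢ = Σ_G P_i / Σ_G C_i` or, more robustly when G is contaminated
   by signal, as the mode of the `P_j/C_j` distribution on G. The signal
   is `S_i = P_i − r̂·C_i` (negatives retained).
2. **Ricker-wavelet detection.** The signal is convolved with Mexican-hat
   wavelets parameterised by *peak width* W (distance between zero
   crossings; σ = W/2), from 50 kb to 51.2 Mbp in √2 steps. Positive
   local maxima at W = 500 kb that exceed the 70th nearest-rank
   percentile of peak heights in *late* timing domains (the noise floor)
   are the RCDs.
3. **Width dynamics.** Isolated RCDs (flanking signal ≤ 25% of
   under-peak signal) are followed over four 30-min pulses; widths are
   fitted by the best-matching wavelet on a 200–1200-kb grid and by
   Nelder-Mead Gaussian fits. Two diverging forks at v = 1.5 kb/min
   predict a width increase of 2·v·Δt = 90 kb per 30-min interval.
4. **Valley filling.** Gaps between adjacent wavelet peaks inside one
   early timing domain, trimmed by 180 kb (fork travel over two hours),
   are tracked across pulses; their mean/min signal as a percentage of
   the flanking peak heights measures later initiation between clusters.
5. **Domino ordering.** RCDs < 1.6 Mbp apart in one timing domain form
   groups; height-rank permutation classes (canonical under reversal) and
   the adjacent-value-similarity metric
   `1 − (ADFA − ADFSV)/(MADFAP − ADFSV)` — exactly 1 for monotone height
   order, mean 0 over random orderings — test whether neighbouring
   clusters activate sequentially.

The simulator (`rcdomains.simulate`) generates P/C bedGraph tracks from
an explicit kinetic model — S-phase entry over a 45-min window, cluster
activation laws, stochastic origin choice, 1.5 kb/min bidirectional forks
merging on meeting, EdU pulses labelling exactly the DNA made in the
window, Poisson read sampling — with full ground truth.

## Worked example

The numbered scripts under `analysis/` run the full study on simulated
genomes and write tables under `results/`:

```sh
python analysis/01_simulate_tracks.py
python analysis/02_normalize_tracks.py
python analysis/04_call_rcds.py
python analysis/05_measure_peak_growth.py
```

Script 04 prints, for the 16-cluster benchmark genome:

```
16 early-domain peaks; cutoff = 70th late percentile (74.2 over 13 late peaks) -> 16 RCDs
mean within-domain separation: 1.500 +/- 0.043 Mb (12 pairs)
recall vs planted clusters: 16/16
```

— every planted cluster is recovered as an RCD and the within-domain
separations match the planted 1.5-Mb spacing.  Script 05 measures fork
kinetics on isolated clusters:

```
growth: 30 RCDs -> 30 isolated, 0 rejected at grid extremes
  mean width per pulse (kb): 509 588 677 764
  mean width increase per interval (kb): 79.2 88.3 87.5; pooled 85.0 kb [95% CI 79.2, 90.8], p = 3.29e-47
  growth rate: 2.83 kb/min (two converging forks at 1.5 kb/min predict 3.0)
```

— peaks widen by ≈ 90 kb per 30-min interval, the signature of two
diverging forks; with S-phase entry staggered over 45 min the first
interval's growth drops to ≈ 34 kb while later intervals stay at ≈ 80–90
(script output for `growth_staggered`).  Scripts 03, 06 and 07 likewise
recover the planted 500-kb scale from the width scan, show valley minima
rising monotonically from ~0% to ~19% of flanking peak height across the
pulses, and separate domino-coupled activation (metric mean +0.996) from
independent activation (+0.065, not significant per group) at 200
simulated groups.

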