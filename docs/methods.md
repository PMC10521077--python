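# Methods

## Data model and conventions

All tracks are fixed-width binned coverage on 0-based half-open
coordinates (bedGraph native). `BinnedTrack` carries an explicit boolean
mask; masked bins (e.g. outside a clipped timing-domain region) are
excluded from sums, percentiles and peak calls rather than set to zero,
so clipping a track to complementary regions partitions its total signal
exactly. Reads are assigned to bins by fragment midpoint, which counts
each read exactly once. Replication-timing tables (chrom, start, end, RT)
are segmented by sign: RT > 0 runs merge into early domains, RT < 0 into
late, RT = 0 into neither; the column layout is configurable because
deposited timing tables vary.

## Background normalization

The pull-down is modelled as `P_i = r·C_i + S_i` with the control C
giving the spatial shape of the background and r the unknown capture
ratio. On `y = log(P_i/C_i)` vs `x = log(P_i + C_i)` (natural logs; G
membership is base-invariant when both axes share a base), a two-segment
model — horizontal left segment at the mean of left ys, ordinary least
squares on the right, no continuity constraint — is scored by total
squared error over 200 candidate breakpoints at the empirical 5th–95th
percentile quantiles of x. Ties resolve toward the larger background
set, so the exact no-signal limit yields G ≈ all bins.

Two estimators of r over G: the ratio of sums (`cis`), and the mode of
the per-bin ratios located by a Gaussian KDE (Silverman bandwidth, argmax
on a 512-point grid spanning the observed ratios; degenerate
zero-variance ratio sets short-circuit to their common value). The mode
is the default because residual signal contaminating G inflates the
ratio-of-sums but barely moves the distribution peak. Bins with C = 0
are excluded from G and get `S = P` in the subtraction; negative S values
are kept (display layers may clamp, the statistics do not).

One caveat found while validating on no-signal data: with pure Poisson
noise the right OLS segment can absorb the intrinsic ratio–total
correlation and carve off a small, biased G. The fit is therefore
flagged degenerate when the right segment's mean ratio is not elevated
above the background band by at least one background standard deviation,
and `normalize_timepoint` then estimates r over all eligible bins. The
breakpoint is fitted genome-wide (ratios are a property of the library,
not the chromosome); a per-chromosome fit is available by calling
`fit_breakpoint` with a single-chromosome map.

## Ricker wavelet and scale scan

"Peak width" W is the distance between the zero crossings of the central
positive lobe: σ = W/2, with the constant isolated in `ricker_kernel`.
Taps are sampled on the bin grid from `(1 − t²/σ²)·exp(−t²/2σ²)`,
truncated at ±4σ, and mean-subtracted afterwards so Σtaps = 0 exactly:
the response to a constant track is identically zero despite truncation.
Widths below two bins are unresolvable and rejected (the multiscale
ladder silently drops them, matching the practice of using 10-kb bins
for the finest scales). Chromosome ends are zero-padded; the first and
last half-support of each convolution carries a known edge bias.

Amplitude normalization divides the unit-maximum taps by σ/bin. The
choice is load-bearing for cross-width comparisons: with unit-maximum
taps the peak response to an isolated flat-topped feature of width F is
`F·exp(−F²/8σ²)` — monotonically increasing in σ, so a width scan of an
isolated feature has no interior optimum. With the 1/σ scaling the
response is `(F/σ)·exp(−F²/8σ²)`, maximised exactly at σ = F/2, i.e.
W = F: the scan recovers the feature width, which is the behaviour the
analysis depends on (validated on planted 300/500/800-kb profiles). The
closed form doubles as the test oracle. Within a single width the
normalization is a constant and does not affect peak calling or height
ranking.

`width_scan` calls peaks per width and records the sum and mean of their
heights, optionally filtered by the late-domain percentile cutoff
recomputed at each width. On the planted-profile genomes the scan
optimum sits at the planted width for 500 and 800 kb and one step above
(400 kb) for 300-kb profiles, whose shoulders are large relative to the
plateau.

## RCD calling

Peaks are strict positive local maxima; plateaus resolve to their centre
bin (leftmost of the two central bins when even), and a peak cannot span
a masked gap. The height cutoff is the nearest-rank percentile
(`ceil(p/100·n)`-th order statistic) of late-domain peak heights at the
same width — late domains carry essentially no first-pulse signal, so
their peaks estimate the noise floor; at p = 70 the rule removes exactly
⌊0.7·n⌋ of the late peaks when 0.7·n is integral. RCDs annotate the
wavelet height, the timing domain containing the peak *position*, and
the replication peak height — the maximum of S over the extent
(position ± W/2, the zero-crossing width convention for "the edges of
the wavelet peak"). Separation statistics use centre-to-centre distances
within domains.

## Width dynamics of isolated peaks

Isolation: the combined signal of the two 500-kb windows abutting the
extent must not exceed 25% of the under-peak signal (a per-side variant
is available; the combined reading is the default interpretation of
"the 500 kb on either side"). Peaks whose extent or flanks cross a
chromosome end are excluded.

Widths per timepoint come from (i) the grid of Ricker widths 200–1200 kb
in 25-kb steps, taking the width maximising the convolved response
within ±W/2 of the peak; and (ii) a Nelder-Mead least-squares Gaussian
`A·exp(−(x−c)²/2σ²) + b` over the extent padded by 500 kb (initialised
at c = peak position, σ = W/4, A = max S, b = 0; relative tolerance
1e-6, 2000 iterations, one restart from a perturbed start on
non-convergence; FWHM = 2√(2 ln 2)·σ identically). A baseline term is
included because background subtraction leaves small offsets. Series
hitting the grid extremes (or Gaussian FWHM outside 200–1200 kb) at any
timepoint are rejected. A flat-topped Gaussian (plateau half-width
parameter; total width at half max = 2·plateau + FWHM) is available as a
diagnostic.

On the simulated flat-topped profiles the plain Gaussian FWHM is a
biased width measure whose bias varies with the plateau-to-shoulder
ratio, so the kinetic growth summary uses the wavelet grid fit; the
Gaussian path is validated on Gaussian-shaped profiles, where it is
exact. Growth statistics are per-interval width differences across
accepted peaks: mean, SE, 95% CI, two-sided one-sample t against zero,
and a rate in kb/min (pooled mean over the 30-min interval). All-equal
deltas make t undefined; p is reported as 1 by convention.

## Valleys

Valleys are gaps between adjacent wavelet peaks (called **without** a
height cutoff) inside one early timing domain, trimmed inward by
180 kb = 1.5 kb/min × 120 min — fork travel between the first and last
pulse starts — so passive fork movement cannot masquerade as valley
replication; the constant is asserted in the tests. Tracking requires
each flank's nearest same-chromosome peak to lie within ±100 kb at every
later timepoint (ties toward the higher peak). Valley mean and min
signal are expressed per timepoint as percentages of the mean flanking
*replication* peak height (max S over each flank extent), making
timepoints with independent library depths comparable; valleys with
non-positive flanking height are excluded. Per-valley filling rates are
least-squares slopes of mean-% against pulse midpoints (25/55/85/115
min) — robust to one noisy timepoint — with a successive-difference mode
available.

## Domino statistics

Groups are maximal runs of RCDs with centre-to-centre distance
< 1.6 Mbp within one timing domain (an edge-to-edge option exists;
centre distance is the default convention). For 3- and 4-member groups
the height ranks along the chromosome (1 = highest; ties broken by
position with a warning) are canonicalised as the lexicographic minimum
of the sequence and its reversal — chromosome direction is arbitrary —
giving 3 classes for n = 3 and 12 for n = 4, uniform under i.i.d.
heights.

The adjacent-value-similarity metric is
`1 − (ADFA − ADFSV)/(MADFAP − ADFSV)` with ADFA the mean |adjacent
difference| of the height array, ADFSV the same for the sorted array
(= (max − min)/(n − 1), the minimum possible ADFA), and MADFAP the mean
|difference| over all unordered distinct pairs, which equals the
expectation of ADFA over random orderings — hence value 1 iff monotone,
exact mean 0 over all permutations, negative for interleaved orders.
It is undefined when MADFAP = ADFSV (always at n = 2).

For reporting, each group of n ≥ 4 contributes its value n − 1 times
(one unit of evidence per adjacency; "recorded", not log-transformed —
the replicated and once-per-group samples are both reported and only the
replicated one depends on that reading). Groups of three are excluded:
with three members the metric cannot separate random from anti-ordered.
The replicated sample's t-test treats duplicated values as independent
and is therefore anti-conservative; the once-per-group test is the
honest null check and both are printed.

## Synthetic data generator

Per cell: S entry `t₀ ~ U[0, entry_window]` (0 = synchronous); each
cluster activates with probability = efficiency at `t₀ +` a draw from
its activation law (normal, floored at 0, or uniform); `n_origins`
origins are chosen uniformly without replacement from candidate
positions evenly spaced across the cluster span (endpoints included,
positional jitter sd = spacing/4), each firing after a non-negative
normal jitter (sd 2 min); bidirectional forks extend at 1.5 kb/min and
merge on meeting (interval union). A pulse labels
`replicated(t₂) \ replicated(t₁)`; consecutive pulses are disjoint and
tile by construction. Expected pull-down reads per bin are
`reads_per_kb × mean labelled kb per cell + background_rate`, Poisson
sampled; the control is Poisson from a uniform profile. With domino
coupling on, clusters sharing a group activate sequentially along the
chromosome, each a positive normal delay after its predecessor.

A geometric fact drives the kinetic presets: if cluster activation times
have uniform density covering the pulse span, the population per-pulse
profile of an isolated cluster is a plateau over the origin span with
linear shoulders, and its half-max width is
`span + 2·v·(t₂ − Δt/2)` — growing by exactly 2·v·Δt = 90 kb per
successive pulse. A cohort with literally simultaneous activation
instead produces hollow per-pulse shells (a pulse labels only the fork
fronts), whose fitted width growth is *not* 2·v·Δt; sustained activation
heterogeneity is what keeps cluster interiors labelling, exactly the
population-mixture picture motivating the growth analysis. Presets that
plant a nominal profile width therefore use an origin span of
`nominal − 75 kb` and record both in the ground truth.

Preset conditions (all four pulses 10–40/40–70/70–100/100–130 min, fork
1.5 kb/min):

* `basic` — 2 × 20 Mb chromosomes, 50-kb bins, 16 clusters of 500-kb
  profile width spaced 1.5 Mb inside early domains, activation
  U[0, 100] min, 100 cells.
* `scale_300/500/800` — one chromosome, five early domains of six
  clusters at 1.8-Mb spacing; planted profile widths for the width scan.
* `growth` / `growth_staggered` — 30 isolated clusters 4 Mb apart,
  10-kb bins, 8 origins per cluster (tight spacing keeps the first-pulse
  interior smooth), activation U[0, 140] min, entry window 0 vs 45 min,
  200 cells.
* `valleys` — 20 domains of two persistent flanks (activation
  U[0, 140]) 1.8 Mb apart with a 1-Mb, 45%-efficient valley cluster
  between them whose activation (normal, mean 130, sd 30 min) has
  *rising* density through the last pulse, so each successive pulse
  labels more valley DNA — per-pulse signal is not cumulative, and only
  a rising initiation rate makes the minimum fill monotonically.
* `domino_null` / `domino_coupled` — 200 groups of five clusters 1.2 Mb
  apart on eight chromosomes; null draws each cluster's mean activation
  i.i.d. U[12, 35] min (sd 5), coupled propagates activation left to
  right with N(5, 2)-min delays from a N(12, 2) start, 60 cells.

Problem sizes were chosen so each preset simulates and analyses in a few
seconds on one core while leaving Monte-Carlo error well inside the
asserted tolerances.

## What the simulations do and do not show

The generator reproduces the features the pipeline measures — bump-like
cluster profiles at a controllable scale, fork-driven width growth,
late valley initiation, height order induced by activation order — under
Poisson counting noise and a uniform background. It does not model
mappability or GC structure in the background, copy-number or S/G2
contamination, chromatin-level correlation of origin efficiency, fork
stalling, or inter-experiment depth differences beyond RPM scaling.
Passing tests therefore demonstrate correctness of the algorithms and
their calibration on data satisfying the kinetic model's assumptions,
not robustness to every artefact of real libraries. Observed analysis
behaviours worth noting: a strong feature rising *between* two tracked
peaks pulls their wavelet positions outward by tens of kb (which is why
valley clusters that overtake their flanks break the ±100-kb tracking),
and the first-pulse wavelet width reads a few kb high when origin
spacing leaves interior gaps (the residual comb).

## Numerical choices and degenerate inputs

Percentiles are nearest-rank throughout the cutoff path. The Nelder-Mead
tolerances and restart policy are fixed (above); non-converged fits are
flagged and excluded rather than silently kept. Zero-variance samples
make t-statistics undefined: flagged, with p = 1 by convention.
All-zero tracks cannot be RPM-scaled (error). Fewer than 10 eligible
bins refuse a breakpoint fit; fewer than 10 late peaks refuse a cutoff
calibration with a pointer to a fallback. All simulator randomness flows
from one seeded generator recorded in the outputs; pipeline reruns with
the same config and seed are byte-identical.
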