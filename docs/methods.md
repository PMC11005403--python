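# Methods

## The two-mode initiation model

The simulator (`mfakit.sim`) represents bulk DNA from an asynchronous
population of chromosome copies on a single circular genome of length L.
Chromosome i is mid-replication with probability r (the replicating
fraction). A replicating chromosome carries one initiation event: at the
annotated origin with probability f, or at a site uniform on [0, L) with
probability 1 − f. The uniform placement models dispersed
recombination-dependent initiation, which starts replication at enough
distinct sites that no individual site is visible in a population-average
profile; whether real dispersed initiation is sequence-biased (e.g. toward
lesions or highly transcribed loci) is unknown, and uniformity is this
package's modelling assumption, not an observed fact.

Bidirectional, equal-speed forks from one initiation site imply the
replicated region is the circular arc of length pL centred on the site,
where p is replication progress. An asynchronous steady population with no
stated cell-cycle structure is modelled as p ~ Uniform(0, 1). Copy number
is 2 inside the arc, 1 outside. Expected copies per chromosome at
position x:

    E[c(x)] = 1 + r [ (1 − f)/2 + f (1 − 2 d(x)/L) ],

d(x) = circular distance to the origin. The uniform mode contributes a
constant (a random arc of uniform length covers any fixed point with
probability 1/2); the origin mode contributes the linear peak. The
genome-wide mean is 1 + r/2; the normalized (mean-1) profile depends on
(f, r) only through the contrast k = f r / (1 + r (1 − f)/2), an exact
non-identifiability that is property-tested and is why the f-estimator
requires r as an input.

Read sampling is Poisson per bin with mean λ × (summed copy number),
λ = reads per bin per chromosome copy. No GC, mappability, or
fragmentation bias is modelled, and there is no re-initiation, fork
stalling, or multi-fork replication: one initiation per replicating
chromosome, the simplest structure consistent with a single origin peak.
These omissions mean passing tests certify the statistical machinery, not
robustness to real-library artefacts.

Defaults mirror the organism scale studied: L = 2,010,000 bp with the
origin at 1,671,000 (a Thermococcus-like chromosome), N = 2,000
chromosomes, λ = 10 reads/bin/copy, bin 1 kb — a population sample deep
enough that per-bin relative noise is a few tenths of a percent, the
regime of a typical MFA sequencing run. One integer seed drives a single
`numpy` generator for the whole simulation; identical parameters reproduce
coverage bit-for-bit.

## MFA profiles

`bin_coverage` averages depth per bin (length-weighted for interval input;
a trailing partial bin is averaged over its actual width).
`normalize_profile` divides by the genome-wide mean bin value — the
"normalized average depth" convention — giving relative copy number with
mean exactly 1 (enforced to 1e−9). The mean rather than the median is used
deliberately; zero-coverage bins participate. Each sample is normalized
independently; no stationary-phase reference track is subtracted.

`gaussian_smooth` convolves with a discrete Gaussian truncated at ±4σ and
renormalized to unit sum (scipy's `gaussian_filter1d`). Circular
wrap-around is the default: the chromosome is circular, and a reference
origin at coordinate 0 (as in *P. furiosus*) would otherwise be split
across the two profile ends and flattened by edge padding. Linear
(reflect-padded) smoothing is available but distorts edges and can leave
the mean slightly off 1. Default σ = 10 bins (10 kb): small relative to
the ~L/2 peak width so the peak shape is preserved, large enough to
suppress Poisson bin noise by roughly a factor of 6. Circular smoothing
preserves the mean to machine precision and is shift-equivariant, both
property-tested against a brute-force convolution oracle.

## Peak calling

`detect_ori_peak` takes the apex as the maximum bin within a window
(default L/10) of the annotated origin, with ties broken toward the origin
then the lower coordinate. The baseline is the median of bins farther than
L/4 from the origin — a far-field median that is robust to leakage from a
broad peak; the peak-analyzer convention behind published area figures is
not documented anywhere, so absolute areas here are comparable only within
this package (relative and ordinal comparisons are the meaningful ones).
Height = apex − baseline; a peak is "detected" when height ≥ 0.05 relative
units, a threshold at which pure-RDR populations at the default depth
essentially never produce false detections (property-tested over seeds).
Bounds are the first bins on each side where the profile falls to the
baseline, clipped at the antipode; area integrates max(profile − baseline,
0) between the bounds by the trapezoidal rule (exact for the piecewise-
linear expected profile, and checked against per-bin summation to 1e−9).
Undetected peaks report height and area 0 rather than missing values so
time courses remain continuous.

`estimate_ori_fraction` inverts the model: k is measured as
apex / far_min − 1, where far_min is the profile minimum within L/8 of the
antipode (the model's trough; the far-half *median* used for the detection
baseline sits above the trough and would bias the inversion), then
f̂ = k (1 + r/2) / (r (1 + k/2)), clipped to [0, 1]. The estimator accepts
an undetected peak (k ≈ 0 ⇒ f̂ ≈ 0): a flat profile is informative, not
missing data. r = 0 is rejected as f is then unidentifiable.

## qPCR ploidy

Standard curves are ordinary least squares of Cq on log10(copies) over a
10-fold dilution series (the synthetic fixture spans 10^3–10^9 copies,
reading the assay's stated range as seven decades); amplification
efficiency E = 10^(−1/slope) − 1, an exact bijection on slope < 0.
Sample copies = 10^((Cq − intercept)/slope), with replicate Cq values
averaged **before** inversion — inverting each replicate first and
averaging copies is biased upward because the inverse is convex. Ploidy =
copies per mL / cells per mL, with first-order SD propagation; cell counts
are treated as error-free unless an SD is supplied. Sub-unity ploidy is
allowed and flagged rather than rejected: early-time-point samples can
lose cells and DNA during harvesting, and the flag preserves that signal.
No correction for DNA-extraction efficiency is applied. A reported ploidy
value is the mean of three independent synthetic experiments, each with
its own standard curve (triplicate wells) and triplicate sample reactions
— the replication structure under which the package's recovery tests are
stated. Per-well Cq noise of SD 0.15 then yields three-experiment
estimates within 10% of truth in ≈99% of studies.

## Growth kinetics

Doubling time is ln(2)/slope from a least-squares fit of ln(density) vs
time, reported in minutes with a delta-method SE from the slope SE. The
ln-linear regression uses every point in the window, unlike per-interval
doubling counts. When no window is given, the contiguous span of ≥ 4
points maximizing R² (ties: more points, then earlier) is used — on
lag/log/stationary curves this lands inside the exponential phase. Ratios
of doubling times propagate SEs to first order,
SE = ratio·sqrt((se_a/τ_a)² + (se_b/τ_b)²), which matches a Monte-Carlo
oracle to a few percent at the SEs involved. Non-positive slopes (no net
growth) are an error, not a NaN.

## Densitometry

Band volumes are corrected for loading by the total-protein (stain-free)
ratio — factor = reference total / lane total; normalized volume = band ×
factor — making the result invariant to uniform loading changes (property-
tested), then expressed as percent of the reference lane. Replicate blots
are summarized as mean ± SD over ≥ 3 experiments. Background subtraction
is assumed done by the imaging software; significance testing of fold
changes is out of scope.

## Pipeline and formats

Depth input is text: 4-column bedGraph or 2-column (position, depth) TSV,
0-based half-open, single chromosome only (multi-contig input is rejected
with a clear message — the organisms modelled have one chromosome).
Intervals crossing the origin of coordinates are accepted only with an
explicit wrap flag on circular genomes. All output coordinates are 0-based
bin starts — note that published origin positions are usually quoted
1-based. Pipeline outputs (per-sample MFA TSV/bedGraph, time-course CSV,
run log) carry the package version and a config hash so any file can be
regenerated; identical configs produce byte-identical outputs.

## Test and verification sizes

Simulation-based tests run at the defaults above (2,000 chromosomes,
2,010 bins), with 5–20 replicate populations per condition and 10-seed
detection sweeps; qPCR recovery uses 100 synthetic studies and growth-fit
recovery 200 noisy curves. Per-bin agreement between the simulator and
the closed-form expectation is asserted at 3 analytic SEs; across ~2,000
bins a correct implementation still leaves ~0.3% of bins outside 3 SE by
chance, so the assertion is that ≥ 99% of bins fall within 3 SE and none
beyond 4–5 SE, the statistical reading of a per-bin 3σ check.

## Known limitations

- One initiation per chromosome; no multi-fork or re-initiation dynamics,
  so the model cannot produce compound origin peaks.
- Uniform RDR site placement is an assumption (see above).
- No sequencing bias model; profiles from real libraries need upstream
  GC/mappability correction before quantitative f̂ inversion.
- The estimator requires r externally (e.g. from flow cytometry or run-out
  experiments); profile shape alone cannot separate f from r.
- Absolute peak areas are convention-dependent; compare only within one
  baseline convention.
- The anomalous convex dip reported at the origin under high hydrostatic
  pressure in one strain/condition is not modelled.
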