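# mfakit

Marker frequency analysis (MFA) of DNA replication initiation in polyploid
archaea, built around the biology of *Thermococcus barophilus* and its
relatives: a single circular chromosome, one annotated origin (*oriC*), and
two cooperating initiation modes — origin firing at *oriC* and dispersed,
recombination-dependent replication (RDR) mediated by the recombinase RadA.

`mfakit` is for microbiologists and genomicists who quantify origin usage
from bulk DNA sequencing across growth phases. It provides:

- a **generative simulator** of an asynchronous replicating population with
  a known mixture of *oriC*-initiated and dispersed initiation, plus its
  closed-form expected-coverage oracle;
- the **MFA pipeline**: depth track → binned coverage → normalization to
  relative copy number (genome-wide mean 1) → circular Gaussian smoothing;
- ***oriC* peak quantification**: apex, height above a far-field baseline,
  integrated area, and time-course summaries;
- **absolute qPCR ploidy**: standard curves, amplification efficiency,
  chromosomes per cell;
- **doubling-time fits** from cell-count kinetics and between-strain ratios;
- **western-blot densitometry** with total-protein loading normalization.

## The model

Each chromosome in a population of N copies is independently
mid-replication with probability *r*. A replicating chromosome initiated at
*oriC* with probability *f*, or at a uniformly random site with probability
1 − *f* (dispersed RDR initiation). Bidirectional forks have replicated a
fraction *p* ~ Uniform(0, 1) of the genome, so copy number is 2 on the
circular arc of length *pL* centred on the initiation site and 1 elsewhere.
The expected copy number at position *x* is

    E[c(x)] = 1 + r · [ (1 − f)/2 + f · (1 − 2 d(x)/L) ]

with d(x) the circular distance from *x* to *oriC*. Origin firing produces
a linear peak at *oriC* of relative contrast k = f·r / (1 + r(1 − f)/2);
dispersed initiation only lifts the flat background — which is why an
origin-deleted strain shows no MFA peak even though it replicates. Reads
per bin are Poisson with mean proportional to summed copy number. Given
*r*, the peak-to-trough ratio inverts to an estimate of *f*:
f̂ = k(1 + r/2) / (r(1 + k/2)); *f* and *r* are not jointly identifiable
from profile shape alone.

## Worked example

Simulate a population of 2,000 chromosomes on a 2.01-Mb circular genome
with *oriC* at 1,671,000 bp, 60% of chromosomes replicating, 80% of
initiations at *oriC*, then quantify the origin peak:

```sh
mfakit simulate --length 2010000 --ori 1671000 --name Tbar \
    --n-chrom 2000 --r 0.6 --f 0.8 --depth 10 --seed 7 --out simdemo
mfakit peaks --in simdemo/coverage.bedgraph \
    --genome-length 2010000 --ori 1671000 --name Tbar --sigma 10
```

prints

```
apex_position=1671000 apex_value=1.1784 baseline=0.9048 height=0.2736 area=212178.7 detected=True
```

The apex lands on the annotated origin; the smoothed relative copy number
there is 1.178 against a far-field baseline of 0.905, a peak height of
0.274 relative units and an integrated area of ~2.1 × 10^5 relative
units·bp. Inverting the peak contrast with the known replicating fraction
(`estimate_ori_fraction(peak, r=0.6)`) returns `f_hat = 0.783`, recovering
the simulated 80% origin usage.

The same operations are available as a library (`mfakit.simulate_population`,
`mfakit.detect_ori_peak`, ...) and as further CLI verbs: `mfa`,
`timecourse`, `ploidy`, `growth`, `blot`, and `run` (a YAML-configured
pipeline over a sample manifest).

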