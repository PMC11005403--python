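"""Generative model of a replicating polyploid cell population.

The simulator emulates bulk DNA sequencing of an asynchronous population in
which every cell carries many chromosome copies (Thermococcales are highly
polyploid).  Each chromosome is independently mid-replication with
probability ``r``; a replicating chromosome initiated either at oriC (with
probability ``f``, origin-dependent initiation) or at a uniformly random
site (with probability ``1 - f``, modelling dispersed recombination-
dependent replication, RDR).  Bidirectional forks from a single initiation
site have replicated a fraction ``p ~ Uniform(0, 1)`` of the genome, so the
replicated region is the circular arc of length ``p * L`` centred on the
initiation site; copy number is 2 inside the arc and 1 outside.  Read
counts per bin are Poisson with mean proportional to the summed copy number
of the bin over all chromosomes.

The closed-form expectation of per-chromosome copy number at position x is

    E[c(x)] = 1 + r * [ (1 - f) / 2 + f * (1 - 2 d(x) / L) ]

where d(x) is the circular distance from x to oriC (uniform initiation
covers any fixed point with probability E[p] = 1/2; oriC initiation covers
x iff p >= 2 d(x) / L).  This expectation is the oracle against which the
Monte-Carlo simulator is validated, and its shape is what marker frequency
analysis measures: a peak at oriC whose relative height grows with f * r,
and a flat profile when initiation is dispersed (f = 0).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .genome import GenomeDef, circular_distance
from .mfa import CoverageProfile


@dataclass(frozen=True)
class SimParams:
    """Parameters of the two-mode initiation population model.

    ``mean_depth_per_copy`` is the expected number of reads per (full-width)
    bin contributed by one chromosome copy.
    """

    genome: GenomeDef
    n_chromosomes: int
    replicating_fraction: float  # r, fraction of chromosomes mid-replication
    ori_fraction: float          # f, P(initiation at oriC | replicating)
    mean_depth_per_copy: float   # lambda, reads per bin per chromosome copy
    bin_size: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        r, f = self.replicating_fraction, self.ori_fraction
        lam = self.mean_depth_per_copy
        if not (np.isfinite(r) and 0.0 <= r <= 1.0):
            raise ValueError(f"replicating_fraction must be in [0, 1], got {r}")
        if not (np.isfinite(f) and 0.0 <= f <= 1.0):
            raise ValueError(f"ori_fraction must be in [0, 1], got {f}")
        if not (np.isfinite(lam) and lam > 0):
            raise ValueError(f"mean_depth_per_copy must be > 0, got {lam}")
        if int(self.n_chromosomes) < 1:
            raise ValueError(f"n_chromosomes must be >= 1, got {self.n_chromosomes}")
        if int(self.bin_size) < 1:
            raise ValueError(f"bin_size must be >= 1, got {self.bin_size}")
        if self.genome.length < 2 * self.bin_size:
            raise ValueError("genome length must be at least two bins")


@dataclass(frozen=True)
class ReplicationState:
    """Replication status of one chromosome copy.

    For a replicating chromosome the replicated arc is
    ``[init_site - p*L/2, init_site + p*L/2)`` modulo L; ``arc_start`` is the
    wrapped left endpoint and ``arc_length = p * L``.
    """

    replicating: bool
    init_site: Optional[float] = None
    progress: Optional[float] = None
    arc_start: Optional[float] = None
    arc_length: Optional[float] = None


@dataclass(frozen=True)
class SimTruth:
    """A simulated population: parameters, per-chromosome ground truth, and
    the Poisson-sampled coverage track."""

    params: SimParams
    states: Sequence[ReplicationState] = field(repr=False)
    coverage: CoverageProfile = field(repr=False)


def expected_copy_number(params: SimParams, position) -> np.ndarray | float:
    """Expected copies per chromosome at ``position`` under the two-mode model.

    Maximal (up to ``1 + r (1 + f) / 2``) at oriC, minimal at the antipode;
    genome-wide mean is ``1 + r / 2``.  Accepts scalar or array positions.
    """
    L = params.genome.length
    pos = np.asarray(position, dtype=float)
    if np.any(pos < 0) or np.any(pos >= L):
        raise ValueError(f"position outside [0, {L})")
    r, f = params.replicating_fraction, params.ori_fraction
    d = circular_distance(pos, params.genome.ori_position, L)
    value = 1.0 + r * ((1.0 - f) / 2.0 + f * (1.0 - 2.0 * d / L))
    return float(value) if np.isscalar(position) else value


def expected_profile(params: SimParams) -> np.ndarray:
    """Expected per-chromosome copy number evaluated at every bin start."""
    starts = np.arange(_n_bins(params)) * float(params.bin_size)
    return expected_copy_number(params, starts)


def _n_bins(params: SimParams) -> int:
    return math.ceil(params.genome.length / params.bin_size)


def _bin_widths(length: int, bin_size: int) -> np.ndarray:
    n = math.ceil(length / bin_size)
    widths = np.full(n, float(bin_size))
    widths[-1] = length - (n - 1) * bin_size
    return widths


def _covered_length_per_bin(starts: np.ndarray, lengths: np.ndarray,
                            genome_length: int, bin_size: int) -> np.ndarray:
    """Total bp of replicated-arc overlap per bin, summed over arcs.

    Wrapping arcs are split into at most two linear intervals, then overlap
    with every bin is computed by interval clipping.
    """
    n = math.ceil(genome_length / bin_size)
    cov = np.zeros(n)
    if starts.size == 0:
        return cov
    ends = starts + lengths
    wraps = ends > genome_length
    lo = np.concatenate([starts, np.zeros(wraps.sum())])
    hi = np.concatenate([np.minimum(ends, genome_length),
                         ends[wraps] - genome_length])
    w = float(bin_size)
    b0 = np.minimum((lo // w).astype(np.intp), n - 1)
    b1 = np.minimum((hi // w).astype(np.intp), n - 1)
    same = b0 == b1
    np.add.at(cov, b0[same], hi[same] - lo[same])
    m = ~same
    np.add.at(cov, b0[m], (b0[m] + 1) * w - lo[m])
    frac_hi = hi[m] - b1[m] * w
    np.add.at(cov, b1[m], frac_hi)
    # full interior bins b0+1 .. b1-1 via a difference array
    diff = np.zeros(n + 1)
    np.add.at(diff, b0[m] + 1, w)
    np.add.at(diff, b1[m], -w)
    cov += np.cumsum(diff)[:n]
    return cov


def simulate_population(params: SimParams) -> SimTruth:
    """Draw one population and its Poisson-sampled coverage track.

    Identical parameters (including the seed) reproduce the output
    bit-for-bit.  Reads per bin are Poisson with mean
    ``lambda * (total copy number of the bin) * (bin width / bin_size)``;
    a trailing partial bin is scaled by its actual width.
    """
    g = params.genome
    L = float(g.length)
    N = int(params.n_chromosomes)
    rng = np.random.default_rng(params.seed)

    replicating = rng.random(N) < params.replicating_fraction
    at_ori = rng.random(N) < params.ori_fraction
    init = np.where(at_ori, float(g.ori_position), rng.uniform(0.0, L, N))
    progress = rng.uniform(0.0, 1.0, N)

    arc_len = progress * L
    arc_start = (init - arc_len / 2.0) % L

    rep = replicating
    cov_len = _covered_length_per_bin(arc_start[rep], arc_len[rep],
                                      g.length, params.bin_size)
    widths = _bin_widths(g.length, params.bin_size)
    # summed copy number per bin: every chromosome contributes 1, arcs add 1
    copy_per_bin = N + cov_len / widths
    mean_reads = params.mean_depth_per_copy * copy_per_bin * (widths / params.bin_size)
    counts = rng.poisson(mean_reads).astype(float)
    # width-correct the trailing partial bin so values are comparable depths
    counts *= params.bin_size / widths

    states = [
        ReplicationState(
            replicating=bool(rep[i]),
            init_site=float(init[i]) if rep[i] else None,
            progress=float(progress[i]) if rep[i] else None,
            arc_start=float(arc_start[i]) if rep[i] else None,
            arc_length=float(arc_len[i]) if rep[i] else None,
        )
        for i in range(N)
    ]
    coverage = CoverageProfile(genome=g, bin_size=int(params.bin_size),
                               values=counts)
    return SimTruth(params=params, states=states, coverage=coverage)


def write_truth(sim: SimTruth, path) -> None:
    """Persist a simulation to ``path`` (a directory): the coverage track as
    ``coverage.bedgraph`` and the parameters as ``params.txt`` (key=value).

    Per-chromosome states are not serialized; they are reproducible from
    the recorded seed via :func:`simulate_population`.
    """
    out = Path(path)
    try:
        out.mkdir(parents=True, exist_ok=True)
        p = sim.params
        meta = {
            "genome_name": p.genome.name,
            "genome_length": p.genome.length,
            "ori_position": p.genome.ori_position,
            "circular": int(p.genome.circular),
            "n_chromosomes": p.n_chromosomes,
            "replicating_fraction": repr(p.replicating_fraction),
            "ori_fraction": repr(p.ori_fraction),
            "mean_depth_per_copy": repr(p.mean_depth_per_copy),
            "bin_size": p.bin_size,
            "seed": p.seed,
        }
        with open(out / "params.txt", "w") as fh:
            for k, v in meta.items():
                fh.write(f"{k}={v}\n")
        sim.coverage.to_bedgraph(out / "coverage.bedgraph")
    except OSError as exc:
        raise OSError(f"cannot write simulation truth under {out}: {exc}") from exc


def read_truth(path) -> SimTruth:
    """Load a simulation written by :func:`write_truth` and regenerate its
    per-chromosome states from the recorded seed."""
    out = Path(path)
    meta: dict[str, str] = {}
    try:
        for line in (out / "params.txt").read_text().splitlines():
            if line.strip():
                k, _, v = line.partition("=")
                meta[k] = v
    except OSError as exc:
        raise OSError(f"cannot read simulation truth under {out}: {exc}") from exc
    genome = GenomeDef(name=meta["genome_name"], length=int(meta["genome_length"]),
                       ori_position=int(meta["ori_position"]),
                       circular=bool(int(meta["circular"])))
    params = SimParams(
        genome=genome,
        n_chromosomes=int(meta["n_chromosomes"]),
        replicating_fraction=float(meta["replicating_fraction"]),
        ori_fraction=float(meta["ori_fraction"]),
        mean_depth_per_copy=float(meta["mean_depth_per_copy"]),
        bin_size=int(meta["bin_size"]),
        seed=int(meta["seed"]),
    )
    regenerated = simulate_population(params)
    stored = CoverageProfile.from_bedgraph(out / "coverage.bedgraph", genome)
    return SimTruth(params=params, states=regenerated.states, coverage=stored)
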