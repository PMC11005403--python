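"""Coverage binning, normalization, and Gaussian smoothing.

Marker frequency analysis (MFA) reads relative replication activity out of
bulk sequencing depth: actively replicating populations over-represent loci
near active origins.  The pipeline here is depth track -> per-bin mean
depth (:func:`bin_coverage`) -> relative copy number with genome-wide mean
exactly 1 (:func:`normalize_profile`) -> smoothed profile
(:func:`gaussian_smooth`, circular by default because the chromosome is
circular and one reference origin sits at coordinate 0).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage


@dataclass(frozen=True)
class CoverageProfile:
    """Binned read depth over one chromosome.

    ``values[j]`` is the mean depth over bin ``[j*bin_size, (j+1)*bin_size)``
    (the trailing bin may be narrower; its value is the mean over its actual
    width).
    """

    genome: "GenomeDef"  # noqa: F821 - forward ref, avoids import cycle
    bin_size: int
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        n_expected = math.ceil(self.genome.length / self.bin_size)
        if vals.ndim != 1 or vals.size != n_expected:
            raise ValueError(
                f"expected {n_expected} bins for length {self.genome.length} "
                f"at bin_size {self.bin_size}, got {vals.size}"
            )
        if np.any(vals < 0) or not np.all(np.isfinite(vals)):
            raise ValueError("coverage values must be finite and non-negative")

    @property
    def n_bins(self) -> int:
        return self.values.size

    @property
    def bin_starts(self) -> np.ndarray:
        return np.arange(self.n_bins) * self.bin_size

    def to_bedgraph(self, path) -> None:
        _write_bedgraph(path, self.genome, self.bin_size, self.values)

    @classmethod
    def from_bedgraph(cls, path, genome: "GenomeDef") -> "CoverageProfile":  # noqa: F821
        bin_size, values = _read_binned_bedgraph(path, genome)
        return cls(genome=genome, bin_size=bin_size, values=values)


@dataclass(frozen=True)
class MFAProfile:
    """Normalized relative-copy-number track (genome-wide mean 1).

    ``sigma`` records the Gaussian smoothing bandwidth in bins (0 =
    unsmoothed).  Linear (non-circular) smoothing may leave the mean
    slightly off 1 near the ends; circular smoothing preserves it exactly.
    """

    genome: "GenomeDef"  # noqa: F821
    bin_size: int
    values: np.ndarray = field(repr=False)
    sigma: float = 0.0

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        if np.any(vals < 0) or not np.all(np.isfinite(vals)):
            raise ValueError("MFA values must be finite and non-negative")
        if self.sigma < 0:
            raise ValueError(f"sigma must be >= 0, got {self.sigma}")

    @property
    def n_bins(self) -> int:
        return self.values.size

    @property
    def bin_starts(self) -> np.ndarray:
        return np.arange(self.n_bins) * self.bin_size

    def to_tsv(self, path, header_lines=()) -> None:
        with open(path, "w") as fh:
            for line in header_lines:
                fh.write(f"# {line}\n")
            fh.write("bin_start\tmfa_value\n")
            for start, v in zip(self.bin_starts, self.values):
                fh.write(f"{int(start)}\t{float(v)!r}\n")

    def to_bedgraph(self, path) -> None:
        _write_bedgraph(path, self.genome, self.bin_size, self.values)


def bin_coverage(depth_track, genome, bin_size: int) -> CoverageProfile:
    """Aggregate a depth track into per-bin mean depths.

    ``depth_track`` is either a 1-D array of per-position depths (length L)
    or an interval track — a ``(start, end, value)`` DataFrame or an (n, 3)
    array with 0-based half-open coordinates.  Interval input is
    length-weighted; positions not covered by any interval count as depth 0.
    """
    if bin_size < 1:
        raise ValueError(f"bin_size must be >= 1, got {bin_size}")
    L = genome.length
    if L < 2 * bin_size:
        raise ValueError("genome shorter than two bins; reduce bin_size")

    if isinstance(depth_track, pd.DataFrame):
        arr = depth_track[["start", "end", "value"]].to_numpy(dtype=float)
        return _bin_intervals(arr, genome, bin_size)
    arr = np.asarray(depth_track, dtype=float)
    if arr.ndim == 1:
        if arr.size != L:
            raise ValueError(
                f"per-position track has {arr.size} values, genome length is {L}"
            )
        if np.any(arr < 0):
            raise ValueError("negative depth values")
        return _bin_intervals(
            np.column_stack([np.arange(L), np.arange(1, L + 1), arr]),
            genome, bin_size,
        )
    if arr.ndim == 2 and arr.shape[1] == 3:
        return _bin_intervals(arr, genome, bin_size)
    raise ValueError("depth_track must be 1-D per-position or (n, 3) intervals")


def _bin_intervals(intervals: np.ndarray, genome, bin_size: int) -> CoverageProfile:
    L = genome.length
    n = math.ceil(L / bin_size)
    if intervals.size:
        starts, ends, vals = intervals.T
        if np.any(vals < 0):
            raise ValueError("negative depth values")
        if np.any(starts < 0) or np.any(ends > L):
            raise ValueError(f"interval coordinates outside [0, {L})")
        if np.any(ends <= starts):
            raise ValueError("intervals must satisfy start < end")
        order = np.argsort(starts, kind="stable")
        if np.any(starts[order][1:] < ends[order][:-1]):
            raise ValueError("overlapping intervals define contradictory depths")
    # accumulate depth*bp per bin via edge clipping, then divide by bin width
    total = np.zeros(n)
    if intervals.size:
        edges = np.arange(n + 1) * float(bin_size)
        edges[-1] = L
        lo = np.searchsorted(edges, starts, side="right") - 1
        hi = np.searchsorted(edges, ends, side="left") - 1
        for s, e, v, b0, b1 in zip(starts, ends, vals, lo, hi):
            if b0 == b1:
                total[b0] += v * (e - s)
            else:
                total[b0] += v * (edges[b0 + 1] - s)
                total[b1] += v * (e - edges[b1])
                if b1 > b0 + 1:
                    total[b0 + 1:b1] += v * np.diff(edges[b0 + 1:b1 + 1])
    widths = np.full(n, float(bin_size))
    widths[-1] = L - (n - 1) * bin_size
    return CoverageProfile(genome=genome, bin_size=bin_size, values=total / widths)


def normalize_profile(cov: CoverageProfile) -> MFAProfile:
    """Divide each bin by the genome-wide mean bin value.

    The output is the relative copy number track used throughout MFA; its
    arithmetic mean is exactly 1.  All-zero coverage carries no replication
    signal and is rejected.
    """
    mean = float(np.mean(cov.values))
    if mean <= 0.0:
        raise ValueError("all-zero coverage: no signal to normalize")
    return MFAProfile(genome=cov.genome, bin_size=cov.bin_size,
                      values=cov.values / mean, sigma=0.0)


def gaussian_smooth(mfa: MFAProfile, sigma: float, circular: bool = True) -> MFAProfile:
    """Convolve with a discrete Gaussian kernel (truncated at +/- 4 sigma,
    normalized to unit sum).

    ``circular=True`` wraps across the coordinate origin, appropriate for a
    circular chromosome, and preserves the mean exactly.  Linear smoothing
    (reflected edges) is available but distorts values near the two ends of
    the coordinate system — relevant when the origin peak sits at position
    0, as in *P. furiosus*.  ``sigma`` is in bins; ``sigma=0`` returns the
    profile unchanged.
    """
    if sigma < 0:
        raise ValueError(f"sigma must be >= 0, got {sigma}")
    if sigma == 0:
        return replace(mfa, sigma=0.0)
    mode = "wrap" if circular else "reflect"
    smoothed = ndimage.gaussian_filter1d(mfa.values, sigma=float(sigma),
                                         mode=mode, truncate=4.0)
    return MFAProfile(genome=mfa.genome, bin_size=mfa.bin_size,
                      values=smoothed, sigma=float(sigma))


def _write_bedgraph(path, genome, bin_size: int, values: np.ndarray) -> None:
    try:
        with open(path, "w") as fh:
            for j, v in enumerate(values):
                start = j * bin_size
                end = min(start + bin_size, genome.length)
                fh.write(f"{genome.name}\t{start}\t{end}\t{float(v)!r}\n")
    except OSError as exc:
        raise OSError(f"cannot write bedGraph {path}: {exc}") from exc


def _read_binned_bedgraph(path, genome):
    starts, ends, vals = [], [], []
    try:
        with open(path) as fh:
            for ln, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.split("\t")
                if len(parts) != 4:
                    raise ValueError(f"{path}:{ln}: expected 4 bedGraph columns")
                chrom, s, e, v = parts
                if chrom != genome.name:
                    raise ValueError(
                        f"{path}:{ln}: chromosome {chrom!r} does not match "
                        f"genome {genome.name!r}"
                    )
                starts.append(int(s)); ends.append(int(e)); vals.append(float(v))
    except OSError as exc:
        raise OSError(f"cannot read bedGraph {path}: {exc}") from exc
    if not starts:
        raise ValueError(f"{path}: empty bedGraph")
    bin_size = ends[0] - starts[0]
    return bin_size, np.asarray(vals, dtype=float)
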