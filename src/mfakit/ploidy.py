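"""Absolute qPCR quantification of chromosome copy number per cell.

Ploidy is measured by quantifying a single-copy chromosomal locus (here the
radA locus) against a plasmid standard curve: Cq is linear in log10 of
template copies, so a 10-fold dilution series yields a line whose slope
gives the amplification efficiency, E = 10^(-1/slope) - 1 (slope
-3.3219 = perfect doubling, E = 1).  Copies per mL of culture divided by
cells per mL (Thoma-chamber counts) gives chromosomes per cell.

Highly polyploid Thermococcales carry on the order of 10 chromosome copies
per cell; the ploidy estimate here follows the experimental design of
triplicate reactions per sample and averaging over independent biological
experiments.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

#: Cq decrease per 10-fold template increase under perfect doubling chemistry
PERFECT_SLOPE = -1.0 / np.log10(2.0)  # -3.3219...


@dataclass(frozen=True)
class StandardCurve:
    """Least-squares dilution-series calibration: Cq = slope*log10(copies) + intercept."""

    slope: float
    intercept: float
    r_squared: float
    efficiency: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.slope):
            raise ValueError("non-finite standard-curve slope")


@dataclass(frozen=True)
class QPCRSample:
    """One quantified sample: replicate Cq values and derived quantities."""

    label: str
    cq_replicates: Tuple[float, ...]
    cq_mean: float
    cq_sd: float
    copies: float                 # per reaction
    copies_per_ml: float
    cells_per_ml: float
    chromosomes_per_cell: float
    chromosomes_per_cell_sd: float
    sub_unity: bool               # flag: estimate below one copy per cell


def fit_standard_curve(dilution_copies: Sequence[float],
                       cq: Sequence[float]) -> StandardCurve:
    """Fit the dilution series and derive the amplification efficiency.

    Requires at least three dilution points with positive copy numbers and
    non-constant log10(copies).
    """
    copies = np.asarray(dilution_copies, dtype=float)
    cq_arr = np.asarray(cq, dtype=float)
    if copies.size != cq_arr.size:
        raise ValueError("dilution_copies and cq must have equal length")
    if copies.size < 3:
        raise ValueError("standard curve needs at least 3 dilution points")
    if np.any(copies <= 0):
        raise ValueError("dilution copy numbers must be positive")
    x = np.log10(copies)
    if np.ptp(x) == 0:
        raise ValueError("degenerate dilution series: all copy numbers equal")
    fit = stats.linregress(x, cq_arr)
    slope = float(fit.slope)
    if slope == 0:
        raise ValueError("flat standard curve: no amplification signal")
    efficiency = 10.0 ** (-1.0 / slope) - 1.0
    return StandardCurve(slope=slope, intercept=float(fit.intercept),
                         r_squared=float(fit.rvalue) ** 2,
                         efficiency=float(efficiency))


def efficiency_to_slope(efficiency: float) -> float:
    """Inverse of ``E = 10^(-1/slope) - 1`` (exact bijection on slope < 0)."""
    if efficiency <= 0:
        raise ValueError("efficiency must be positive")
    return -1.0 / np.log10(1.0 + efficiency)


def copies_from_cq(curve: StandardCurve, cq: float) -> float:
    """Invert the standard curve: copies = 10^((cq - intercept) / slope).

    Monotonically decreasing in Cq for a valid (negative-slope) curve.
    """
    if curve.slope >= 0:
        raise ValueError("standard curve slope must be negative to invert")
    return float(10.0 ** ((cq - curve.intercept) / curve.slope))


def predict_cq(curve: StandardCurve, copies: float) -> float:
    if copies <= 0:
        raise ValueError("copies must be positive")
    return float(curve.slope * np.log10(copies) + curve.intercept)


def chromosomes_per_cell(copies_per_ml: float, cells_per_ml: float,
                         copies_sd: float = 0.0,
                         cells_sd: float = 0.0) -> Tuple[float, float]:
    """Ploidy as copies/cells with first-order SD propagation.

    Cell counts are treated as error-free unless ``cells_sd`` is supplied.
    """
    if cells_per_ml <= 0:
        raise ValueError(f"cells_per_ml must be positive, got {cells_per_ml}")
    ploidy = copies_per_ml / cells_per_ml
    rel = 0.0
    if copies_per_ml > 0:
        rel += (copies_sd / copies_per_ml) ** 2
    rel += (cells_sd / cells_per_ml) ** 2
    return float(ploidy), float(abs(ploidy) * np.sqrt(rel))


def quantify_sample(curve: StandardCurve, label: str,
                    cq_replicates: Sequence[float], cells_per_ml: float,
                    volume_equivalent_ml: float = 1.0) -> QPCRSample:
    """Quantify one sample: average replicate Cq values, invert the curve,
    scale to culture volume, and express as chromosomes per cell.

    Replicates are averaged on the Cq scale before inversion (inverting each
    replicate and averaging copies is biased upward because the inverse is
    convex).  ``volume_equivalent_ml`` is the culture volume whose DNA one
    reaction contains.  Sub-unity ploidy is allowed but flagged — early
    time points can lose cells/DNA during harvesting.
    """
    reps = np.asarray(cq_replicates, dtype=float)
    if reps.size < 1:
        raise ValueError("need at least one Cq replicate")
    if volume_equivalent_ml <= 0:
        raise ValueError("volume_equivalent_ml must be positive")
    cq_mean = float(reps.mean())
    cq_sd = float(reps.std(ddof=1)) if reps.size > 1 else 0.0
    copies = copies_from_cq(curve, cq_mean)
    copies_per_ml = copies / volume_equivalent_ml
    # delta-method SD of copies from the Cq-mean SD
    se_cq = cq_sd / np.sqrt(reps.size) if reps.size > 1 else 0.0
    copies_sd = copies_per_ml * np.log(10.0) * se_cq / abs(curve.slope)
    ploidy, ploidy_sd = chromosomes_per_cell(copies_per_ml, cells_per_ml,
                                             copies_sd=copies_sd)
    return QPCRSample(label=label, cq_replicates=tuple(map(float, reps)),
                      cq_mean=cq_mean, cq_sd=cq_sd, copies=float(copies),
                      copies_per_ml=float(copies_per_ml),
                      cells_per_ml=float(cells_per_ml),
                      chromosomes_per_cell=ploidy,
                      chromosomes_per_cell_sd=ploidy_sd,
                      sub_unity=bool(ploidy < 1.0))


def quantify_table(standards: pd.DataFrame, samples: pd.DataFrame,
                   volume_equivalent_ml: float = 1.0) -> pd.DataFrame:
    """Run the full quantification on CSV-shaped tables.

    ``standards`` needs columns (copies, cq); ``samples`` needs (sample,
    cells_per_ml) plus one or more cq columns (cq1..cqN or cq).  Returns one
    row per sample with copies, ploidy, and SD.
    """
    curve = fit_standard_curve(standards["copies"].to_numpy(),
                               standards["cq"].to_numpy())
    cq_cols = [c for c in samples.columns if c == "cq" or c.startswith("cq")]
    if not cq_cols:
        raise ValueError("samples table has no cq columns")
    rows = []
    for _, row in samples.iterrows():
        reps = [row[c] for c in cq_cols if np.isfinite(row[c])]
        q = quantify_sample(curve, str(row["sample"]), reps,
                            float(row["cells_per_ml"]),
                            volume_equivalent_ml=volume_equivalent_ml)
        rows.append({
            "sample": q.label, "cq_mean": q.cq_mean, "cq_sd": q.cq_sd,
            "copies": q.copies, "copies_per_ml": q.copies_per_ml,
            "chromosomes_per_cell": q.chromosomes_per_cell,
            "sd": q.chromosomes_per_cell_sd, "sub_unity": q.sub_unity,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# synthetic qPCR experiments

#: 10-fold plasmid dilution series spanning 10^3 to 10^9 copies
DILUTION_SERIES = tuple(10.0 ** k for k in range(3, 10))


def simulate_qpcr_experiment(true_ploidy: float, cells_per_ml: float,
                             efficiency: float = 0.90,
                             intercept: float = 38.0,
                             cq_sd: float = 0.15,
                             n_replicates: int = 3,
                             volume_equivalent_ml: float = 1e-3,
                             rng: Optional[np.random.Generator] = None,
                             label: str = "sample"):
    """Generate one synthetic qPCR experiment with known ground truth.

    Emulates the assay design: a 7-decade plasmid dilution series run in
    triplicate, plus one culture sample run in ``n_replicates``; per-well Cq
    noise is Gaussian with SD ``cq_sd``.  Returns ``(standards, samples)``
    DataFrames shaped for :func:`quantify_table`.
    """
    rng = np.random.default_rng() if rng is None else rng
    slope = efficiency_to_slope(efficiency)
    std_copies = np.repeat(DILUTION_SERIES, 3)
    std_cq = (slope * np.log10(std_copies) + intercept
              + rng.normal(0.0, cq_sd, std_copies.size))
    standards = pd.DataFrame({"copies": std_copies, "cq": std_cq})

    true_copies = true_ploidy * cells_per_ml * volume_equivalent_ml
    sample_cq = (slope * np.log10(true_copies) + intercept
                 + rng.normal(0.0, cq_sd, n_replicates))
    samples = pd.DataFrame({
        "sample": [label],
        **{f"cq{i + 1}": [sample_cq[i]] for i in range(n_replicates)},
        "cells_per_ml": [cells_per_ml],
    })
    return standards, samples


def estimate_ploidy_study(true_ploidy: float, cells_per_ml: float,
                          n_experiments: int = 3,
                          rng: Optional[np.random.Generator] = None,
                          **kwargs) -> float:
    """Mean ploidy over independent synthetic experiments, each with its own
    standard curve and triplicate sample — the study design under which
    reported ploidy values are averages of three experiments."""
    rng = np.random.default_rng() if rng is None else rng
    vol = kwargs.pop("volume_equivalent_ml", 1e-3)
    estimates = []
    for _ in range(n_experiments):
        standards, samples = simulate_qpcr_experiment(
            true_ploidy, cells_per_ml, rng=rng,
            volume_equivalent_ml=vol, **kwargs)
        out = quantify_table(standards, samples, volume_equivalent_ml=vol)
        estimates.append(float(out["chromosomes_per_cell"].iloc[0]))
    return float(np.mean(estimates))
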