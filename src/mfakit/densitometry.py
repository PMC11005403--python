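"""Western-blot densitometry arithmetic.

Band volumes (chemiluminescence intensities) are corrected for lane loading
using total-protein stain-free imaging: each lane's band volume is scaled
by ``reference_total / lane_total`` so that unequal loading cancels, then
expressed as a percentage of the reference lane.  Replicate blots are
summarized as mean +/- SD across experiments.  Inputs are already-
quantified volumes; image processing happens upstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class BlotLane:
    label: str
    band_volume: float
    total_protein: float

    def __post_init__(self) -> None:
        if self.band_volume < 0:
            raise ValueError("band_volume must be non-negative")
        if self.total_protein <= 0:
            raise ValueError("total_protein must be positive")


def normalize_lane(lane: BlotLane, reference: BlotLane) -> float:
    """Loading-corrected band volume.

    normalization factor = reference total protein / lane total protein;
    normalized volume = band volume x factor.  Scaling a lane's loading
    (band and total together) leaves the result unchanged.
    """
    if reference.total_protein <= 0 or lane.total_protein <= 0:
        raise ValueError("total protein must be positive in both lanes")
    factor = reference.total_protein / lane.total_protein
    return lane.band_volume * factor


def relative_expression(lane_norm: float, reference_norm: float) -> float:
    """Normalized volume as a percentage of the reference lane's."""
    if reference_norm <= 0:
        raise ValueError("reference normalized volume must be positive")
    return 100.0 * lane_norm / reference_norm


def summarize_blot(table: pd.DataFrame, reference: str) -> pd.DataFrame:
    """Percent-of-reference per lane, averaged over replicate experiments.

    ``table`` has columns (lane, band_volume, total_protein, experiment);
    ``reference`` names the lane used for both loading normalization and the
    100% anchor within each experiment.  Returns one row per lane with
    mean percent and SD across experiments.
    """
    required = {"lane", "band_volume", "total_protein", "experiment"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"blot table missing columns: {sorted(missing)}")
    pct_rows = []
    for exp, grp in table.groupby("experiment"):
        ref_rows = grp[grp["lane"] == reference]
        if len(ref_rows) != 1:
            raise ValueError(
                f"experiment {exp!r} needs exactly one reference lane "
                f"{reference!r}, found {len(ref_rows)}"
            )
        ref = BlotLane(reference, float(ref_rows["band_volume"].iloc[0]),
                       float(ref_rows["total_protein"].iloc[0]))
        ref_norm = normalize_lane(ref, ref)
        for _, row in grp.iterrows():
            lane = BlotLane(str(row["lane"]), float(row["band_volume"]),
                            float(row["total_protein"]))
            pct = relative_expression(normalize_lane(lane, ref), ref_norm)
            pct_rows.append({"lane": lane.label, "experiment": exp,
                             "percent_of_reference": pct})
    per_exp = pd.DataFrame(pct_rows)
    out = (per_exp.groupby("lane")["percent_of_reference"]
           .agg(["mean", "std", "count"])
           .rename(columns={"mean": "percent_mean", "std": "percent_sd",
                            "count": "n_experiments"})
           .reset_index())
    out["percent_sd"] = out["percent_sd"].fillna(0.0)
    return out
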