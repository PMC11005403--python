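"""Depth-track and manifest parsing.

Depth input is text: bedGraph (chrom, start, end, value; 0-based half-open)
or a two-column TSV of (position, depth).  A single circular chromosome is
assumed throughout; multi-contig tracks are rejected.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .genome import GenomeDef

_SKIP_PREFIXES = ("#", "track", "browser")


def read_depth(path, genome: GenomeDef, allow_wrap: bool = False) -> pd.DataFrame:
    """Parse a depth track into an interval DataFrame (start, end, value).

    bedGraph rows must name the genome's chromosome; two-column input is
    per-position (position, depth) and becomes width-1 intervals.  Intervals
    running past the genome end are an error unless the genome is circular
    and ``allow_wrap`` is set, in which case they are split at the origin.
    Malformed lines are reported with their line number.
    """
    path = Path(path)
    rows: list[tuple[float, float, float]] = []
    ncols = None
    try:
        fh = open(path)
    except OSError as exc:
        raise OSError(f"cannot open depth track {path}: {exc}") from exc
    with fh:
        for ln, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith(_SKIP_PREFIXES):
                continue
            parts = line.split()
            if ncols is None:
                if len(parts) not in (2, 4):
                    raise ValueError(
                        f"{path}:{ln}: expected 2 (position, depth) or 4 "
                        f"(bedGraph) columns, found {len(parts)}"
                    )
                ncols = len(parts)
            if len(parts) != ncols:
                raise ValueError(f"{path}:{ln}: inconsistent column count")
            try:
                if ncols == 4:
                    chrom, s, e, v = parts
                    start, end, value = int(s), int(e), float(v)
                else:
                    chrom = genome.name
                    start = int(parts[0])
                    end = start + 1
                    value = float(parts[1])
            except ValueError as exc:
                raise ValueError(f"{path}:{ln}: malformed numeric field "
                                 f"({exc})") from exc
            if chrom != genome.name:
                raise ValueError(
                    f"{path}:{ln}: chromosome {chrom!r} does not match "
                    f"genome {genome.name!r} (multi-contig input is not "
                    f"supported)"
                )
            if value < 0:
                raise ValueError(f"{path}:{ln}: negative depth {value}")
            if start < 0 or start >= genome.length:
                raise ValueError(
                    f"{path}:{ln}: start {start} outside [0, {genome.length})"
                )
            if end <= start:
                raise ValueError(f"{path}:{ln}: end {end} <= start {start}")
            if end > genome.length:
                if not (genome.circular and allow_wrap):
                    raise ValueError(
                        f"{path}:{ln}: interval end {end} exceeds genome "
                        f"length {genome.length} (pass allow_wrap for "
                        f"circular wrap-around)"
                    )
                rows.append((start, genome.length, value))
                rows.append((0, end - genome.length, value))
            else:
                rows.append((start, end, value))
    if not rows:
        raise ValueError(f"{path}: no depth records found")
    df = pd.DataFrame(rows, columns=["start", "end", "value"])
    return df.sort_values("start", kind="stable").reset_index(drop=True)


def read_manifest(path) -> pd.DataFrame:
    """Read a time-course manifest CSV with columns (label, hours, path) and
    optional extras (e.g. strain).  Labels must be unique."""
    try:
        df = pd.read_csv(path, comment="#")
    except OSError as exc:
        raise OSError(f"cannot read manifest {path}: {exc}") from exc
    required = {"label", "hours", "path"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"manifest {path} missing columns: {sorted(missing)}")
    if df["label"].duplicated().any():
        dupes = df.loc[df["label"].duplicated(), "label"].tolist()
        raise ValueError(f"manifest {path}: duplicate labels {dupes}")
    return df


def read_growth_csv(path) -> pd.DataFrame:
    """Read growth kinetics CSV (time_h, cells_per_ml[, replicate])."""
    df = pd.read_csv(path, comment="#")
    required = {"time_h", "cells_per_ml"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"growth table {path} missing columns: {sorted(missing)}")
    if "replicate" not in df.columns:
        df["replicate"] = "1"
    return df


def write_csv_with_provenance(df: pd.DataFrame, path, header_lines=()) -> None:
    """Write a CSV preceded by '#'-prefixed provenance comment lines
    (config hash, seed, parameters), readable back with comment='#'."""
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        df.to_csv(fh, index=False)
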