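"""Genome definitions and circular coordinate arithmetic.

Thermococcales carry a single circular chromosome of ~2 Mb with one
annotated replication origin (oriC).  All coordinates in this package are
0-based, half-open; circular arithmetic is modulo the genome length.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class GenomeDef:
    """A single circular (or linear) chromosome with an annotated oriC.

    Parameters
    ----------
    name : str
        Chromosome name as it appears in depth tracks (bedGraph column 1).
    length : int
        Chromosome length in bp; must be positive.
    ori_position : int
        Coordinate of the replication origin, in ``[0, length)``.
    circular : bool
        Whether coordinate arithmetic wraps modulo ``length``.
    """

    name: str
    length: int
    ori_position: int
    circular: bool = True

    def __post_init__(self) -> None:
        if int(self.length) <= 0:
            raise ValueError(f"genome length must be positive, got {self.length}")
        if not (0 <= int(self.ori_position) < int(self.length)):
            raise ValueError(
                f"ori_position {self.ori_position} outside [0, {self.length})"
            )

    @property
    def antipode(self) -> int:
        """Coordinate diametrically opposite oriC (the replication terminus
        under symmetric bidirectional fork progression)."""
        return (self.ori_position + self.length // 2) % self.length

    def distance_to_ori(self, position):
        """Circular distance (bp) from ``position`` to oriC, always <= L/2."""
        return circular_distance(position, self.ori_position, self.length)


def circular_distance(a, b, length):
    """Shortest distance between coordinates on a circle of given length.

    Accepts scalars or numpy arrays; result is in ``[0, length/2]``.
    """
    d = np.abs(np.asarray(a, dtype=float) - np.asarray(b, dtype=float)) % length
    return np.minimum(d, length - d)


def wrap(position, length):
    """Map a coordinate onto ``[0, length)`` modulo the genome length."""
    return np.asarray(position, dtype=float) % length
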