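"""Mitotic spindle tilt geometry from 3D spindle-pole centroids.

Each metaphase cell contributes two centrosome centroids in µm, with x and y
in the growth-substrate (coverslip) plane and z normal to it.  The spindle
tilt is the angle between the inter-pole axis and the substrate plane:
projecting one pole onto the plane of the other gives a right triangle whose
legs are the in-plane distance and the z-offset.  Anisotropic voxel sizes
must be applied by the reader before these functions are called.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["SpindlePolePair", "spindle_angle", "pole_distance"]


@dataclass
class SpindlePolePair:
    """Two spindle-pole (centrosome) centroids of one cell, µm."""

    cell_id: str
    pole_a: np.ndarray
    pole_b: np.ndarray
    group: str | None = None

    def __post_init__(self) -> None:
        self.pole_a = np.asarray(self.pole_a, dtype=float)
        self.pole_b = np.asarray(self.pole_b, dtype=float)
        for p in (self.pole_a, self.pole_b):
            if p.shape != (3,):
                raise ValueError("poles must be 3-D coordinates")
            if not np.all(np.isfinite(p)):
                raise ValueError("pole coordinates must be finite")


def spindle_angle(pair: SpindlePolePair) -> float:
    """Tilt of the inter-pole axis relative to the substrate plane, degrees.

    ``θ = atan2(|Δz|, √(Δx² + Δy²))`` in [0, 90]; symmetric under pole swap
    and invariant under rotations about the z axis and under z-mirroring.
    Raises ``ValueError`` for coincident poles.
    """
    d = pair.pole_b - pair.pole_a
    dxy = math.hypot(d[0], d[1])
    dz = abs(d[2])
    if dxy == 0 and dz == 0:
        raise ValueError(f"cell {pair.cell_id!r}: poles coincide")
    return math.degrees(math.atan2(dz, dxy))


def pole_distance(pair: SpindlePolePair) -> float:
    """Euclidean 3D distance between the two poles, µm."""
    return float(np.linalg.norm(pair.pole_b - pair.pole_a))
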