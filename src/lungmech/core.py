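"""Shared containers for 4D micro-CT volume series and displacement fields.

Conventions used throughout the package:

* arrays are indexed ``(z, y, x)``, 0-based, voxel-centered;
* physical position = index * ``voxel_size`` (µm, isotropic);
* displacement fields are stored as ``(3, Z, Y, X)`` arrays in *voxel*
  units, component order ``(z, y, x)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

#: label values shared by the phantom generator and the segmentation module
BACKGROUND = 0
PROXIMAL = 1
INTERMEDIATE = 2
TERMINAL = 3
VESSEL = 4

LABEL_NAMES = {
    BACKGROUND: "background",
    PROXIMAL: "proximal",
    INTERMEDIATE: "intermediate",
    TERMINAL: "terminal",
    VESSEL: "vessel",
}

AIR_LABELS = (PROXIMAL, INTERMEDIATE, TERMINAL)


@dataclass
class VolumeSeries:
    """Ordered 3D greyscale volumes on a shared grid, one per phase bin.

    Parameters
    ----------
    data : ndarray, shape (T, Z, Y, X)
        Greyscale volumes.
    voxel_size : float
        Isotropic voxel edge length in µm.
    times : ndarray, shape (T,)
        Phase times in seconds (start of each bin).
    """

    data: np.ndarray
    voxel_size: float
    times: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError("VolumeSeries.data must be 4-D (T, Z, Y, X)")
        if self.times is None:
            self.times = np.arange(self.data.shape[0], dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.times.shape != (self.data.shape[0],):
            raise ValueError("times length must match number of phases")

    @property
    def n_phases(self) -> int:
        return self.data.shape[0]

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.data.shape[1:]

    def __getitem__(self, i: int) -> np.ndarray:
        return self.data[i]


@dataclass
class DisplacementField:
    """Per-voxel 3-vector displacement field in voxel units.

    ``kind`` is either ``"pairwise"`` (step ``from_step`` -> ``from_step+1``)
    or ``"lagrangian"`` (reference step 0 -> ``to_step``).  ``mask`` marks
    voxels whose value is trustworthy (advected points that left the domain
    are clamped and masked out).
    """

    vectors: np.ndarray
    kind: str = "pairwise"
    from_step: int = 0
    to_step: int = 1
    mask: np.ndarray | None = None
    voxel_size: float = 1.0

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=float)
        if self.vectors.ndim != 4 or self.vectors.shape[0] != 3:
            raise ValueError("vectors must have shape (3, Z, Y, X)")
        if not np.all(np.isfinite(self.vectors)):
            raise ValueError("displacement field contains non-finite values")
        if self.kind not in ("pairwise", "lagrangian"):
            raise ValueError(f"unknown field kind {self.kind!r}")
        if self.kind == "pairwise" and self.to_step != self.from_step + 1:
            raise ValueError("pairwise field must have to_step = from_step + 1")
        if self.kind == "lagrangian" and self.from_step != 0:
            raise ValueError("lagrangian field must have from_step = 0")
        if self.mask is None:
            self.mask = np.ones(self.vectors.shape[1:], dtype=bool)

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.vectors.shape[1:]

    def magnitude(self) -> np.ndarray:
        return np.sqrt(np.sum(self.vectors**2, axis=0))


def as_points(coords: Sequence) -> np.ndarray:
    """Coerce point coordinates to an (N, 3) float array in (z, y, x) order."""
    pts = np.atleast_2d(np.asarray(coords, dtype=float))
    if pts.shape[-1] != 3:
        raise ValueError("points must have 3 coordinates (z, y, x)")
    return pts
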