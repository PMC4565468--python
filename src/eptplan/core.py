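"""Core grid-aligned data structures.

Conventions used throughout the package:

* Voxel arrays are indexed ``(i, j, k)`` with 0-based indices; axis 2 (``k``)
  is the slice axis for axial stacks.
* World position of a voxel center is ``origin + index * spacing`` along the
  direction cosines (phantoms and all synthetic data are axis aligned).
* Spacing and all geometry are in millimetres; electric fields are reported
  in V/cm; conductivities in S/m.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict

import numpy as np

__all__ = ["ImageVolume", "LabelMask", "dice"]


@dataclass
class ImageVolume:
    """A 3D scalar image on a regular grid.

    Parameters
    ----------
    voxels : ndarray, shape (ni, nj, nk)
        Scalar intensities; Hounsfield units for CT, arbitrary for MRI.
    spacing : 3-tuple of float
        Voxel edge length per axis in mm, strictly positive.
    origin : 3-tuple of float
        World coordinate of voxel (0, 0, 0) in mm.
    modality : str
        Either ``"CT"`` or ``"MRI"``.
    direction : ndarray, shape (3, 3)
        Direction cosines; identity for all synthetic volumes.
    """

    voxels: np.ndarray
    spacing: tuple = (1.0, 1.0, 1.0)
    origin: tuple = (0.0, 0.0, 0.0)
    modality: str = "CT"
    direction: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError("voxels must be a 3D array")
        if any(s < n for s, n in zip(self.voxels.shape, (8, 8, 3))):
            raise ValueError(
                f"volume shape {self.voxels.shape} below minimum (8, 8, 3)"
            )
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")
        self.origin = tuple(float(o) for o in self.origin)
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("voxel values must be finite")
        if self.modality not in ("CT", "MRI"):
            raise ValueError(f"modality must be CT or MRI, got {self.modality!r}")
        self.direction = np.asarray(self.direction, dtype=float)

    @property
    def shape(self):
        return self.voxels.shape

    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def index_to_world(self, index) -> np.ndarray:
        """World-space position (mm) of a voxel center."""
        idx = np.atleast_2d(np.asarray(index, dtype=float))
        pos = np.asarray(self.origin) + (idx * np.asarray(self.spacing)) @ self.direction.T
        return pos[0] if np.ndim(index) == 1 else pos

    def world_to_index(self, point) -> np.ndarray:
        """Continuous voxel index of a world-space point (mm)."""
        pt = np.atleast_2d(np.asarray(point, dtype=float))
        idx = ((pt - np.asarray(self.origin)) @ np.linalg.inv(self.direction).T) / np.asarray(
            self.spacing
        )
        return idx[0] if np.ndim(point) == 1 else idx


@dataclass
class LabelMask:
    """Integer tissue labels aligned to a parent :class:`ImageVolume` grid."""

    labels: np.ndarray
    label_table: Dict[int, str]
    spacing: tuple = (1.0, 1.0, 1.0)
    origin: tuple = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("labels must be a 3D array")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be an integer array")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        self.label_table = {int(k): str(v) for k, v in self.label_table.items()}
        present = set(np.unique(self.labels)) - {0}
        missing = present - set(self.label_table)
        if missing:
            raise ValueError(f"labels {sorted(missing)} missing from label table")

    @property
    def shape(self):
        return self.labels.shape

    def label_of(self, tissue: str) -> int:
        for lab, name in self.label_table.items():
            if name == tissue:
                return lab
        raise KeyError(f"tissue {tissue!r} not in label table")

    def mask_of(self, tissue: str) -> np.ndarray:
        """Boolean mask of one named tissue."""
        return self.labels == self.label_of(tissue)

    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap 2|A∩B| / (|A|+|B|) of two boolean masks."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return 2.0 * np.logical_and(a, b).sum() / float(denom)
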