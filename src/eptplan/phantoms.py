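"""Synthetic test volumes with ground-truth masks.

Every segmentation and modeling stage in the package can be exercised on
these phantoms without any external data: an abdomen-like CT/MRI volume
(ellipsoidal liver with a contrast vessel, a spherical tumor and an optional
bone shell), a bright tube for tubularity filtering, and a multi-slice
brain/skull stack.

Intensities are configuration, not constants: the CT preset uses
Hounsfield-like values (air background -1000, liver 60, vessel 150, tumor 30,
bone 700); the MRI preset uses arbitrary units. Noise is additive Gaussian
per voxel.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np

from .core import ImageVolume, LabelMask

__all__ = [
    "PhantomSpec",
    "generate_abdomen_phantom",
    "generate_tube_phantom",
    "generate_brain_stack_phantom",
    "ABDOMEN_LABELS",
    "BRAIN_LABELS",
]

ABDOMEN_LABELS = {1: "liver", 2: "vessel", 3: "tumor", 4: "bone"}
BRAIN_LABELS = {1: "brain", 2: "skull"}

CT_INTENSITIES = {
    "background": -1000.0,
    "liver": 60.0,
    "vessel": 150.0,
    "tumor": 30.0,
    "bone": 700.0,
    "brain": 40.0,
}
MRI_INTENSITIES = {
    "background": 20.0,
    "liver": 400.0,
    "vessel": 620.0,
    "tumor": 250.0,
    "bone": 80.0,
    "brain": 500.0,
}


@dataclass
class PhantomSpec:
    """Geometry, intensity and noise description of a synthetic volume.

    All lengths in mm. ``seed`` makes generation fully deterministic.
    """

    shape: Tuple[int, int, int] = (96, 96, 48)
    spacing: Tuple[float, float, float] = (2.0, 2.0, 2.0)
    modality: str = "CT"
    intensities: Optional[Dict[str, float]] = None
    noise_sd: float = 0.0
    liver_semiaxes: Tuple[float, float, float] = (70.0, 55.0, 38.0)
    liver_center: Optional[Tuple[float, float, float]] = None
    vessel_radius: float = 3.0
    vessel_waypoints: Optional[Sequence[Tuple[float, float, float]]] = None
    tumor_center: Optional[Tuple[float, float, float]] = None
    tumor_radius: float = 10.0
    include_bone: bool = True
    bone_radius: float = 12.0
    seed: int = 0

    def __post_init__(self):
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be > 0")
        if self.vessel_radius <= 0 or self.tumor_radius <= 0:
            raise ValueError("radii must be > 0")
        if self.intensities is None:
            self.intensities = dict(
                CT_INTENSITIES if self.modality == "CT" else MRI_INTENSITIES
            )

    def grid_mm(self):
        """World coordinates (mm) of voxel centers, one 3D array per axis."""
        axes = [
            np.arange(n, dtype=float) * s
            for n, s in zip(self.shape, self.spacing)
        ]
        return np.meshgrid(*axes, indexing="ij")

    def extent_mm(self) -> np.ndarray:
        return np.asarray(self.shape, dtype=float) * np.asarray(self.spacing)


def _ellipsoid(grid, center, semiaxes) -> np.ndarray:
    x, y, z = grid
    cx, cy, cz = center
    ax, ay, az = semiaxes
    return ((x - cx) / ax) ** 2 + ((y - cy) / ay) ** 2 + ((z - cz) / az) ** 2 <= 1.0


def _sphere(grid, center, radius) -> np.ndarray:
    return _ellipsoid(grid, center, (radius, radius, radius))


def _capsule_mask(grid, p0, p1, radius) -> np.ndarray:
    """Voxels within ``radius`` of segment p0-p1 (cylinder with round caps)."""
    x, y, z = grid
    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    d = p1 - p0
    L2 = float(d @ d)
    if L2 == 0:
        return _sphere(grid, p0, radius)
    t = ((x - p0[0]) * d[0] + (y - p0[1]) * d[1] + (z - p0[2]) * d[2]) / L2
    t = np.clip(t, 0.0, 1.0)
    dx = x - (p0[0] + t * d[0])
    dy = y - (p0[1] + t * d[1])
    dz = z - (p0[2] + t * d[2])
    return dx * dx + dy * dy + dz * dz <= radius * radius


def generate_abdomen_phantom(spec: PhantomSpec):
    """Build the abdomen preset: ellipsoidal liver containing a tubular
    contrast vessel and a spherical tumor, plus an optional bone rod.

    Returns ``(ImageVolume, LabelMask)``; the mask uses labels
    liver=1, vessel=2, tumor=3, bone=4. The tumor must lie fully inside the
    liver ellipsoid or a ``ValueError`` is raised.
    """
    extent = spec.extent_mm()
    center = (
        np.asarray(spec.liver_center, dtype=float)
        if spec.liver_center is not None
        else extent / 2.0
    )
    a = np.asarray(spec.liver_semiaxes, dtype=float)
    tumor_center = (
        np.asarray(spec.tumor_center, dtype=float)
        if spec.tumor_center is not None
        else center + np.array([a[0] * 0.3, 0.0, 0.0])
    )
    # tumor containment: worst-case support point of the sphere vs ellipsoid
    rel = (tumor_center - center) / a
    if np.sqrt(rel @ rel) + spec.tumor_radius / a.min() > 1.0:
        raise ValueError("tumor not fully inside liver ellipsoid")

    grid = spec.grid_mm()
    liver = _ellipsoid(grid, center, a)
    if spec.vessel_waypoints is not None:
        wps = [np.asarray(w, dtype=float) for w in spec.vessel_waypoints]
    else:
        wps = [
            center - np.array([0.0, a[1] * 0.75, 0.0]),
            center + np.array([0.0, a[1] * 0.75, 0.0]),
        ]
    vessel = np.zeros(spec.shape, dtype=bool)
    for p0, p1 in zip(wps[:-1], wps[1:]):
        vessel |= _capsule_mask(grid, p0, p1, spec.vessel_radius)
    vessel &= liver
    tumor = _sphere(grid, tumor_center, spec.tumor_radius)

    labels = np.zeros(spec.shape, dtype=np.int16)
    labels[liver] = 1
    labels[vessel] = 2
    labels[tumor] = 3
    if spec.include_bone:
        # bone rod along z near a corner of the body, clear of the liver
        bone_c = np.array([extent[0] * 0.1, extent[1] * 0.15, 0.0])
        bone = _capsule_mask(
            grid, bone_c, bone_c + np.array([0.0, 0.0, extent[2]]), spec.bone_radius
        )
        bone &= ~liver
        labels[bone] = 4

    names = {0: "background", 1: "liver", 2: "vessel", 3: "tumor", 4: "bone"}
    intens = spec.intensities
    vox = np.full(spec.shape, intens["background"], dtype=np.float64)
    for lab, name in names.items():
        if lab == 0:
            continue
        vox[labels == lab] = intens[name]
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        vox = vox + rng.normal(0.0, spec.noise_sd, size=spec.shape)

    vol = ImageVolume(vox, spacing=spec.spacing, modality=spec.modality)
    table = {k: v for k, v in ABDOMEN_LABELS.items() if (labels == k).any()}
    mask = LabelMask(labels, table, spacing=spec.spacing)
    return vol, mask


def generate_tube_phantom(
    shape=(48, 48, 48),
    spacing=(1.0, 1.0, 1.0),
    radius: float = 3.0,
    orientation=(0, 0, 1),
    background: float = 0.0,
    contrast: float = 100.0,
    noise_sd: float = 0.0,
    seed: int = 0,
):
    """Bright cylinder through the volume center along ``orientation``.

    Returns ``(ImageVolume, centerline LabelMask)`` where the centerline mask
    marks voxels whose centers lie within half a voxel of the cylinder axis.
    ``orientation`` must be (close to) axis aligned or arbitrary; the axis
    line is extended across the full volume.
    """
    spacing = tuple(float(s) for s in spacing)
    if radius < min(spacing):
        raise ValueError("tube radius must be at least one voxel")
    d = np.asarray(orientation, dtype=float)
    norm = np.linalg.norm(d)
    if norm == 0:
        raise ValueError("orientation must be a nonzero vector")
    d = d / norm
    extent = np.asarray(shape, dtype=float) * np.asarray(spacing)
    center = extent / 2.0
    half = float(np.linalg.norm(extent))
    p0, p1 = center - half * d, center + half * d

    axes = [np.arange(n, dtype=float) * s for n, s in zip(shape, spacing)]
    grid = np.meshgrid(*axes, indexing="ij")
    tube = _capsule_mask(grid, p0, p1, radius)
    axis_line = _capsule_mask(grid, p0, p1, 0.5 * min(spacing))

    vox = np.full(shape, background, dtype=np.float64)
    vox[tube] = background + contrast
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        vox = vox + rng.normal(0.0, noise_sd, size=shape)
    vol = ImageVolume(vox, spacing=spacing, modality="CT")
    mask = LabelMask(
        axis_line.astype(np.int16), {1: "centerline"}, spacing=spacing
    )
    return vol, mask


@dataclass
class BrainStackSpec:
    """Geometry of the multi-slice brain/skull phantom."""

    shape: Tuple[int, int, int] = (64, 64, 15)
    spacing: Tuple[float, float, float] = (1.5, 1.5, 3.0)
    # the z semiaxis exceeds the stack half-extent slightly, so the polar
    # caps are truncated and every slice keeps a sizeable cross-section
    brain_semiaxes: Tuple[float, float, float] = (32.0, 26.0, 26.0)
    skull_thickness: float = 4.0
    intensities: Dict[str, float] = field(
        default_factory=lambda: {"background": 20.0, "brain": 500.0, "skull": 120.0}
    )
    noise_sd: float = 0.0
    seed: int = 0


def generate_brain_stack_phantom(spec: BrainStackSpec = None):
    """Ellipsoidal "brain" wrapped in a "skull" shell on an MRI-like stack.

    Cross-section area peaks at the central slice and decreases monotonically
    toward both ends (ellipsoid geometry guarantees this). Returns
    ``(ImageVolume, LabelMask)`` with labels brain=1, skull=2.
    """
    if spec is None:
        spec = BrainStackSpec()
    if spec.shape[2] < 5:
        raise ValueError("brain stack needs at least 5 slices")
    extent = np.asarray(spec.shape, dtype=float) * np.asarray(spec.spacing)
    center = extent / 2.0
    # snap the center to a voxel plane so the central slice is strictly largest
    center[2] = (spec.shape[2] // 2) * spec.spacing[2]
    axes = [np.arange(n, dtype=float) * s for n, s in zip(spec.shape, spec.spacing)]
    grid = np.meshgrid(*axes, indexing="ij")
    brain = _ellipsoid(grid, center, spec.brain_semiaxes)
    outer = _ellipsoid(
        grid, center, np.asarray(spec.brain_semiaxes) + spec.skull_thickness
    )
    skull = outer & ~brain

    labels = np.zeros(spec.shape, dtype=np.int16)
    labels[skull] = 2
    labels[brain] = 1
    vox = np.full(spec.shape, spec.intensities["background"], dtype=np.float64)
    vox[skull] = spec.intensities["skull"]
    vox[brain] = spec.intensities["brain"]
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        vox = vox + rng.normal(0.0, spec.noise_sd, size=spec.shape)
    vol = ImageVolume(vox, spacing=spec.spacing, modality="MRI")
    mask = LabelMask(labels, BRAIN_LABELS, spacing=spec.spacing)
    return vol, mask
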