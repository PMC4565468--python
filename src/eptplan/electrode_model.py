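"""Electrode catalog, parallel-array placement and rasterization.

An array is placed from a two-point trajectory (entry and target); all
needles are exactly parallel to the trajectory direction with their tips on
the plane through the target point perpendicular to it. Fixed-geometry
styles take their in-plane offsets from the catalog; the variable style lays
needles out in a symmetric row (or grid) at a user spacing. Pulses are
delivered across an ordered pair sequence.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import yaml
from scipy import ndimage

__all__ = [
    "ElectrodeSpec",
    "ElectrodeArray",
    "ClearanceViolation",
    "catalog",
    "get_spec",
    "place_parallel_array",
    "check_trajectory_clearance",
    "rasterize_electrodes",
]

STYLES = {"linear", "hexagonal", "finger-axial", "finger-perpendicular", "variable"}


@dataclass
class ElectrodeSpec:
    id: str
    style: str
    needle_diameter_mm: float
    active_lengths_mm: List[float]
    default_active_length_mm: float
    max_voltage_v: float
    offsets_mm: Optional[List[Tuple[float, float]]] = None
    hex_radius_mm: Optional[float] = None

    def __post_init__(self):
        if self.style not in STYLES:
            raise ValueError(f"unknown electrode style {self.style!r}")
        if self.needle_diameter_mm <= 0:
            raise ValueError("needle diameter must be > 0")
        if self.default_active_length_mm <= 0 or any(
            l <= 0 for l in self.active_lengths_mm
        ):
            raise ValueError("active lengths must be > 0")
        if self.style == "hexagonal":
            if not self.hex_radius_mm or self.hex_radius_mm <= 0:
                raise ValueError("hexagonal spec needs hex_radius_mm > 0")
            r = float(self.hex_radius_mm)
            angles = np.arange(6) * np.pi / 3.0
            self.offsets_mm = [(0.0, 0.0)] + [
                (r * np.cos(a), r * np.sin(a)) for a in angles
            ]
        if self.style not in ("variable",):
            if not self.offsets_mm or len(self.offsets_mm) < 2:
                raise ValueError(f"fixed-geometry spec {self.id} needs >= 2 offsets")


@dataclass
class ElectrodeArray:
    """A parallel needle array: shared direction, per-needle tip positions."""

    spec_id: str
    direction: np.ndarray  # unit vector, shared by all needles
    tips_mm: np.ndarray  # (n, 3) world positions of needle tips
    active_length_mm: float
    needle_diameter_mm: float
    pairs: List[Tuple[int, int]]
    entry_mm: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.direction = np.asarray(self.direction, dtype=float)
        self.tips_mm = np.asarray(self.tips_mm, dtype=float)
        self.entry_mm = np.asarray(self.entry_mm, dtype=float)
        n = len(self.tips_mm)
        for i, j in self.pairs:
            if not (0 <= i < n and 0 <= j < n and i != j):
                raise ValueError(f"invalid pair ({i}, {j}) for {n} needles")
        if len({tuple(t) for t in np.round(self.tips_mm, 9)}) != n:
            raise ValueError("needle tips must be distinct")

    @property
    def n_needles(self) -> int:
        return len(self.tips_mm)

    def active_segment(self, i: int):
        """(proximal, distal) endpoints of needle i's active segment."""
        tip = self.tips_mm[i]
        return tip - self.active_length_mm * self.direction, tip

    def to_json(self) -> dict:
        return {
            "spec_id": self.spec_id,
            "direction": self.direction.tolist(),
            "tips_mm": self.tips_mm.tolist(),
            "active_length_mm": self.active_length_mm,
            "needle_diameter_mm": self.needle_diameter_mm,
            "pairs": [list(p) for p in self.pairs],
            "entry_mm": self.entry_mm.tolist(),
        }

    @classmethod
    def from_json(cls, d: dict) -> "ElectrodeArray":
        return cls(d["spec_id"], np.asarray(d["direction"]), np.asarray(d["tips_mm"]),
                   d["active_length_mm"], d["needle_diameter_mm"],
                   [tuple(p) for p in d["pairs"]], np.asarray(d["entry_mm"]))


def catalog(path=None) -> List[ElectrodeSpec]:
    """Load the electrode catalog (built-in config unless a path is given)."""
    if path is None:
        ref = importlib.resources.files("eptplan") / "data" / "electrodes.yaml"
        text = ref.read_text()
    else:
        with open(path) as f:
            text = f.read()
    data = yaml.safe_load(text)
    if not isinstance(data, dict) or "electrodes" not in data:
        raise ValueError("malformed electrode catalog: missing 'electrodes' key")
    specs = []
    for entry in data["electrodes"]:
        offsets = entry.get("offsets_mm")
        specs.append(ElectrodeSpec(
            id=entry["id"], style=entry["style"],
            needle_diameter_mm=float(entry["needle_diameter_mm"]),
            active_lengths_mm=[float(v) for v in entry["active_lengths_mm"]],
            default_active_length_mm=float(entry["default_active_length_mm"]),
            max_voltage_v=float(entry["max_voltage_v"]),
            offsets_mm=[tuple(map(float, o)) for o in offsets] if offsets else None,
            hex_radius_mm=entry.get("hex_radius_mm"),
        ))
    return specs


def get_spec(spec_id: str, path=None) -> ElectrodeSpec:
    for spec in catalog(path):
        if spec.id == spec_id:
            return spec
    raise KeyError(f"electrode spec {spec_id!r} not in catalog")


def _plane_basis(direction: np.ndarray):
    """Right-handed orthonormal (u, v) basis of the plane ⊥ direction."""
    ref = np.zeros(3)
    ref[int(np.argmin(np.abs(direction)))] = 1.0
    u = np.cross(direction, ref)
    u /= np.linalg.norm(u)
    v = np.cross(direction, u)
    return u, v


HEX_PAIR_SEQUENCE = [
    (0, 1), (0, 2), (0, 3), (0, 4), (0, 5), (0, 6),
    (1, 2), (2, 3), (3, 4), (4, 5), (5, 6), (6, 1),
]


def place_parallel_array(spec: ElectrodeSpec, entry_mm, target_mm,
                         n_needles: int = 2, spacing_mm: float = 10.0,
                         active_length_mm: float = None) -> ElectrodeArray:
    """Place a parallel needle array along the entry→target trajectory.

    Needle tips lie on the plane through the target perpendicular to the
    trajectory: at the catalog offsets for fixed-geometry styles, or on a
    symmetric row with ``spacing_mm`` for the variable style (``n_needles``
    is ignored for fixed styles).
    """
    entry = np.asarray(entry_mm, dtype=float)
    target = np.asarray(target_mm, dtype=float)
    d = target - entry
    norm = np.linalg.norm(d)
    if norm == 0:
        raise ValueError("entry and target coincide: zero-length trajectory")
    d = d / norm
    u, v = _plane_basis(d)

    if spec.style == "variable":
        if n_needles < 2:
            raise ValueError("variable arrays need at least 2 needles")
        offs = [( (i - (n_needles - 1) / 2.0) * spacing_mm, 0.0)
                for i in range(n_needles)]
        pairs = [(i, i + 1) for i in range(n_needles - 1)]
    else:
        offs = spec.offsets_mm
        if spec.style == "hexagonal":
            pairs = list(HEX_PAIR_SEQUENCE)
        else:
            pairs = [(i, i + 1) for i in range(len(offs) - 1)]
    tips = np.array([target + a * u + b * v for a, b in offs])

    length = active_length_mm or spec.default_active_length_mm
    if length not in spec.active_lengths_mm:
        raise ValueError(
            f"active length {length} not offered by {spec.id}: "
            f"{spec.active_lengths_mm}"
        )
    return ElectrodeArray(spec.id, d, tips, float(length),
                          spec.needle_diameter_mm, pairs, entry)


@dataclass
class ClearanceViolation:
    needle: int
    obstacle: str
    closest_mm: float
    at_mm: Tuple[float, float, float]


def check_trajectory_clearance(array: ElectrodeArray, obstacles: Dict[str, np.ndarray],
                               margin_mm: float, spacing=(1.0, 1.0, 1.0),
                               origin=(0.0, 0.0, 0.0),
                               step_mm: float = 0.5) -> List[ClearanceViolation]:
    """Report obstacles closer than ``margin_mm`` to any insertion path.

    Each needle's insertion segment (entry plane to tip) is sampled at
    ``step_mm``; distances come from the Euclidean distance transform of
    each obstacle mask. Returns a (possibly empty) list of violations with
    the closest approach per needle/obstacle.
    """
    spacing = np.asarray(spacing, dtype=float)
    origin = np.asarray(origin, dtype=float)
    dist_maps = {}
    for name, mask in obstacles.items():
        mask = np.asarray(mask, dtype=bool)
        if not mask.any():
            continue
        dist_maps[name] = ndimage.distance_transform_edt(~mask, sampling=spacing)

    violations = []
    for i in range(array.n_needles):
        # insertion path: parallel entry through the plane containing entry_mm
        tip = array.tips_mm[i]
        start = tip - array.direction * np.dot(tip - array.entry_mm, array.direction)
        length = np.linalg.norm(tip - start)
        nsteps = max(2, int(np.ceil(length / step_mm)) + 1)
        pts = start + np.outer(np.linspace(0, 1, nsteps), tip - start)
        idx = ((pts - origin) / spacing).T
        for name, dmap in dist_maps.items():
            vals = ndimage.map_coordinates(dmap, idx, order=1, mode="nearest")
            jmin = int(np.argmin(vals))
            if vals[jmin] < margin_mm:
                violations.append(ClearanceViolation(
                    needle=i, obstacle=name, closest_mm=float(vals[jmin]),
                    at_mm=tuple(pts[jmin]),
                ))
    return violations


def rasterize_electrodes(array: ElectrodeArray, shape, spacing=(1.0, 1.0, 1.0),
                         origin=(0.0, 0.0, 0.0)) -> np.ndarray:
    """Label voxels whose centers lie within diameter/2 of an active segment.

    Returns an int array with needle ``i`` marked as ``i + 1``; these voxels
    are conductor interiors and excluded from the solver's unknowns.
    """
    spacing = np.asarray(spacing, dtype=float)
    origin = np.asarray(origin, dtype=float)
    shape = tuple(shape)
    labels = np.zeros(shape, dtype=np.int16)
    radius = array.needle_diameter_mm / 2.0
    for i in range(array.n_needles):
        p0, p1 = array.active_segment(i)
        for p in (p0, p1):
            idx = (p - origin) / spacing
            if np.any(idx < -0.5) or np.any(idx > np.asarray(shape) - 0.5):
                raise ValueError(f"needle {i} active segment outside the grid")
        lo = np.floor((np.minimum(p0, p1) - radius - origin) / spacing).astype(int)
        hi = np.ceil((np.maximum(p0, p1) + radius - origin) / spacing).astype(int) + 1
        lo = np.maximum(lo, 0)
        hi = np.minimum(hi, shape)
        sub = [np.arange(lo[a], hi[a]) * spacing[a] + origin[a] for a in range(3)]
        X, Y, Z = np.meshgrid(*sub, indexing="ij")
        d = p1 - p0
        L2 = float(d @ d)
        t = ((X - p0[0]) * d[0] + (Y - p0[1]) * d[1] + (Z - p0[2]) * d[2]) / L2
        dx = X - (p0[0] + t * d[0])
        dy = Y - (p0[1] + t * d[1])
        dz = Z - (p0[2] + t * d[2])
        # finite cylinder: radial test plus axial containment (no end caps)
        inside = (dx * dx + dy * dy + dz * dz <= radius * radius) \
            & (t >= 0.0) & (t <= 1.0)
        region = labels[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
        region[inside] = i + 1
        labels[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = region
        if not inside.any():
            # thin needle on a coarse grid: mark the voxel line along the axis
            # so the conductor is never empty
            npts = max(2, int(np.ceil(np.linalg.norm(p1 - p0) / min(spacing))) + 1)
            pts = p0 + np.outer(np.linspace(0, 1, npts), p1 - p0)
            idx = np.rint((pts - origin) / spacing).astype(int)
            idx = np.clip(idx, 0, np.asarray(shape) - 1)
            labels[idx[:, 0], idx[:, 1], idx[:, 2]] = i + 1
    return labels
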