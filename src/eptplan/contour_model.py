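"""Slice-contour model: extraction, relevance-based simplification, edits.

Segmentation masks are presented for validation as closed 2D polylines per
slice. Contours are decimated to a configurable percentage of their points
(default 20%) by iteratively removing the point with the least influence,
where influence combines the turn angle at the point with the lengths of its
adjacent edges. User edits (moved points, redrawn contours) are merged back
by piecewise-cubic reconstruction and the result is rasterized to a mask.

Coordinates are continuous pixel units ``(r, c)`` — indices along the first
and second in-plane axes — 0-based, on the slice plane.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from math import ceil
from typing import Dict, List, Optional, Sequence

import numpy as np
from scipy.interpolate import CubicSpline
from scipy import ndimage
from shapely.geometry import LineString
from skimage import draw, measure

from .core import LabelMask

__all__ = [
    "SliceContour",
    "ContourEdit",
    "extract_slice_contours",
    "point_influence",
    "simplify_contour",
    "refine_contour",
    "apply_edits",
    "rasterize_contours",
    "manual_contour_ingest",
    "contours_to_json",
    "contours_from_json",
]

DEFAULT_RETAINED_PERCENT = 20.0

FLAG_ORIGINAL = "original"
FLAG_MOVED = "user-moved"
FLAG_SYNTHETIC = "synthetic"
FLAG_DRAWN = "user-drawn"


@dataclass
class SliceContour:
    """Ordered closed polyline on one slice (closure implicit, first≠last)."""

    slice_index: int
    points: np.ndarray  # (N, 2) float, (r, c)
    flags: List[str] = None
    plane_axis: int = 2
    object_id: str = ""
    label: int = 1
    original_count: int = 0
    retained_percent: float = 100.0

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError("points must be an (N, 2) array")
        if len(self.points) >= 2 and np.allclose(self.points[0], self.points[-1]):
            self.points = self.points[:-1]
            if self.flags is not None and len(self.flags) == len(self.points) + 1:
                self.flags = self.flags[:-1]
        if len(self.points) < 3:
            raise ValueError("a contour needs at least 3 points")
        if self.flags is None:
            self.flags = [FLAG_ORIGINAL] * len(self.points)
        if len(self.flags) != len(self.points):
            raise ValueError("flags length must match point count")
        if self.original_count == 0:
            self.original_count = len(self.points)
        if not (0 < self.retained_percent <= 100):
            raise ValueError("retained percent must be in (0, 100]")

    def __len__(self):
        return len(self.points)

    def is_simple(self) -> bool:
        ring = np.vstack([self.points, self.points[0]])
        return LineString(ring).is_simple

    def area(self) -> float:
        """Signed shoelace area (positive for counterclockwise order)."""
        r, c = self.points[:, 0], self.points[:, 1]
        return 0.5 * float(
            np.sum(r * np.roll(c, -1) - np.roll(r, -1) * c)
        )


@dataclass
class ContourEdit:
    """One user edit against a contour set."""

    slice_index: int
    object_id: str
    operation: str  # move_point | set_retained_percent | delete_object | replace_contour
    point_index: Optional[int] = None
    new_point: Optional[Sequence[float]] = None
    percent: Optional[float] = None
    polyline: Optional[Sequence[Sequence[float]]] = None


def extract_slice_contours(mask: LabelMask, label: int,
                           plane_axis: int = 2) -> List[SliceContour]:
    """Marching-squares boundaries of ``label``, one contour per 2D region.

    Contours are ordered counterclockwise at the 0.5 iso-level; holes are
    filled before extraction and therefore ignored. Returns an empty list if
    the label is absent.
    """
    binary = mask.labels == label
    if not binary.any():
        return []
    contours: List[SliceContour] = []
    nslices = binary.shape[plane_axis]
    for k in range(nslices):
        sl = np.take(binary, k, axis=plane_axis)
        if not sl.any():
            continue
        filled = ndimage.binary_fill_holes(sl)
        padded = np.pad(filled.astype(float), 1)
        for ring in measure.find_contours(padded, 0.5):
            pts = ring - 1.0  # undo padding offset
            if np.allclose(pts[0], pts[-1]):
                pts = pts[:-1]
            if len(pts) < 3:
                continue
            sc = SliceContour(slice_index=k, points=pts, plane_axis=plane_axis,
                              label=label,
                              object_id=mask.label_table.get(label, str(label)))
            if sc.area() < 0:
                sc.points = sc.points[::-1].copy()
            contours.append(sc)
    return contours


def point_influence(contour: SliceContour) -> np.ndarray:
    """Per-point relevance scores on the closed cycle.

    ``K(p) = beta(p) * l1 * l2 / (l1 + l2)`` with ``beta`` the turn angle at
    ``p`` in radians and ``l1``, ``l2`` the adjacent edge lengths. Collinear
    points score exactly 0.
    """
    return _influence(contour.points)


def _influence(pts: np.ndarray) -> np.ndarray:
    prev_pts = np.roll(pts, 1, axis=0)
    next_pts = np.roll(pts, -1, axis=0)
    e1 = pts - prev_pts
    e2 = next_pts - pts
    l1 = np.linalg.norm(e1, axis=1)
    l2 = np.linalg.norm(e2, axis=1)
    if np.any(l1 == 0):
        raise ValueError("duplicate consecutive points in contour")
    cosb = np.sum(e1 * e2, axis=1) / (l1 * l2)
    beta = np.arccos(np.clip(cosb, -1.0, 1.0))
    return beta * l1 * l2 / (l1 + l2)


def _influence_at(pts, i):
    n = len(pts)
    p, q, r = pts[(i - 1) % n], pts[i], pts[(i + 1) % n]
    e1, e2 = q - p, r - q
    l1, l2 = np.linalg.norm(e1), np.linalg.norm(e2)
    if l1 == 0 or l2 == 0:
        raise ValueError("duplicate consecutive points in contour")
    beta = np.arccos(np.clip(np.dot(e1, e2) / (l1 * l2), -1.0, 1.0))
    return beta * l1 * l2 / (l1 + l2)


def simplify_contour(contour: SliceContour,
                     retained_percent: float = DEFAULT_RETAINED_PERCENT) -> SliceContour:
    """Decimate to ``ceil(percent/100 * N)`` points by sequential deletion.

    At each step the minimum-influence point is removed (ties broken toward
    the lower index) and the influences of its two neighbours are recomputed.
    Points flagged user-moved are never deleted. Deletion-only: the surviving
    point set is a subset of the input, in the original order.
    """
    n = len(contour)
    target = ceil(retained_percent / 100.0 * n)
    if target < 3:
        raise ValueError(
            f"retained percent {retained_percent} keeps {target} < 3 points"
        )
    pts = [p for p in contour.points]
    flags = list(contour.flags)
    if len(pts) > target:
        scores = list(_influence(np.asarray(pts)))
        while len(pts) > target:
            best, best_score = -1, np.inf
            for i, s in enumerate(scores):
                if flags[i] == FLAG_MOVED:
                    continue
                if s < best_score:
                    best, best_score = i, s
            if best < 0:
                break  # everything protected
            del pts[best], flags[best], scores[best]
            m = len(pts)
            arr = np.asarray(pts)
            for j in ((best - 1) % m, best % m):
                scores[j] = _influence_at(arr, j)
    return replace(
        contour,
        points=np.asarray(pts),
        flags=flags,
        original_count=contour.original_count or n,
        retained_percent=float(retained_percent),
    )


def _moved_runs(flags: List[str]):
    """Contiguous cyclic runs of user-moved indices."""
    n = len(flags)
    moved = [i for i in range(n) if flags[i] == FLAG_MOVED]
    if not moved or len(moved) == n:
        return moved, []
    runs, current = [], [moved[0]]
    for i in moved[1:]:
        if i == current[-1] + 1:
            current.append(i)
        else:
            runs.append(current)
            current = [i]
    runs.append(current)
    # merge a wrap-around run (… n-1 | 0 …)
    if len(runs) > 1 and runs[0][0] == 0 and runs[-1][-1] == n - 1:
        runs[0] = runs.pop() + runs[0]
    return moved, runs


def _sample_cubic(control: np.ndarray, step: float = 1.0, periodic: bool = False):
    """Chord-length parameterized cubic through ``control``, sampled ~``step``."""
    if periodic:
        control = np.vstack([control, control[0]])
    chord = np.linalg.norm(np.diff(control, axis=0), axis=1)
    t = np.concatenate([[0.0], np.cumsum(chord)])
    bc = "periodic" if periodic else "natural"
    spline = CubicSpline(t, control, bc_type=bc)
    samples = [control[0]]
    param_of_control = set(t.tolist())
    for t0, t1 in zip(t[:-1], t[1:]):
        nseg = max(1, int(ceil((t1 - t0) / step)))
        ts = np.linspace(t0, t1, nseg + 1)[1:]
        for tv in ts:
            # control points must appear exactly, not via spline evaluation
            samples.append(control[np.argmin(np.abs(t - tv))]
                           if tv in param_of_control else spline(tv))
    pts = np.asarray(samples)
    return pts[:-1] if periodic else pts


def refine_contour(contour: SliceContour,
                   retained_percent: float = DEFAULT_RETAINED_PERCENT) -> SliceContour:
    """Re-simplify after edits, reconstructing edited spans first.

    Spans of user-moved points are replaced by a piecewise cubic interpolant
    through the moved points and their unmodified anchor neighbours, densely
    sampled (1-pixel step); untouched points are kept as-is; the merged
    polyline is then decimated to ``retained_percent``. Every user-moved
    coordinate survives exactly.
    """
    moved, runs = _moved_runs(contour.flags)
    if not moved:
        return simplify_contour(contour, retained_percent)
    pts = contour.points
    n = len(pts)
    if len(moved) == n:  # fully redrawn: periodic fit through all points
        dense = _sample_cubic(pts, periodic=True)
        flags = [FLAG_MOVED if any(np.allclose(d, p) for p in pts) else FLAG_SYNTHETIC
                 for d in dense]
        merged = SliceContour(contour.slice_index, dense, flags,
                              plane_axis=contour.plane_axis,
                              object_id=contour.object_id, label=contour.label,
                              original_count=contour.original_count)
        return simplify_contour(merged, retained_percent)

    new_pts: List[np.ndarray] = []
    new_flags: List[str] = []
    in_run = {i: r for r in runs for i in r}
    i = 0
    visited = set()
    # walk the cycle starting from an unmodified point
    start = next(i for i in range(n) if contour.flags[i] != FLAG_MOVED)
    order = [(start + d) % n for d in range(n)]
    for i in order:
        if i in visited:
            continue
        if i not in in_run:
            new_pts.append(pts[i])
            new_flags.append(contour.flags[i])
            visited.add(i)
            continue
        run = in_run[i]
        visited.update(run)
        a0 = (run[0] - 1) % n
        a1 = (run[-1] + 1) % n
        control = np.vstack([pts[a0], pts[run], pts[a1]])
        dense = _sample_cubic(control, step=1.0)
        # drop the anchors: they are emitted on their own turn of the walk
        run_set = {tuple(pts[j]) for j in run}
        for d in dense[1:-1]:
            new_pts.append(d)
            new_flags.append(FLAG_MOVED if tuple(d) in run_set else FLAG_SYNTHETIC)
    if len(new_pts) < 3:
        raise ValueError("fewer than 3 points survive refinement")
    merged = SliceContour(contour.slice_index, np.asarray(new_pts), new_flags,
                          plane_axis=contour.plane_axis,
                          object_id=contour.object_id, label=contour.label,
                          original_count=contour.original_count)
    return simplify_contour(merged, retained_percent)


def apply_edits(contours: List[SliceContour],
                edits: List[ContourEdit]) -> List[SliceContour]:
    """Apply a list of edits, returning the updated contour set."""
    result = [replace(c, points=c.points.copy(), flags=list(c.flags))
              for c in contours]
    for e in edits:
        matches = [c for c in result
                   if c.slice_index == e.slice_index and c.object_id == e.object_id]
        if e.operation == "delete_object":
            for c in matches:
                result.remove(c)
            continue
        if not matches:
            raise ValueError(
                f"no contour for object {e.object_id!r} on slice {e.slice_index}"
            )
        c = matches[0]
        if e.operation == "move_point":
            if e.point_index is None or not (0 <= e.point_index < len(c)):
                raise IndexError(f"point index {e.point_index} out of range")
            c.points[e.point_index] = np.asarray(e.new_point, dtype=float)
            c.flags[e.point_index] = FLAG_MOVED
        elif e.operation == "set_retained_percent":
            idx = result.index(c)
            result[idx] = refine_contour(c, e.percent)
        elif e.operation == "replace_contour":
            idx = result.index(c)
            result[idx] = SliceContour(
                c.slice_index, np.asarray(e.polyline, dtype=float),
                [FLAG_DRAWN] * len(e.polyline), plane_axis=c.plane_axis,
                object_id=c.object_id, label=c.label)
        else:
            raise ValueError(f"unknown edit operation {e.operation!r}")
    return result


def rasterize_contours(contours: List[SliceContour], shape, label_table=None,
                       spacing=(1.0, 1.0, 1.0), origin=(0.0, 0.0, 0.0),
                       plane_axis: int = 2) -> LabelMask:
    """Polygon-fill contours back into a label mask (pixel-center inclusion)."""
    labels = np.zeros(shape, dtype=np.int16)
    plane_shape = tuple(s for ax, s in enumerate(shape) if ax != plane_axis)
    for c in contours:
        if not c.is_simple():
            raise ValueError(f"self-intersecting contour on slice {c.slice_index}")
        rr, cc = draw.polygon(c.points[:, 0], c.points[:, 1], shape=plane_shape)
        sl = [slice(None)] * 3
        sl[plane_axis] = c.slice_index
        plane = labels[tuple(sl)]
        plane[rr, cc] = c.label
        labels[tuple(sl)] = plane
    if label_table is None:
        label_table = {int(v): f"label{int(v)}" for v in np.unique(labels) if v != 0}
    return LabelMask(labels, label_table, spacing=spacing, origin=origin)


def manual_contour_ingest(data, plane_axis: int = 2) -> List[SliceContour]:
    """Validate manually drawn polylines (JSON object, path or dict).

    Expected schema::

        {"object_id": str, "label": int,
         "slices": [{"index": int, "points": [[r, c], ...]}, ...]}

    Every point is flagged user-drawn. Degenerate (< 3 point) polylines are
    rejected.
    """
    if isinstance(data, (str, bytes)) or hasattr(data, "read"):
        if hasattr(data, "read"):
            data = json.load(data)
        else:
            with open(data) as f:
                data = json.load(f)
    contours = []
    for entry in data["slices"]:
        pts = np.asarray(entry["points"], dtype=float)
        if len(pts) >= 2 and np.allclose(pts[0], pts[-1]):
            pts = pts[:-1]
        if pts.ndim != 2 or len(pts) < 3:
            raise ValueError(
                f"slice {entry['index']}: polyline must have at least 3 points"
            )
        sc = SliceContour(int(entry["index"]), pts,
                          [FLAG_DRAWN] * len(pts), plane_axis=plane_axis,
                          object_id=str(data.get("object_id", "manual")),
                          label=int(data.get("label", 1)))
        if not sc.is_simple():
            raise ValueError(f"slice {entry['index']}: self-intersecting polyline")
        contours.append(sc)
    return contours


def contours_to_json(contours: List[SliceContour]) -> Dict:
    by_object: Dict[str, Dict] = {}
    for c in contours:
        obj = by_object.setdefault(
            c.object_id, {"object_id": c.object_id, "label": c.label, "slices": []}
        )
        obj["slices"].append({
            "index": c.slice_index,
            "points": c.points.tolist(),
            "flags": list(c.flags),
            "retained_percent": c.retained_percent,
        })
    return {"objects": list(by_object.values())}


def contours_from_json(data) -> List[SliceContour]:
    if isinstance(data, (str, bytes)):
        with open(data) as f:
            data = json.load(f)
    contours = []
    for obj in data["objects"]:
        for s in obj["slices"]:
            contours.append(SliceContour(
                int(s["index"]), np.asarray(s["points"], dtype=float),
                list(s.get("flags") or [FLAG_ORIGINAL] * len(s["points"])),
                object_id=obj["object_id"], label=int(obj["label"]),
                retained_percent=float(s.get("retained_percent", 100.0)),
            ))
    return contours
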