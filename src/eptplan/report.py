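"""Treatment-report rendering and field overlays.

The report is a self-contained HTML document (PDF export optional) with four
content panels: (A) orthogonal model views with electrode positions, (B) the
per-pair voltage table, (C) cumulative coverage curves for the target, and
(D) field-distribution overlays on the original slices, plus the table of
reversibly/irreversibly treated volumes per tissue. All numbers come from
the plan bundle verbatim — nothing is recomputed at render time — and the
output is byte-deterministic for fixed inputs.
"""

from __future__ import annotations

import base64
import io
from dataclasses import dataclass, field
from typing import Dict, List, Tuple

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
from skimage import measure

from .core import ImageVolume, LabelMask
from .coverage_planner import CoverageCurve, VoltagePlan
from .electrode_model import ElectrodeArray
from .field_solver import FieldSolution, PulseProtocol

__all__ = [
    "TreatmentPlanBundle",
    "overlay_field_slice",
    "field_iso_contours",
    "render_treatment_report",
]


@dataclass
class TreatmentPlanBundle:
    """Everything the report needs, geometry-consistent by construction."""

    case_id: str
    volume: ImageVolume
    masks: LabelMask
    array: ElectrodeArray
    plan: VoltagePlan
    solution: FieldSolution
    curves: Dict[str, CoverageCurve]
    protocol: PulseProtocol
    thresholds: Dict[str, Tuple[float, float]]
    treated_volumes_mm3: Dict[str, Dict[str, float]] = field(default_factory=dict)

    def __post_init__(self):
        if self.volume.shape != self.masks.shape:
            raise ValueError("volume and mask grids differ")
        if self.solution is not None and \
                self.solution.cumulative_field.shape != self.volume.shape:
            raise ValueError("field map not aligned to the volume")


def field_iso_contours(E_slice: np.ndarray, threshold: float) -> List[np.ndarray]:
    """Iso-lines of a field slice at one threshold, in pixel coordinates."""
    padded = np.pad(E_slice, 1, mode="constant")
    return [ring - 1.0 for ring in measure.find_contours(padded, threshold)]


def _to_gray_rgb(slice2d: np.ndarray) -> np.ndarray:
    lo, hi = float(slice2d.min()), float(slice2d.max())
    span = hi - lo if hi > lo else 1.0
    g = ((slice2d - lo) / span * 255.0).astype(np.uint8)
    return np.stack([g, g, g], axis=-1)


def overlay_field_slice(vol: ImageVolume, E: np.ndarray, slice_index: int,
                        thresholds: Tuple[float, float] = None,
                        scale: int = 2, max_alpha: float = 0.6,
                        plane_axis: int = 2) -> np.ndarray:
    """Anatomy slice with a semi-transparent field colormap and iso-lines.

    Alpha is proportional to the local field, so zero-field pixels show the
    unmodified grayscale anatomy. Iso-contour lines are drawn at the
    reversible and irreversible thresholds if given. Output is an RGB uint8
    array of the slice dimensions times ``scale``.
    """
    nslices = vol.shape[plane_axis]
    if not (0 <= slice_index < nslices):
        raise IndexError(f"slice {slice_index} out of range [0, {nslices})")
    base = np.take(vol.voxels, slice_index, axis=plane_axis)
    e2d = np.take(E, slice_index, axis=plane_axis)

    rgb = _to_gray_rgb(base).astype(np.float64)
    emax = float(E.max()) if E.max() > 0 else 1.0
    cmap = plt.get_cmap("jet")
    colored = cmap(np.clip(e2d / emax, 0, 1))[..., :3] * 255.0
    alpha = np.clip(e2d / emax, 0, 1) * max_alpha
    rgb = rgb * (1 - alpha[..., None]) + colored * alpha[..., None]

    out = np.repeat(np.repeat(rgb, scale, axis=0), scale, axis=1)
    if thresholds is not None:
        for thr, color in zip(thresholds, ((255, 255, 255), (255, 0, 0))):
            for ring in field_iso_contours(e2d, thr):
                rr = np.clip((ring[:, 0] * scale).astype(int), 0, out.shape[0] - 1)
                cc = np.clip((ring[:, 1] * scale).astype(int), 0, out.shape[1] - 1)
                out[rr, cc] = color
    return out.astype(np.uint8)


def _png_data_uri(fig) -> str:
    buf = io.BytesIO()
    fig.savefig(buf, format="png", dpi=100, metadata={"Software": None})
    plt.close(fig)
    return "data:image/png;base64," + base64.b64encode(buf.getvalue()).decode()


def _array_png_uri(img: np.ndarray) -> str:
    fig, ax = plt.subplots(figsize=(img.shape[1] / 100, img.shape[0] / 100), dpi=100)
    ax.imshow(img)
    ax.axis("off")
    fig.subplots_adjust(0, 0, 1, 1)
    return _png_data_uri(fig)


def _panel_a(bundle: TreatmentPlanBundle) -> str:
    """Orthogonal mid-views of the labels with projected needle tips."""
    labels = bundle.masks.labels
    tips_idx = (bundle.array.tips_mm - np.asarray(bundle.masks.origin)) / \
        np.asarray(bundle.masks.spacing)
    fig, axes = plt.subplots(1, 3, figsize=(9, 3))
    for ax_i, (a, b, axis) in zip(axes, [(0, 1, 2), (0, 2, 1), (1, 2, 0)]):
        mid = labels.shape[axis] // 2
        ax_i.imshow(np.take(labels, mid, axis=axis).T, origin="lower",
                    cmap="tab10", interpolation="nearest", vmin=0, vmax=9)
        ax_i.plot(tips_idx[:, a], tips_idx[:, b], "k^", markersize=6)
        ax_i.set_title(f"axis {axis} mid-slice")
    fig.tight_layout()
    return _png_data_uri(fig)


def _panel_c(bundle: TreatmentPlanBundle) -> str:
    fig, ax = plt.subplots(figsize=(5, 3.5))
    for name, curve in sorted(bundle.curves.items()):
        ax.plot(curve.thresholds, curve.fractions * 100.0, label=name)
    ax.set_xlabel("electric field threshold (V/cm)")
    ax.set_ylabel("volume coverage (%)")
    ax.legend()
    fig.tight_layout()
    return _png_data_uri(fig)


def _panel_d(bundle: TreatmentPlanBundle, n_slices: int = 3) -> List[str]:
    E = bundle.solution.cumulative_field
    target = bundle.masks.labels == _target_label(bundle)
    ks = sorted({int(k) for k in np.linspace(
        *_slice_span(target), n_slices)}) if target.any() else \
        [bundle.volume.shape[2] // 2]
    thr = bundle.thresholds.get("tumor", bundle.thresholds.get("default"))
    return [_array_png_uri(
        overlay_field_slice(bundle.volume, E, k, thresholds=thr)) for k in ks]


def _target_label(bundle: TreatmentPlanBundle) -> int:
    for lab, name in bundle.masks.label_table.items():
        if name == "tumor":
            return lab
    return max(bundle.masks.label_table, default=1)


def _slice_span(mask3d: np.ndarray):
    ks = np.flatnonzero(mask3d.any(axis=(0, 1)))
    return int(ks.min()), int(ks.max())


_TEMPLATE = """<!DOCTYPE html>
<html><head><meta charset="utf-8"><title>Treatment report — {case_id}</title>
<style>body{{font-family:sans-serif;max-width:900px;margin:auto}}
table{{border-collapse:collapse}}td,th{{border:1px solid #999;padding:4px 10px}}
section{{margin:2em 0}}</style></head><body>
<h1>Treatment report — case {case_id}</h1>
<p>Protocol: {mode}, {count} pulses × {dur:g} µs @ {freq:g} Hz.
Plan {feasible}; target coverage at reversible threshold: {coverage:.1f}%.</p>
<section id="panel-A"><h2>A. Model and electrode positions</h2>
<img src="{panel_a}" alt="model views"/></section>
<section id="panel-B"><h2>B. Optimal voltages per electrode pair</h2>
<table><tr><th>pair</th><th>needles</th><th>voltage (V)</th></tr>
{voltage_rows}
</table></section>
<section id="panel-C"><h2>C. Cumulative coverage curves</h2>
<img src="{panel_c}" alt="coverage curves"/></section>
<section id="panel-D"><h2>D. Electric field overlays</h2>
{overlays}</section>
<section id="volumes"><h2>Treated volumes per tissue</h2>
<table><tr><th>tissue</th><th>reversible (mm³)</th><th>irreversible (mm³)</th></tr>
{volume_rows}
</table></section>
</body></html>
"""


def render_treatment_report(bundle: TreatmentPlanBundle, path) -> str:
    """Write the report as self-contained HTML; returns the path."""
    if bundle.plan is None or bundle.solution is None:
        raise ValueError("bundle is missing the plan or the field solution")
    voltage_rows = "\n".join(
        f"<tr><td>{k + 1}</td><td>{i}–{j}</td><td>{v:.0f}</td></tr>"
        for k, ((i, j), v) in enumerate(zip(bundle.plan.pairs,
                                            bundle.plan.voltages))
    )
    volume_rows = "\n".join(
        f"<tr><td>{name}</td><td>{vols.get('reversible_mm3', 0.0):.0f}</td>"
        f"<td>{vols.get('irreversible_mm3', 0.0):.0f}</td></tr>"
        for name, vols in sorted(bundle.treated_volumes_mm3.items())
    )
    overlays = "\n".join(f'<img src="{uri}" alt="field overlay"/>'
                         for uri in _panel_d(bundle))
    html = _TEMPLATE.format(
        case_id=bundle.case_id,
        mode=bundle.protocol.mode, count=bundle.protocol.pulse_count,
        dur=bundle.protocol.pulse_duration_us, freq=bundle.protocol.frequency_hz,
        feasible="is feasible" if bundle.plan.feasible else "is NOT feasible",
        coverage=bundle.plan.target_coverage * 100.0,
        panel_a=_panel_a(bundle), voltage_rows=voltage_rows,
        panel_c=_panel_c(bundle), overlays=overlays, volume_rows=volume_rows,
    )
    with open(path, "w") as f:
        f.write(html)
    return str(path)


def treated_volumes(solution: FieldSolution, masks: LabelMask,
                    thresholds: Dict[str, Tuple[float, float]]) -> Dict[str, Dict[str, float]]:
    """Per-tissue volumes at or above the reversible/irreversible thresholds."""
    voxel = masks.voxel_volume_mm3()
    out = {}
    for lab, name in masks.label_table.items():
        sel = masks.labels == lab
        if not sel.any():
            continue
        e_rev, e_irr = thresholds.get(name, thresholds.get("default", (400.0, 800.0)))
        vals = solution.cumulative_field[sel]
        out[name] = {
            "reversible_mm3": float(np.count_nonzero(vals >= e_rev)) * voxel,
            "irreversible_mm3": float(np.count_nonzero(vals >= e_irr)) * voxel,
        }
    return out
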