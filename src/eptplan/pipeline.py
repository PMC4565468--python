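"""Procedure orchestration: ordered stages from import to report.

A procedure is a list of named stages with parameters (YAML/JSON on the
CLI). Each stage declares the state keys it requires and provides, so a
mis-ordered procedure fails up front with an error naming both stages.
Segmentation results are cached in the work directory keyed by a content
hash of the stage inputs; re-running a procedure reuses them.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Dict

import numpy as np

from . import phantoms, segmentation, volume_io
from .contour_model import (apply_edits, contours_from_json, ContourEdit,
                            extract_slice_contours, rasterize_contours)
from .coverage_planner import PlannerConstraints, cumulative_coverage_curve, \
    optimize_pair_voltages
from .core import ImageVolume, LabelMask
from .electrode_model import get_spec, place_parallel_array, rasterize_electrodes
from .field_solver import default_protocols, load_tissue_config, \
    properties_by_label, protocol_thresholds, solve_sequence
from .report import TreatmentPlanBundle, render_treatment_report, treated_volumes

log = logging.getLogger("eptplan.pipeline")

__all__ = ["run_procedure", "STAGES"]

MERGED_LABELS = {"liver": 1, "vessel": 2, "tumor": 3, "bone": 4, "brain": 5}


def _content_hash(*parts) -> str:
    h = hashlib.sha256()
    for p in parts:
        if isinstance(p, np.ndarray):
            h.update(p.tobytes())
        else:
            h.update(json.dumps(p, sort_keys=True, default=str).encode())
    return h.hexdigest()[:16]


def _merge_mask(state, name: str, mask: LabelMask):
    lab = MERGED_LABELS[name]
    if "masks" not in state:
        state["masks"] = LabelMask(
            np.zeros(mask.shape, dtype=np.int16), {},
            spacing=mask.spacing, origin=mask.origin,
        )
    merged = state["masks"]
    merged.labels[mask.labels > 0] = lab
    merged.label_table[lab] = name
    state["masks"] = LabelMask(merged.labels, merged.label_table,
                               spacing=merged.spacing, origin=merged.origin)


def _stage_phantom(state, params, workdir):
    spec = phantoms.PhantomSpec(**params.get("spec", {}))
    vol, truth = phantoms.generate_abdomen_phantom(spec)
    state["volume"] = vol
    state["truth"] = truth
    for lab, name in truth.label_table.items():
        sub = LabelMask((truth.labels == lab).astype(np.int16), {1: name},
                        spacing=truth.spacing, origin=truth.origin)
        if params.get("use_truth_masks", False):
            _merge_mask(state, name, sub)


def _stage_import(state, params, workdir):
    state["volume"] = volume_io.read_dicom_series(params["path"])


def _stage_anonymize(state, params, workdir):
    volume_io.anonymize_dicom(params["src"], params["dst"],
                              overwrite=params.get("overwrite", False))


def _stage_segment(state, params, workdir):
    vol: ImageVolume = state["volume"]
    target = params["target"]
    key = _content_hash(vol.voxels, {"target": target, **params})
    cache = Path(workdir) / f"segment_{target}_{key}.nii"
    if cache.exists():
        log.info("segment %s: cache hit (%s)", target, cache.name)
        mask = volume_io.read_mask(cache, expect_shape=vol.shape)
        state[f"cache_hit_{target}"] = True
    else:
        if target == "liver-ct":
            mask = segmentation.segment_liver_ct(vol)
        elif target == "liver-mri":
            mask = segmentation.segment_liver_mri(vol, tuple(params["seed"]))
        elif target == "vessels":
            liver = LabelMask(
                (state["masks"].labels == MERGED_LABELS["liver"]).astype(np.int16),
                {1: "liver"}, spacing=vol.spacing)
            mask = segmentation.segment_vessels(vol, liver)
        elif target == "bone":
            mask = segmentation.segment_bone_ct(vol)
        elif target == "brain":
            mask = segmentation.segment_canine_brain(vol)
        else:
            raise ValueError(f"unknown segmentation target {target!r}")
        volume_io.write_mask(mask, cache)
    name = {"liver-ct": "liver", "liver-mri": "liver"}.get(target, target)
    name = {"vessels": "vessel"}.get(name, name)
    _merge_mask(state, name, mask)


def _stage_manual_tumor(state, params, workdir):
    contours = contours_from_json(params["contours"])
    vol = state["volume"]
    for c in contours:
        c.label = MERGED_LABELS["tumor"]
    mask = rasterize_contours(contours, vol.shape, {MERGED_LABELS["tumor"]: "tumor"},
                              spacing=vol.spacing)
    sub = LabelMask((mask.labels > 0).astype(np.int16), {1: "tumor"},
                    spacing=vol.spacing)
    _merge_mask(state, "tumor", sub)


def _stage_validate(state, params, workdir):
    masks: LabelMask = state["masks"]
    tissue = params["tissue"]
    lab = masks.label_of(tissue)
    contours = extract_slice_contours(masks, lab)
    edits = [ContourEdit(**e) for e in params.get("edits", [])]
    edited = apply_edits(contours, edits)
    new_mask = rasterize_contours(edited, masks.shape, {lab: tissue},
                                  spacing=masks.spacing, origin=masks.origin)
    merged = masks.labels.copy()
    merged[masks.labels == lab] = 0
    merged[new_mask.labels > 0] = lab
    state["masks"] = LabelMask(merged, masks.label_table,
                               spacing=masks.spacing, origin=masks.origin)


def _stage_electrodes(state, params, workdir):
    spec = get_spec(params["spec_id"], params.get("catalog"))
    array = place_parallel_array(
        spec, params["entry_mm"], params["target_mm"],
        n_needles=params.get("n_needles", 2),
        spacing_mm=params.get("spacing_mm", 10.0),
        active_length_mm=params.get("active_length_mm"),
    )
    state["electrodes"] = array
    vol = state["volume"]
    state["electrode_labels"] = rasterize_electrodes(
        array, vol.shape, vol.spacing, vol.origin)


def _resolve_props(state, params):
    protocol = default_protocols(params.get("tissue_config"))[
        params.get("protocol", "ECT")]
    thresholds = protocol_thresholds(protocol, params.get("tissue_config"))
    tissue_table = load_tissue_config(protocol, params.get("tissue_config"))
    props = properties_by_label(state["masks"].label_table, tissue_table)
    return protocol, thresholds, props


def _stage_solve(state, params, workdir):
    protocol, thresholds, props = _resolve_props(state, params)
    array = state["electrodes"]
    vol = state["volume"]
    voltages = params.get("voltages") or [params.get("voltage", 1000.0)] * len(array.pairs)
    state["solution"] = solve_sequence(
        state["masks"].labels, state["electrode_labels"], array.pairs,
        voltages, props, vol.spacing)
    state["protocol"], state["thresholds"] = protocol, thresholds


def _stage_plan(state, params, workdir):
    protocol, thresholds, props = _resolve_props(state, params)
    masks: LabelMask = state["masks"]
    vol = state["volume"]
    target_name = params.get("target", "tumor")
    target_label = masks.label_of(target_name)
    target_mask = masks.labels == target_label
    e_rev = thresholds.get(target_name, thresholds.get("default"))[0]
    constraints = PlannerConstraints(**params.get("constraints", {}))
    plan = optimize_pair_voltages(
        masks.labels, state["electrode_labels"], state["electrodes"], props,
        target_mask, e_rev, vol.spacing, constraints,
        mask_table=masks.label_table, target_label=target_label,
        thresholds=thresholds)
    state["plan"] = plan
    state["solution"] = plan.solution
    state["protocol"], state["thresholds"] = protocol, thresholds
    state["curves"] = {
        target_name: cumulative_coverage_curve(plan.solution.cumulative_field,
                                               target_mask)
    }


def _stage_report(state, params, workdir):
    bundle = TreatmentPlanBundle(
        case_id=params.get("case_id", "case"),
        volume=state["volume"], masks=state["masks"],
        array=state["electrodes"], plan=state["plan"],
        solution=state["solution"], curves=state.get("curves", {}),
        protocol=state["protocol"], thresholds=state["thresholds"],
        treated_volumes_mm3=treated_volumes(state["solution"], state["masks"],
                                            state["thresholds"]),
    )
    out = Path(workdir) / params.get("filename", "treatment_report.html")
    render_treatment_report(bundle, out)
    state["bundle"] = bundle
    state["report_path"] = str(out)


STAGES: Dict[str, Dict] = {
    "phantom": {"fn": _stage_phantom, "requires": [], "provides": ["volume"]},
    "import": {"fn": _stage_import, "requires": [], "provides": ["volume"]},
    "anonymize": {"fn": _stage_anonymize, "requires": [], "provides": []},
    "segment": {"fn": _stage_segment, "requires": ["volume"], "provides": ["masks"]},
    "manual-tumor": {"fn": _stage_manual_tumor, "requires": ["volume"],
                     "provides": ["masks"]},
    "validate": {"fn": _stage_validate, "requires": ["masks"], "provides": ["masks"]},
    "electrodes": {"fn": _stage_electrodes, "requires": ["volume"],
                   "provides": ["electrodes", "electrode_labels"]},
    "solve": {"fn": _stage_solve,
              "requires": ["masks", "electrodes", "electrode_labels"],
              "provides": ["solution"]},
    "plan": {"fn": _stage_plan,
             "requires": ["masks", "electrodes", "electrode_labels"],
             "provides": ["plan", "solution", "curves"]},
    "report": {"fn": _stage_report,
               "requires": ["plan", "solution", "electrodes", "masks"],
               "provides": ["bundle"]},
}

_PROVIDER = {key: name for name, st in STAGES.items() for key in st["provides"]}


def run_procedure(config: Dict, workdir=None) -> Dict:
    """Execute an ordered stage list; returns the final pipeline state.

    ``config`` = ``{"case_id": ..., "stages": [{"name": ..., "params": {...}},
    ...]}``. Raises on unknown stages or on a stage whose required inputs
    were not produced by an earlier stage (the error names both stages).
    """
    workdir = Path(workdir or config.get("workdir", "."))
    workdir.mkdir(parents=True, exist_ok=True)
    state: Dict = {"case_id": config.get("case_id", "case")}
    for entry in config["stages"]:
        name = entry["name"] if isinstance(entry, dict) else entry
        params = entry.get("params", {}) if isinstance(entry, dict) else {}
        if name not in STAGES:
            raise ValueError(f"unknown stage {name!r}")
        stage = STAGES[name]
        for req in stage["requires"]:
            if req not in state:
                provider = _PROVIDER.get(req, "?")
                raise ValueError(
                    f"stage {name!r} requires {req!r} which is produced by "
                    f"stage {provider!r}; run {provider!r} first"
                )
        t0 = time.perf_counter()
        stage["fn"](state, params, workdir)
        log.info("stage %s finished in %.2f s", name, time.perf_counter() - t0)
    return state
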