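# eptplan

Treatment-planning toolkit for electroporation-based therapies
(electrochemotherapy and irreversible electroporation). It takes 3D medical
volumes from DICOM to a treatment report: automatic segmentation of the
target anatomy, contour-based validation and manual editing, parallel
needle-electrode placement from a two-point trajectory, nonlinear
electric-field computation with field-dependent tissue conductivity,
target-coverage analysis with per-pair voltage optimization, and report
generation.

Everything is testable offline: the `phantoms` module generates synthetic
CT/MRI volumes (ellipsoidal liver with a contrast vessel and spherical
tumor, bone rod, multi-slice brain/skull stack) with ground-truth masks.

## Modules

| module            | purpose |
|-------------------|---------|
| `phantoms`        | synthetic volumes + ground-truth masks for every stage |
| `volume_io`       | DICOM series import, anonymization, NIfTI/NRRD masks |
| `segmentation`    | liver (CT two-stage, MRI region-growing), hepatic vessels (multiscale Hessian tubularity + local thresholding), bone, canine brain |
| `contour_model`   | mask↔contour conversion, relevance-based point decimation (default 20% retained), cubic reconstruction of user edits |
| `electrode_model` | electrode catalog, parallel-array placement, obstacle clearance, conductor rasterization |
| `field_solver`    | finite-volume ∇·(σ∇u)=0 with σ(E) smoothstep, iterated to convergence per electrode pair, cumulative max-field map |
| `coverage_planner`| coverage fractions/curves, minimal-voltage search, needle-count escalation |
| `report` / `pipeline` / `cli` | HTML treatment report, staged procedure runner with caching, `eptplan` CLI |

## CLI

```sh
eptplan phantom --preset abdomen --out-volume vol.nii --out-mask truth.nii
eptplan import DICOM_DIR --out vol.nii
eptplan anonymize DICOM_DIR anonymized/
eptplan segment --target liver-ct --volume vol.nii --out liver.nii
eptplan segment --target vessels --volume vol.nii --liver-mask liver.nii --out vessels.nii
eptplan validate --mask liver.nii --percent 20 --out contours.json
eptplan electrodes --list
eptplan electrodes --spec-id variable-single --entry 60 60 0 --target 60 60 45 --out array.json
eptplan run procedure.yaml --workdir case01/
```

A procedure YAML lists ordered stages (`phantom`/`import`, `segment`,
`manual-tumor`, `validate`, `electrodes`, `solve`, `plan`, `report`) with
parameters; `run` validates stage dependencies, caches segmentation results
by content hash, and writes `treatment_report.html` with the electrode
views, the per-pair voltage table, cumulative coverage curves and field
overlays.

Tissue electrical properties and the pulse-protocol threshold tables live in
`src/eptplan/data/tissues.yaml`; the electrode catalog in
`src/eptplan/data/electrodes.yaml`. Both are editable configuration.

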