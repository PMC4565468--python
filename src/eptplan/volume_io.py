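"""Volume and mask I/O: DICOM series import, anonymization, NIfTI/NRRD masks.

DICOM handling is limited to uncompressed single-frame axial stacks
(Explicit VR Little Endian), which covers the synthetic series this package
writes and plain exported CT/MR slices. Masks and volumes interchange as
NIfTI, with the label table in a JSON sidecar.
"""

from __future__ import annotations

import json
import os
from pathlib import Path
from typing import List, Sequence

import nibabel as nib
import numpy as np

from . import _dicom
from .core import ImageVolume, LabelMask

__all__ = [
    "read_dicom_series",
    "write_dicom_series",
    "anonymize_dicom",
    "DEFAULT_ANONYMIZE_TAGS",
    "write_volume",
    "read_volume",
    "write_mask",
    "read_mask",
]

# Patient-identifying attributes removed by default. The identity of this
# list is a documented policy choice; callers may pass their own.
DEFAULT_ANONYMIZE_TAGS: List[str] = [
    "PatientName",
    "PatientID",
    "PatientBirthDate",
    "PatientSex",
    "PatientAge",
    "PatientAddress",
    "OtherPatientIDs",
    "ReferringPhysicianName",
    "PerformingPhysicianName",
    "OperatorsName",
    "InstitutionName",
    "InstitutionAddress",
    "AccessionNumber",
]


def _dicom_files(path) -> List[Path]:
    p = Path(path)
    files = sorted(f for f in p.iterdir() if f.is_file() and f.suffix.lower() == ".dcm")
    if not files:
        files = sorted(f for f in p.iterdir() if f.is_file())
    if not files:
        raise FileNotFoundError(f"no files in {path}")
    return files


def read_dicom_series(path) -> ImageVolume:
    """Read a single-series axial DICOM stack into an :class:`ImageVolume`.

    Slices are sorted by their position projected on the slice normal
    (file order on disk is irrelevant); CT values get rescale slope and
    intercept applied.
    """
    datasets = [_dicom.read_file(f) for f in _dicom_files(path)]

    uids = {ds.get_value("SeriesInstanceUID") for ds in datasets}
    if len(uids) > 1:
        raise ValueError(f"directory mixes {len(uids)} series: {sorted(map(str, uids))}")
    dims = {(ds.get_value("Rows"), ds.get_value("Columns")) for ds in datasets}
    if len(dims) > 1:
        raise ValueError(f"inconsistent in-plane dimensions across slices: {dims}")

    ds0 = datasets[0]
    pix_spacing = ds0.numbers("PixelSpacing")
    if pix_spacing is None:
        raise ValueError("missing PixelSpacing (0028,0030)")
    orient = ds0.numbers("ImageOrientationPatient") or [1, 0, 0, 0, 1, 0]
    row_dir = np.asarray(orient[:3])
    col_dir = np.asarray(orient[3:])
    normal = np.cross(row_dir, col_dir)

    positions = []
    for ds in datasets:
        ipp = ds.numbers("ImagePositionPatient")
        if ipp is None:
            raise ValueError("missing ImagePositionPatient (0020,0032)")
        positions.append(float(np.dot(ipp, normal)))
    order = np.argsort(positions)
    datasets = [datasets[i] for i in order]
    positions = [positions[i] for i in order]

    if len(datasets) > 1:
        slice_spacing = float(np.mean(np.diff(positions)))
        if slice_spacing <= 0:
            raise ValueError("non-increasing slice positions")
    else:
        st = ds0.numbers("SliceThickness") or ds0.numbers("SpacingBetweenSlices")
        if st is None:
            raise ValueError("missing SliceThickness (0018,0050) for single slice")
        slice_spacing = st[0]

    rows = int(ds0.get_value("Rows"))
    cols = int(ds0.get_value("Columns"))
    modality = str(ds0.get_value("Modality", "CT"))
    slices = []
    for ds in datasets:
        raw = ds.get_value("PixelData")
        signed = int(ds.get_value("PixelRepresentation", 1))
        dtype = np.int16 if signed else np.uint16
        arr = np.frombuffer(raw, dtype=dtype).reshape(rows, cols).astype(np.float64)
        slope = (ds.numbers("RescaleSlope") or [1.0])[0]
        intercept = (ds.numbers("RescaleIntercept") or [0.0])[0]
        if modality == "CT":
            arr = arr * slope + intercept
        # slice array is (rows, cols) = (y, x); volume stores (x, y, z)
        slices.append(arr.T)
    voxels = np.stack(slices, axis=2)

    origin = ds0.numbers("ImagePositionPatient")
    spacing = (pix_spacing[1], pix_spacing[0], slice_spacing)
    return ImageVolume(
        voxels, spacing=spacing, origin=tuple(origin),
        modality="MRI" if modality == "MR" else modality,
    )


def write_dicom_series(vol: ImageVolume, path, patient: dict = None,
                       series_uid: str = "1.2.826.0.1.3680043.9.9999.2.1",
                       prefix: str = "slice"):
    """Write a volume as one file per axial slice (testing / interchange)."""
    os.makedirs(path, exist_ok=True)
    patient = patient or {}
    nx, ny, nz = vol.shape
    data = np.rint(vol.voxels).astype(np.int16)
    modality = "MR" if vol.modality == "MRI" else vol.modality
    for k in range(nz):
        ds = _dicom.Dataset()
        ds.set_value("SOPClassUID",
                     _dicom.CT_STORAGE if modality == "CT" else _dicom.MR_STORAGE)
        ds.set_value("SOPInstanceUID", f"{series_uid}.{k + 1}")
        ds.set_value("SeriesInstanceUID", series_uid)
        ds.set_value("StudyInstanceUID", series_uid.rsplit(".", 1)[0])
        ds.set_value("Modality", modality)
        ds.set_value("SamplesPerPixel", 1)
        ds.set_value("PhotometricInterpretation", "MONOCHROME2")
        ds.set_value("Rows", ny)
        ds.set_value("Columns", nx)
        ds.set_value("PixelSpacing", [f"{vol.spacing[1]:g}", f"{vol.spacing[0]:g}"])
        ds.set_value("SliceThickness", f"{vol.spacing[2]:g}")
        ds.set_value("InstanceNumber", str(k + 1))
        pos = np.asarray(vol.origin) + np.array([0.0, 0.0, k * vol.spacing[2]])
        ds.set_value("ImagePositionPatient", [f"{v:g}" for v in pos])
        ds.set_value("ImageOrientationPatient", ["1", "0", "0", "0", "1", "0"])
        ds.set_value("BitsAllocated", 16)
        ds.set_value("BitsStored", 16)
        ds.set_value("HighBit", 15)
        ds.set_value("PixelRepresentation", 1)
        ds.set_value("RescaleSlope", "1")
        ds.set_value("RescaleIntercept", "0")
        for kw, val in patient.items():
            ds.set_value(kw, val)
        ds.set_value("PixelData", data[:, :, k].T.tobytes())
        _dicom.write_file(Path(path) / f"{prefix}_{k:04d}.dcm", ds)


def anonymize_dicom(src, dst, policy: Sequence[str] = None, overwrite: bool = False) -> int:
    """Strip patient-identifying attributes from DICOM file(s).

    ``src``/``dst`` may be single files or directories. Pixel data and
    geometry are untouched; the operation is idempotent. Returns the number
    of attributes removed.
    """
    policy = list(policy) if policy is not None else DEFAULT_ANONYMIZE_TAGS
    src, dst = Path(src), Path(dst)
    if src.is_dir():
        os.makedirs(dst, exist_ok=True)
        removed = 0
        for f in _dicom_files(src):
            removed += anonymize_dicom(f, dst / f.name, policy, overwrite)
        return removed
    if dst.exists() and not overwrite and dst.resolve() != src.resolve():
        raise FileExistsError(f"{dst} exists; pass overwrite=True")
    ds = _dicom.read_file(src)
    removed = 0
    for kw in policy:
        tag = _dicom.KEYWORD_TO_TAG[kw]
        if tag in ds:
            del ds[tag]
            removed += 1
    _dicom.write_file(dst, ds)
    return removed


def _affine(spacing, origin):
    aff = np.eye(4)
    aff[:3, :3] = np.diag(spacing)
    aff[:3, 3] = origin
    return aff


def write_volume(vol: ImageVolume, path):
    img = nib.Nifti1Image(vol.voxels.astype(np.float32), _affine(vol.spacing, vol.origin))
    nib.save(img, str(path))


def read_volume(path, modality: str = "CT") -> ImageVolume:
    img = nib.load(str(path))
    aff = img.affine
    spacing = tuple(float(s) for s in np.abs(np.diag(aff)[:3]))
    origin = tuple(float(o) for o in aff[:3, 3])
    return ImageVolume(np.asarray(img.dataobj, dtype=np.float64),
                       spacing=spacing, origin=origin, modality=modality)


def write_mask(mask: LabelMask, path):
    """Write labels as NIfTI with the label table in a ``.labels.json`` sidecar."""
    img = nib.Nifti1Image(mask.labels.astype(np.int16), _affine(mask.spacing, mask.origin))
    nib.save(img, str(path))
    sidecar = _sidecar_path(path)
    with open(sidecar, "w") as f:
        json.dump({str(k): v for k, v in mask.label_table.items()}, f, indent=1)


def read_mask(path, expect_shape=None) -> LabelMask:
    p = str(path)
    if p.endswith(".nrrd"):
        labels, spacing, origin = _read_nrrd(p)
    else:
        img = nib.load(p)
        aff = img.affine
        spacing = tuple(float(s) for s in np.abs(np.diag(aff)[:3]))
        origin = tuple(float(o) for o in aff[:3, 3])
        labels = np.asarray(img.dataobj).astype(np.int16)
    if expect_shape is not None and tuple(labels.shape) != tuple(expect_shape):
        raise ValueError(
            f"mask shape {labels.shape} does not match expected {tuple(expect_shape)}"
        )
    sidecar = _sidecar_path(path)
    if os.path.exists(sidecar):
        with open(sidecar) as f:
            table = {int(k): v for k, v in json.load(f).items()}
    else:
        table = {int(v): f"label{int(v)}" for v in np.unique(labels) if v != 0}
    return LabelMask(labels, table, spacing=spacing, origin=origin)


def _sidecar_path(path) -> str:
    p = str(path)
    for suffix in (".nii.gz", ".nii", ".nrrd"):
        if p.endswith(suffix):
            return p[: -len(suffix)] + ".labels.json"
    return p + ".labels.json"


def _read_nrrd(path):
    """Tiny NRRD reader: raw-encoded, 3D, little endian."""
    with open(path, "rb") as f:
        header = {}
        magic = f.readline()
        if not magic.startswith(b"NRRD"):
            raise ValueError(f"{path}: not an NRRD file")
        while True:
            line = f.readline()
            if line in (b"\n", b"\r\n", b""):
                break
            text = line.decode().strip()
            if ":" in text and not text.startswith("#"):
                key, val = text.split(":", 1)
                header[key.strip()] = val.strip("= ").strip()
        sizes = [int(v) for v in header["sizes"].split()]
        dtype = np.dtype(header.get("type", "short"))
        if header.get("encoding", "raw") != "raw":
            raise ValueError("only raw NRRD encoding supported")
        data = np.frombuffer(f.read(), dtype=dtype)
    labels = data.reshape(sizes[::-1]).transpose().astype(np.int16)
    spacing = (1.0, 1.0, 1.0)
    if "spacings" in header:
        spacing = tuple(float(v) for v in header["spacings"].split())
    elif "space directions" in header:
        vecs = [v.strip("()") for v in header["space directions"].split(") (")]
        spacing = tuple(
            float(np.linalg.norm([float(x) for x in v.split(",")])) for v in vecs
        )
    origin = (0.0, 0.0, 0.0)
    if "space origin" in header:
        origin = tuple(
            float(x) for x in header["space origin"].strip("()").split(",")
        )
    return labels, spacing, origin
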