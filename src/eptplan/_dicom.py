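"""Minimal DICOM file codec (Explicit VR Little Endian, single-frame).

Supports exactly what the import/anonymize pipeline needs: reading and
writing uncompressed single-frame grayscale slices with their geometry,
rescale and patient-identity attributes. Sequences, compressed transfer
syntaxes and multi-frame objects are out of scope.
"""

from __future__ import annotations

import struct
from typing import Dict, Tuple

Tag = Tuple[int, int]

EXPLICIT_VR_LE = "1.2.840.10008.1.2.1"
CT_STORAGE = "1.2.840.10008.5.1.4.1.1.2"
MR_STORAGE = "1.2.840.10008.5.1.4.1.1.4"

# VRs with a 4-byte length field preceded by 2 reserved bytes
_LONG_VRS = {"OB", "OW", "OF", "SQ", "UT", "UN"}
_TEXT_VRS = {"AE", "AS", "CS", "DA", "DS", "DT", "IS", "LO", "LT", "PN", "SH",
             "ST", "TM", "UI", "UT"}

# tag -> VR for every attribute this package reads or writes
DICT: Dict[Tag, Tuple[str, str]] = {
    (0x0002, 0x0001): ("OB", "FileMetaInformationVersion"),
    (0x0002, 0x0002): ("UI", "MediaStorageSOPClassUID"),
    (0x0002, 0x0003): ("UI", "MediaStorageSOPInstanceUID"),
    (0x0002, 0x0010): ("UI", "TransferSyntaxUID"),
    (0x0002, 0x0012): ("UI", "ImplementationClassUID"),
    (0x0008, 0x0016): ("UI", "SOPClassUID"),
    (0x0008, 0x0018): ("UI", "SOPInstanceUID"),
    (0x0008, 0x0020): ("DA", "StudyDate"),
    (0x0008, 0x0030): ("TM", "StudyTime"),
    (0x0008, 0x0050): ("SH", "AccessionNumber"),
    (0x0008, 0x0060): ("CS", "Modality"),
    (0x0008, 0x0080): ("LO", "InstitutionName"),
    (0x0008, 0x0081): ("ST", "InstitutionAddress"),
    (0x0008, 0x0090): ("PN", "ReferringPhysicianName"),
    (0x0008, 0x1050): ("PN", "PerformingPhysicianName"),
    (0x0008, 0x1070): ("PN", "OperatorsName"),
    (0x0010, 0x0010): ("PN", "PatientName"),
    (0x0010, 0x0020): ("LO", "PatientID"),
    (0x0010, 0x0030): ("DA", "PatientBirthDate"),
    (0x0010, 0x0040): ("CS", "PatientSex"),
    (0x0010, 0x1000): ("LO", "OtherPatientIDs"),
    (0x0010, 0x1010): ("AS", "PatientAge"),
    (0x0010, 0x1040): ("LO", "PatientAddress"),
    (0x0018, 0x0050): ("DS", "SliceThickness"),
    (0x0018, 0x0088): ("DS", "SpacingBetweenSlices"),
    (0x0020, 0x000D): ("UI", "StudyInstanceUID"),
    (0x0020, 0x000E): ("UI", "SeriesInstanceUID"),
    (0x0020, 0x0013): ("IS", "InstanceNumber"),
    (0x0020, 0x0032): ("DS", "ImagePositionPatient"),
    (0x0020, 0x0037): ("DS", "ImageOrientationPatient"),
    (0x0028, 0x0002): ("US", "SamplesPerPixel"),
    (0x0028, 0x0004): ("CS", "PhotometricInterpretation"),
    (0x0028, 0x0010): ("US", "Rows"),
    (0x0028, 0x0011): ("US", "Columns"),
    (0x0028, 0x0030): ("DS", "PixelSpacing"),
    (0x0028, 0x0100): ("US", "BitsAllocated"),
    (0x0028, 0x0101): ("US", "BitsStored"),
    (0x0028, 0x0102): ("US", "HighBit"),
    (0x0028, 0x0103): ("US", "PixelRepresentation"),
    (0x0028, 0x1052): ("DS", "RescaleIntercept"),
    (0x0028, 0x1053): ("DS", "RescaleSlope"),
    (0x7FE0, 0x0010): ("OW", "PixelData"),
}

KEYWORD_TO_TAG = {kw: tag for tag, (_, kw) in DICT.items()}


class Dataset(dict):
    """Mapping of (group, element) -> (VR, decoded value).

    Text VRs decode to ``str`` (multi-valued backslash-joined), US/SS to int,
    OW/OB to ``bytes``.
    """

    def get_value(self, keyword, default=None):
        tag = KEYWORD_TO_TAG[keyword]
        if tag not in self:
            return default
        return self[tag][1]

    def set_value(self, keyword, value):
        tag = KEYWORD_TO_TAG[keyword]
        self[tag] = (DICT[tag][0], value)

    def numbers(self, keyword):
        """DS/IS attribute as a list of floats."""
        raw = self.get_value(keyword)
        if raw is None:
            return None
        return [float(v) for v in str(raw).split("\\") if v != ""]


def _encode_value(vr: str, value) -> bytes:
    if vr in ("OB", "OW", "UN"):
        data = bytes(value)
        if len(data) % 2:
            data += b"\x00"
        return data
    if vr == "US":
        vals = value if isinstance(value, (list, tuple)) else [value]
        return struct.pack(f"<{len(vals)}H", *[int(v) for v in vals])
    if vr == "SS":
        vals = value if isinstance(value, (list, tuple)) else [value]
        return struct.pack(f"<{len(vals)}h", *[int(v) for v in vals])
    if vr in _TEXT_VRS:
        if isinstance(value, (list, tuple)):
            value = "\\".join(str(v) for v in value)
        data = str(value).encode("ascii")
        if len(data) % 2:
            data += b"\x00" if vr == "UI" else b" "
        return data
    raise ValueError(f"unsupported VR {vr}")


def _decode_value(vr: str, data: bytes):
    if vr in ("OB", "OW", "UN"):
        return data
    if vr == "US":
        vals = struct.unpack(f"<{len(data) // 2}H", data)
        return vals[0] if len(vals) == 1 else list(vals)
    if vr == "SS":
        vals = struct.unpack(f"<{len(data) // 2}h", data)
        return vals[0] if len(vals) == 1 else list(vals)
    text = data.decode("ascii", errors="replace")
    return text.rstrip("\x00 ").strip()


def _write_element(out, tag: Tag, vr: str, data: bytes):
    out.write(struct.pack("<HH", tag[0], tag[1]))
    out.write(vr.encode("ascii"))
    if vr in _LONG_VRS:
        out.write(struct.pack("<HI", 0, len(data)))
    else:
        out.write(struct.pack("<H", len(data)))
    out.write(data)


def write_file(path, ds: Dataset):
    """Serialize a dataset as Explicit VR Little Endian Part-10 file."""
    meta = Dataset()
    meta[(0x0002, 0x0001)] = ("OB", b"\x00\x01")
    meta[(0x0002, 0x0002)] = ("UI", ds.get_value("SOPClassUID", CT_STORAGE))
    meta[(0x0002, 0x0003)] = ("UI", ds.get_value("SOPInstanceUID", "0"))
    meta[(0x0002, 0x0010)] = ("UI", EXPLICIT_VR_LE)
    meta[(0x0002, 0x0012)] = ("UI", "1.2.826.0.1.3680043.9.9999.1")

    import io

    meta_buf = io.BytesIO()
    for tag in sorted(meta):
        vr, value = meta[tag]
        _write_element(meta_buf, tag, vr, _encode_value(vr, value))
    meta_bytes = meta_buf.getvalue()

    with open(path, "wb") as f:
        f.write(b"\x00" * 128)
        f.write(b"DICM")
        # group length of the file meta group
        _write_element(f, (0x0002, 0x0000), "UL", struct.pack("<I", len(meta_bytes)))
        f.write(meta_bytes)
        for tag in sorted(ds):
            if tag[0] == 0x0002:
                continue
            vr, value = ds[tag]
            _write_element(f, tag, vr, _encode_value(vr, value))


def read_file(path) -> Dataset:
    """Parse an Explicit VR Little Endian Part-10 file."""
    with open(path, "rb") as f:
        blob = f.read()
    if blob[128:132] != b"DICM":
        raise ValueError(f"{path}: not a DICOM Part-10 file")
    ds = Dataset()
    pos = 132
    n = len(blob)
    while pos + 8 <= n:
        group, elem = struct.unpack_from("<HH", blob, pos)
        vr = blob[pos + 4 : pos + 6].decode("ascii")
        if vr in _LONG_VRS:
            (length,) = struct.unpack_from("<I", blob, pos + 8)
            data_start = pos + 12
        else:
            (length,) = struct.unpack_from("<H", blob, pos + 6)
            data_start = pos + 8
        if length == 0xFFFFFFFF:
            raise ValueError("undefined-length elements are not supported")
        data = blob[data_start : data_start + length]
        pos = data_start + length
        tag = (group, elem)
        if tag == (0x0002, 0x0000):
            continue
        known_vr = DICT.get(tag, (vr, None))[0]
        ds[tag] = (known_vr, _decode_value(known_vr, data))
    ts = ds.get((0x0002, 0x0010), (None, EXPLICIT_VR_LE))[1]
    if ts != EXPLICIT_VR_LE:
        raise ValueError(f"unsupported transfer syntax {ts}")
    return ds
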