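"""Minimal single-frame grayscale DICOM codec.

Scope: uncompressed Explicit VR Little Endian only — exactly the dialect
the package's own series writer emits plus the handful of tags the reader
needs (geometry, rescale, pixel data).  Not a general DICOM library.
"""
from __future__ import annotations

import struct
from typing import Any

import numpy as np

__all__ = ["read_dicom_file", "write_dicom_file", "EXPLICIT_VR_LE"]

EXPLICIT_VR_LE = "1.2.840.10008.1.2.1"
_SECONDARY_CAPTURE = "1.2.840.10008.5.1.4.1.1.7"

# VRs that use the 4-byte length form (2 reserved bytes + 32-bit length).
_LONG_VRS = {b"OB", b"OW", b"OF", b"SQ", b"UT", b"UN"}

# tag -> (name, vr)
TAGS = {
    (0x0008, 0x0016): ("SOPClassUID", b"UI"),
    (0x0008, 0x0018): ("SOPInstanceUID", b"UI"),
    (0x0020, 0x000D): ("StudyInstanceUID", b"UI"),
    (0x0020, 0x000E): ("SeriesInstanceUID", b"UI"),
    (0x0020, 0x0013): ("InstanceNumber", b"IS"),
    (0x0020, 0x0032): ("ImagePositionPatient", b"DS"),
    (0x0020, 0x0037): ("ImageOrientationPatient", b"DS"),
    (0x0018, 0x0050): ("SliceThickness", b"DS"),
    (0x0028, 0x0002): ("SamplesPerPixel", b"US"),
    (0x0028, 0x0010): ("Rows", b"US"),
    (0x0028, 0x0011): ("Columns", b"US"),
    (0x0028, 0x0030): ("PixelSpacing", b"DS"),
    (0x0028, 0x0100): ("BitsAllocated", b"US"),
    (0x0028, 0x0101): ("BitsStored", b"US"),
    (0x0028, 0x0102): ("HighBit", b"US"),
    (0x0028, 0x0103): ("PixelRepresentation", b"US"),
    (0x0028, 0x1052): ("RescaleIntercept", b"DS"),
    (0x0028, 0x1053): ("RescaleSlope", b"DS"),
    (0x7FE0, 0x0010): ("PixelData", b"OW"),
}
_NAME_TO_TAG = {name: (tag, vr) for tag, (name, vr) in TAGS.items()}


def _encode_value(vr: bytes, value: Any) -> bytes:
    if vr == b"US":
        return struct.pack("<H", int(value))
    if vr in (b"DS", b"IS"):
        if isinstance(value, (list, tuple, np.ndarray)):
            s = "\\".join(f"{v:.10g}" for v in value)
        elif isinstance(value, str):
            s = value
        else:
            s = f"{value:.10g}"
        b = s.encode("ascii")
        return b + b" " if len(b) % 2 else b
    if vr == b"UI":
        b = str(value).encode("ascii")
        return b + b"\x00" if len(b) % 2 else b
    if vr in (b"OW", b"OB"):
        b = bytes(value)
        return b + b"\x00" if len(b) % 2 else b
    raise ValueError(f"unsupported VR {vr!r}")


def _element(group: int, elem: int, vr: bytes, value: Any) -> bytes:
    payload = _encode_value(vr, value)
    head = struct.pack("<HH", group, elem) + vr
    if vr in _LONG_VRS:
        return head + b"\x00\x00" + struct.pack("<I", len(payload)) + payload
    return head + struct.pack("<H", len(payload)) + payload


def write_dicom_file(path, pixel_array: np.ndarray, *, pixel_spacing_mm: float,
                     slice_thickness_mm: float, position_mm: tuple,
                     instance_number: int, series_uid: str, study_uid: str,
                     sop_uid: str, rescale_slope: float = 1.0,
                     rescale_intercept: float = 0.0) -> None:
    """Write one unsigned 16-bit grayscale slice."""
    arr = np.asarray(pixel_array)
    if arr.ndim != 2:
        raise ValueError("pixel_array must be 2D")
    stored = np.round(arr).astype(np.uint16)

    meta_body = (
        _element(0x0002, 0x0001, b"OB", b"\x00\x01")
        + _element(0x0002, 0x0002, b"UI", _SECONDARY_CAPTURE)
        + _element(0x0002, 0x0003, b"UI", sop_uid)
        + _element(0x0002, 0x0010, b"UI", EXPLICIT_VR_LE)
    )
    group_length = (struct.pack("<HH", 0x0002, 0x0000) + b"UL"
                    + struct.pack("<H", 4) + struct.pack("<I", len(meta_body)))
    meta = group_length + meta_body

    body = b"".join([
        _element(0x0008, 0x0016, b"UI", _SECONDARY_CAPTURE),
        _element(0x0008, 0x0018, b"UI", sop_uid),
        _element(0x0020, 0x000D, b"UI", study_uid),
        _element(0x0020, 0x000E, b"UI", series_uid),
        _element(0x0020, 0x0013, b"IS", str(int(instance_number))),
        _element(0x0020, 0x0032, b"DS", position_mm),
        _element(0x0020, 0x0037, b"DS", (1, 0, 0, 0, 1, 0)),
        _element(0x0018, 0x0050, b"DS", slice_thickness_mm),
        _element(0x0028, 0x0002, b"US", 1),
        _element(0x0028, 0x0010, b"US", stored.shape[0]),
        _element(0x0028, 0x0011, b"US", stored.shape[1]),
        _element(0x0028, 0x0030, b"DS", (pixel_spacing_mm, pixel_spacing_mm)),
        _element(0x0028, 0x0100, b"US", 16),
        _element(0x0028, 0x0101, b"US", 16),
        _element(0x0028, 0x0102, b"US", 15),
        _element(0x0028, 0x0103, b"US", 0),
        _element(0x0028, 0x1052, b"DS", rescale_intercept),
        _element(0x0028, 0x1053, b"DS", rescale_slope),
        _element(0x7FE0, 0x0010, b"OW", stored.astype("<u2").tobytes()),
    ])
    with open(path, "wb") as fh:
        fh.write(b"\x00" * 128 + b"DICM" + meta + body)


def read_dicom_file(path) -> dict:
    """Parse one slice into ``{name: value}``; pixel data as uint16 array."""
    with open(path, "rb") as fh:
        raw = fh.read()
    if raw[128:132] != b"DICM":
        raise ValueError(f"{path}: not a DICOM file (missing DICM marker)")
    pos = 132
    out: dict[str, Any] = {}

    def read_element(pos: int) -> tuple[int, int, bytes, bytes]:
        group, elem = struct.unpack_from("<HH", raw, pos)
        vr = raw[pos + 4 : pos + 6]
        if vr in _LONG_VRS:
            (length,) = struct.unpack_from("<I", raw, pos + 8)
            start = pos + 12
        else:
            (length,) = struct.unpack_from("<H", raw, pos + 6)
            start = pos + 8
        return group, elem, vr, raw[start : start + length], start + length

    # file meta group
    while pos < len(raw):
        group, elem, vr, payload, nxt = read_element(pos)
        if group != 0x0002:
            break
        if (group, elem) == (0x0002, 0x0010):
            ts = payload.rstrip(b"\x00 ").decode("ascii")
            if ts != EXPLICIT_VR_LE:
                raise ValueError(f"unsupported transfer syntax {ts}")
        pos = nxt

    while pos < len(raw):
        group, elem, vr, payload, nxt = read_element(pos)
        name_vr = TAGS.get((group, elem))
        if name_vr is not None:
            name, _ = name_vr
            if vr in (b"DS", b"IS"):
                parts = payload.decode("ascii").strip("\x00 ").split("\\")
                vals = [float(p) for p in parts if p != ""]
                out[name] = vals[0] if len(vals) == 1 else vals
            elif vr == b"US":
                out[name] = struct.unpack("<H", payload)[0]
            elif vr == b"UI":
                out[name] = payload.rstrip(b"\x00 ").decode("ascii")
            elif vr == b"OW":
                out[name] = np.frombuffer(payload, dtype="<u2")
        pos = nxt

    for required in ("Rows", "Columns", "PixelData", "PixelSpacing",
                     "ImagePositionPatient"):
        if required not in out:
            raise ValueError(f"{path}: missing required tag {required}")
    out["PixelData"] = out["PixelData"][: out["Rows"] * out["Columns"]].reshape(
        out["Rows"], out["Columns"]
    )
    return out
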