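"""Minimal single-frame DICOM reader/writer.

Supports exactly what the pipeline needs: uncompressed little-endian
single-frame grayscale images with the acquisition tags TR/TE/TI/FA,
pixel spacing and rescale slope/intercept.  Files are written as
Explicit VR Little Endian; both Explicit and Implicit VR Little Endian
are accepted on read.  Anything else (compressed transfer syntaxes,
sequences with undefined length, multi-frame objects) is rejected.
"""

from __future__ import annotations

import hashlib
import struct
from typing import Dict, Optional, Tuple

import numpy as np

from qt1seg.exceptions import FormatError

_EXPLICIT_LE = "1.2.840.10008.1.2.1"
_IMPLICIT_LE = "1.2.840.10008.1.2"
_SC_SOP_CLASS = "1.2.840.10008.5.1.4.1.1.7"
_UID_ROOT = "1.2.826.0.1.3680043.8.498"

# VRs whose explicit encoding uses a 12-byte header (2-byte reserved + 4-byte length)
_LONG_VRS = {b"OB", b"OW", b"OF", b"SQ", b"UT", b"UN"}

TAG_SOP_CLASS = (0x0008, 0x0016)
TAG_SOP_INSTANCE = (0x0008, 0x0018)
TAG_MODALITY = (0x0008, 0x0060)
TAG_SERIES_DESC = (0x0008, 0x103E)
TAG_TR = (0x0018, 0x0080)
TAG_TE = (0x0018, 0x0081)
TAG_TI = (0x0018, 0x0082)
TAG_FA = (0x0018, 0x1314)
TAG_SAMPLES = (0x0028, 0x0002)
TAG_PHOTOMETRIC = (0x0028, 0x0004)
TAG_NFRAMES = (0x0028, 0x0008)
TAG_ROWS = (0x0028, 0x0010)
TAG_COLS = (0x0028, 0x0011)
TAG_SPACING = (0x0028, 0x0030)
TAG_BITS_ALLOC = (0x0028, 0x0100)
TAG_BITS_STORED = (0x0028, 0x0101)
TAG_HIGH_BIT = (0x0028, 0x0102)
TAG_PIXEL_REP = (0x0028, 0x0103)
TAG_INTERCEPT = (0x0028, 0x1052)
TAG_SLOPE = (0x0028, 0x1053)
TAG_PIXEL_DATA = (0x7FE0, 0x0010)


def _ds(value: float) -> bytes:
    """Encode a decimal string (DS), max 16 bytes."""
    s = f"{value:.10g}"[:16]
    if len(s) % 2:
        s += " "
    return s.encode("ascii")


def _str(value: str, pad: bytes = b" ") -> bytes:
    raw = value.encode("ascii")
    if len(raw) % 2:
        raw += pad
    return raw


def _element(group: int, elem: int, vr: bytes, value: bytes) -> bytes:
    if len(value) % 2:
        raise ValueError("element values must have even length")
    if vr in _LONG_VRS:
        return struct.pack("<HH2sHI", group, elem, vr, 0, len(value)) + value
    return struct.pack("<HH2sH", group, elem, vr, len(value)) + value


def write_dicom(
    path,
    pixels: np.ndarray,
    *,
    pixel_spacing: float = 1.0,
    tr: Optional[float] = None,
    te: Optional[float] = None,
    ti: Optional[float] = None,
    fa: Optional[float] = None,
    series_description: str = "other",
) -> None:
    """Write a single-frame grayscale DICOM (Explicit VR Little Endian).

    Float pixel values are quantized to 16-bit unsigned integers with a
    rescale slope/intercept chosen from the data range; integer-valued data
    in [0, 65535] round-trips exactly (slope 1, intercept 0).
    """
    pixels = np.asarray(pixels, dtype=np.float64)
    if pixels.ndim != 2:
        raise FormatError("only 2D single-frame images can be written")
    if not np.all(np.isfinite(pixels)):
        raise FormatError("pixel values must be finite")

    lo, hi = float(pixels.min()), float(pixels.max())
    integral = np.all(pixels == np.round(pixels))
    if integral and 0.0 <= lo and hi <= 65535.0:
        slope, intercept = 1.0, 0.0
        stored = pixels.astype(np.uint16)
    elif hi == lo:
        slope, intercept = 1.0, lo
        stored = np.zeros_like(pixels, dtype=np.uint16)
    else:
        slope = (hi - lo) / 65535.0
        intercept = lo
        stored = np.round((pixels - intercept) / slope).astype(np.uint16)

    rows, cols = pixels.shape
    pixel_bytes = stored.astype("<u2").tobytes()
    if len(pixel_bytes) % 2:  # cannot happen for u2, kept for clarity
        pixel_bytes += b"\x00"

    digest = hashlib.sha1(pixel_bytes).hexdigest()[:16]
    sop_instance = f"{_UID_ROOT}.{int(digest, 16)}"

    meta_body = b"".join(
        [
            _element(0x0002, 0x0001, b"OB", b"\x00\x01"),
            _element(0x0002, 0x0002, b"UI", _str(_SC_SOP_CLASS, b"\x00")),
            _element(0x0002, 0x0003, b"UI", _str(sop_instance, b"\x00")),
            _element(0x0002, 0x0010, b"UI", _str(_EXPLICIT_LE, b"\x00")),
        ]
    )
    meta = _element(0x0002, 0x0000, b"UL", struct.pack("<I", len(meta_body))) + meta_body

    elements = [
        _element(*TAG_SOP_CLASS, b"UI", _str(_SC_SOP_CLASS, b"\x00")),
        _element(*TAG_SOP_INSTANCE, b"UI", _str(sop_instance, b"\x00")),
        _element(*TAG_MODALITY, b"CS", _str("MR")),
        _element(*TAG_SERIES_DESC, b"LO", _str(series_description)),
    ]
    for tag, value in ((TAG_TR, tr), (TAG_TE, te), (TAG_TI, ti)):
        if value is not None:
            elements.append(_element(*tag, b"DS", _ds(value)))
    if fa is not None:
        elements.append(_element(*TAG_FA, b"DS", _ds(fa)))
    elements += [
        _element(*TAG_SAMPLES, b"US", struct.pack("<H", 1)),
        _element(*TAG_PHOTOMETRIC, b"CS", _str("MONOCHROME2")),
        _element(*TAG_ROWS, b"US", struct.pack("<H", rows)),
        _element(*TAG_COLS, b"US", struct.pack("<H", cols)),
        _element(*TAG_SPACING, b"DS", _str(f"{pixel_spacing:.8g}\\{pixel_spacing:.8g}")),
        _element(*TAG_BITS_ALLOC, b"US", struct.pack("<H", 16)),
        _element(*TAG_BITS_STORED, b"US", struct.pack("<H", 16)),
        _element(*TAG_HIGH_BIT, b"US", struct.pack("<H", 15)),
        _element(*TAG_PIXEL_REP, b"US", struct.pack("<H", 0)),
        _element(*TAG_INTERCEPT, b"DS", _ds(intercept)),
        _element(*TAG_SLOPE, b"DS", _ds(slope)),
        _element(*TAG_PIXEL_DATA, b"OW", pixel_bytes),
    ]

    with open(path, "wb") as fh:
        fh.write(b"\x00" * 128)
        fh.write(b"DICM")
        fh.write(meta)
        fh.write(b"".join(elements))


def _parse_elements(buf: bytes) -> Dict[Tuple[int, int], Tuple[Optional[bytes], bytes]]:
    """Parse the full element stream into {tag: (vr, raw_value)}."""
    n = len(buf)
    if n < 132 or buf[128:132] != b"DICM":
        raise FormatError("not a DICOM file (missing DICM marker)")
    pos = 132
    out: Dict[Tuple[int, int], Tuple[Optional[bytes], bytes]] = {}
    explicit = True  # file meta is always explicit
    transfer_syntax = _EXPLICIT_LE
    in_meta = True
    while pos + 8 <= n:
        group, elem = struct.unpack_from("<HH", buf, pos)
        if in_meta and group != 0x0002:
            in_meta = False
            if transfer_syntax == _IMPLICIT_LE:
                explicit = False
            elif transfer_syntax != _EXPLICIT_LE:
                raise FormatError(
                    f"unsupported transfer syntax {transfer_syntax!r}; "
                    "only uncompressed little-endian is handled"
                )
        if explicit or in_meta:
            vr = buf[pos + 4 : pos + 6]
            if vr in _LONG_VRS:
                (length,) = struct.unpack_from("<I", buf, pos + 8)
                pos += 12
            else:
                (length,) = struct.unpack_from("<H", buf, pos + 6)
                pos += 8
        else:
            vr = None
            (length,) = struct.unpack_from("<I", buf, pos + 4)
            pos += 8
        if length == 0xFFFFFFFF:
            raise FormatError("undefined-length elements are not supported")
        if pos + length > n:
            raise FormatError("truncated DICOM element")
        value = buf[pos : pos + length]
        pos += length
        out[(group, elem)] = (vr, value)
        if (group, elem) == (0x0002, 0x0010):
            transfer_syntax = value.rstrip(b"\x00 ").decode("ascii")
    return out


def _get_float(elements, tag) -> Optional[float]:
    entry = elements.get(tag)
    if entry is None:
        return None
    raw = entry[1].rstrip(b"\x00 ").split(b"\\")[0]
    if not raw:
        return None
    return float(raw)


def _get_ushort(elements, tag) -> Optional[int]:
    entry = elements.get(tag)
    if entry is None:
        return None
    return struct.unpack("<H", entry[1][:2])[0]


def _get_str(elements, tag) -> Optional[str]:
    entry = elements.get(tag)
    if entry is None:
        return None
    return entry[1].rstrip(b"\x00 ").decode("ascii", errors="replace").strip()


def read_dicom(path) -> dict:
    """Read a single-frame DICOM; returns a dict of decoded fields.

    Keys: ``pixels`` (float64 array with rescale applied), ``pixel_spacing``,
    ``tr``, ``te``, ``ti``, ``fa``, ``series_description``, ``modality``.
    """
    with open(path, "rb") as fh:
        buf = fh.read()
    elements = _parse_elements(buf)

    nframes = _get_str(elements, TAG_NFRAMES)
    if nframes is not None and int(nframes) > 1:
        raise FormatError(f"multi-frame DICOM ({nframes} frames) is not supported")
    if TAG_PIXEL_DATA not in elements:
        raise FormatError("DICOM file has no PixelData element")

    rows = _get_ushort(elements, TAG_ROWS)
    cols = _get_ushort(elements, TAG_COLS)
    if not rows or not cols:
        raise FormatError("missing Rows/Columns")
    bits = _get_ushort(elements, TAG_BITS_ALLOC) or 16
    signed = (_get_ushort(elements, TAG_PIXEL_REP) or 0) == 1
    dtype = {(8, False): "u1", (8, True): "i1", (16, False): "<u2", (16, True): "<i2"}.get(
        (bits, signed)
    )
    if dtype is None:
        raise FormatError(f"unsupported BitsAllocated={bits}")

    raw = elements[TAG_PIXEL_DATA][1]
    expected = rows * cols * (bits // 8)
    if len(raw) < expected:
        raise FormatError("PixelData shorter than Rows*Columns")
    stored = np.frombuffer(raw[:expected], dtype=dtype).reshape(rows, cols)

    slope = _get_float(elements, TAG_SLOPE)
    intercept = _get_float(elements, TAG_INTERCEPT)
    pixels = stored.astype(np.float64)
    if slope is not None or intercept is not None:
        pixels = pixels * (slope if slope is not None else 1.0) + (
            intercept if intercept is not None else 0.0
        )

    spacing_entry = elements.get(TAG_SPACING)
    spacing = 1.0
    if spacing_entry is not None:
        first = spacing_entry[1].rstrip(b"\x00 ").split(b"\\")[0]
        if first:
            spacing = float(first)

    return {
        "pixels": pixels,
        "pixel_spacing": spacing,
        "tr": _get_float(elements, TAG_TR),
        "te": _get_float(elements, TAG_TE),
        "ti": _get_float(elements, TAG_TI),
        "fa": _get_float(elements, TAG_FA),
        "series_description": _get_str(elements, TAG_SERIES_DESC),
        "modality": _get_str(elements, TAG_MODALITY),
    }
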