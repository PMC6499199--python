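"""Minimal LAS 1.2 reader/writer (point record formats 0 and 1).

Only the fields this pipeline uses are honoured: x, y, z (int32 with
scale/offset) and intensity (uint16). Everything else in the point record
is written as zero and ignored on read. Coordinates are de-quantized to
float64 meters at this boundary so downstream analysis never sees the
integer grid.
"""
from __future__ import annotations

import struct

import numpy as np

_HEADER_FMT = "<4sHH16sBB32s32sHHHIIBHI5I12d"
_HEADER_SIZE = struct.calcsize(_HEADER_FMT)  # 227 bytes, LAS 1.2
assert _HEADER_SIZE == 227

_POINT_DTYPE_0 = np.dtype(
    [
        ("X", "<i4"),
        ("Y", "<i4"),
        ("Z", "<i4"),
        ("intensity", "<u2"),
        ("flags", "u1"),
        ("classification", "u1"),
        ("scan_angle", "i1"),
        ("user_data", "u1"),
        ("point_source", "<u2"),
    ]
)
_POINT_DTYPE_1 = np.dtype(_POINT_DTYPE_0.descr + [("gps_time", "<f8")])

#: half of the default coordinate quantization step
DEFAULT_SCALE = 1e-4


class LASParseError(ValueError):
    pass


def write_las(path, coords: np.ndarray, intensity: np.ndarray | None, scale: float = DEFAULT_SCALE) -> None:
    coords = np.asarray(coords, dtype=np.float64).reshape(-1, 3)
    n = coords.shape[0]
    if n:
        mins = coords.min(axis=0)
        maxs = coords.max(axis=0)
    else:
        mins = maxs = np.zeros(3)
    offset = np.floor(mins)
    rec = np.zeros(n, dtype=_POINT_DTYPE_0)
    quant = np.round((coords - offset) / scale)
    if n and (np.abs(quant) > 2**31 - 1).any():
        raise ValueError("coordinate range too large for LAS int32 records at this scale")
    rec["X"], rec["Y"], rec["Z"] = quant[:, 0], quant[:, 1], quant[:, 2]
    if intensity is not None:
        inten = np.asarray(intensity)
        if inten.shape != (n,):
            raise ValueError("intensity length mismatch")
        if inten.size and ((inten < 0).any() or (inten > 65535).any()):
            raise ValueError("LAS intensity must lie in [0, 65535]")
        rec["intensity"] = np.round(inten).astype(np.uint16)
    header = struct.pack(
        _HEADER_FMT,
        b"LASF",
        0,
        0,
        b"\0" * 16,
        1,
        2,
        b"tlstrack".ljust(32, b"\0"),
        b"tlstrack".ljust(32, b"\0"),
        0,
        0,
        _HEADER_SIZE,
        _HEADER_SIZE,
        0,
        0,
        _POINT_DTYPE_0.itemsize,
        n,
        n, 0, 0, 0, 0,
        scale, scale, scale,
        offset[0], offset[1], offset[2],
        maxs[0], mins[0], maxs[1], mins[1], maxs[2], mins[2],
    )
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(rec.tobytes())


def read_las(path):
    """Return ``(coords, intensity)``; intensity is always present in LAS records."""
    with open(path, "rb") as fh:
        raw = fh.read(_HEADER_SIZE)
        if len(raw) < _HEADER_SIZE:
            raise LASParseError(f"{path}: truncated LAS header")
        fields = struct.unpack(_HEADER_FMT, raw)
        if fields[0] != b"LASF":
            raise LASParseError(f"{path}: missing LASF signature")
        point_fmt = fields[13]
        rec_len = fields[14]
        n = fields[15]
        offset_to_points = fields[11]
        scales = np.array(fields[21:24])
        offsets = np.array(fields[24:27])
        if point_fmt == 0:
            dtype = _POINT_DTYPE_0
        elif point_fmt == 1:
            dtype = _POINT_DTYPE_1
        else:
            raise LASParseError(f"{path}: unsupported LAS point format {point_fmt}")
        if rec_len < dtype.itemsize:
            raise LASParseError(f"{path}: point record length {rec_len} too short for format {point_fmt}")
        fh.seek(offset_to_points)
        buf = fh.read(n * rec_len)
    if len(buf) < n * rec_len:
        got = len(buf) // rec_len
        raise LASParseError(f"{path}: truncated point data at record {got} of {n}")
    if rec_len == dtype.itemsize:
        rec = np.frombuffer(buf, dtype=dtype, count=n)
    else:  # extra bytes per record: view the leading standard fields
        padded = np.frombuffer(buf, dtype=np.uint8).reshape(n, rec_len)
        rec = padded[:, : dtype.itemsize].copy().view(dtype).reshape(n)
    coords = np.column_stack([rec["X"], rec["Y"], rec["Z"]]).astype(np.float64) * scales + offsets
    return coords, rec["intensity"].astype(np.float64)
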