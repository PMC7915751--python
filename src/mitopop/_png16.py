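"""Minimal 16-bit RGB PNG codec.

Pillow cannot round-trip 16-bit-per-sample RGB PNGs, so the pseudocolor
path uses this small codec: non-interlaced, color type 2, bit depth 16.
The writer emits filter type 0; the reader decodes all standard scanline
filters (0-4) of that pixel layout.
"""

from __future__ import annotations

import struct
import zlib

import numpy as np

_SIGNATURE = b"\x89PNG\r\n\x1a\n"


def _chunk(tag: bytes, payload: bytes) -> bytes:
    return (struct.pack(">I", len(payload)) + tag + payload
            + struct.pack(">I", zlib.crc32(tag + payload)))


def write_rgb16(path, rgb: np.ndarray) -> None:
    """Write an (H, W, 3) uint16 array as a 16-bit RGB PNG."""
    rgb = np.asarray(rgb)
    if rgb.ndim != 3 or rgb.shape[-1] != 3 or rgb.dtype != np.uint16:
        raise ValueError("expected an (H, W, 3) uint16 array")
    h, w = rgb.shape[:2]
    ihdr = struct.pack(">IIBBBBB", w, h, 16, 2, 0, 0, 0)
    raw = rgb.astype(">u2").tobytes()
    stride = w * 6
    scanlines = b"".join(
        b"\x00" + raw[y * stride:(y + 1) * stride] for y in range(h))
    with open(path, "wb") as fh:
        fh.write(_SIGNATURE)
        fh.write(_chunk(b"IHDR", ihdr))
        fh.write(_chunk(b"IDAT", zlib.compress(scanlines, 6)))
        fh.write(_chunk(b"IEND", b""))


def _unfilter(scanlines: bytes, h: int, stride: int, bpp: int) -> bytearray:
    out = bytearray(h * stride)
    pos = 0
    for y in range(h):
        ftype = scanlines[pos]
        pos += 1
        row = bytearray(scanlines[pos:pos + stride])
        pos += stride
        prev = out[(y - 1) * stride:y * stride] if y else bytes(stride)
        if ftype == 1:  # Sub
            for i in range(bpp, stride):
                row[i] = (row[i] + row[i - bpp]) & 0xFF
        elif ftype == 2:  # Up
            for i in range(stride):
                row[i] = (row[i] + prev[i]) & 0xFF
        elif ftype == 3:  # Average
            for i in range(stride):
                left = row[i - bpp] if i >= bpp else 0
                row[i] = (row[i] + ((left + prev[i]) >> 1)) & 0xFF
        elif ftype == 4:  # Paeth
            for i in range(stride):
                a = row[i - bpp] if i >= bpp else 0
                b = prev[i]
                c = prev[i - bpp] if i >= bpp else 0
                p = a + b - c
                pa, pb, pc = abs(p - a), abs(p - b), abs(p - c)
                pred = a if pa <= pb and pa <= pc else (b if pb <= pc else c)
                row[i] = (row[i] + pred) & 0xFF
        elif ftype != 0:
            raise ValueError(f"unsupported PNG filter type {ftype}")
        out[y * stride:(y + 1) * stride] = row
    return out


def read_rgb16(path) -> np.ndarray:
    """Read a non-interlaced 16-bit RGB PNG into an (H, W, 3) uint16 array."""
    with open(path, "rb") as fh:
        data = fh.read()
    if not data.startswith(_SIGNATURE):
        raise ValueError("not a PNG file")
    pos = len(_SIGNATURE)
    idat = b""
    w = h = None
    while pos < len(data):
        (length,) = struct.unpack(">I", data[pos:pos + 4])
        tag = data[pos + 4:pos + 8]
        payload = data[pos + 8:pos + 8 + length]
        pos += 12 + length
        if tag == b"IHDR":
            w, h, depth, ctype, _, _, interlace = struct.unpack(">IIBBBBB", payload)
            if depth != 16 or ctype != 2 or interlace != 0:
                raise ValueError(
                    "only non-interlaced 16-bit RGB PNGs are supported")
        elif tag == b"IDAT":
            idat += payload
        elif tag == b"IEND":
            break
    if w is None:
        raise ValueError("missing IHDR chunk")
    stride = w * 6
    raw = _unfilter(zlib.decompress(idat), h, stride, bpp=6)
    return np.frombuffer(bytes(raw), dtype=">u2").reshape(h, w, 3).astype(np.uint16)
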