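"""Minimal ImageJ ``.roi`` codec for polygon ROIs.

Implements just the slice of the ImageJ ROI binary format this package
needs: reading and writing closed polygon outlines, with sub-pixel float
coordinates when present.  Layout (big-endian):

====== ==========================================================
offset field
====== ==========================================================
0      magic ``Iout``
4      version (int16; >= 222 supports sub-pixel coordinates)
6      roi type (0 = polygon), 1 pad byte
8      top, left, bottom, right (4 x int16)
16     n_coordinates (int16)
50     options (int16; bit 7 = sub-pixel resolution)
64     x coords relative to left (n x int16), then y relative to top
...    optional sub-pixel block: absolute x then y as float32
====== ==========================================================
"""

from __future__ import annotations

import struct
from pathlib import Path

import numpy as np

from .errors import InvalidPolygonError

_MAGIC = b"Iout"
_VERSION = 227
_TYPE_POLYGON = 0
_OPT_SUBPIXEL = 128
_HEADER_SIZE = 64


def write_roi(path, vertices: np.ndarray, name: str = "") -> None:
    """Write an (n, 2) array of (x, y) vertices as an ImageJ polygon ROI."""
    v = np.asarray(vertices, dtype=float)
    if v.ndim != 2 or v.shape[1] != 2 or len(v) < 3:
        raise InvalidPolygonError("need an (n>=3, 2) vertex array")
    x, y = v[:, 0], v[:, 1]
    left, top = int(np.floor(x.min())), int(np.floor(y.min()))
    right, bottom = int(np.ceil(x.max())), int(np.ceil(y.max()))
    n = len(v)

    header = bytearray(_HEADER_SIZE)
    header[0:4] = _MAGIC
    struct.pack_into(">h", header, 4, _VERSION)
    header[6] = _TYPE_POLYGON
    struct.pack_into(">4h", header, 8, top, left, bottom, right)
    struct.pack_into(">h", header, 16, n)
    struct.pack_into(">h", header, 50, _OPT_SUBPIXEL)

    xi = np.round(x).astype(int) - left
    yi = np.round(y).astype(int) - top
    body = struct.pack(f">{n}h", *xi) + struct.pack(f">{n}h", *yi)
    sub = struct.pack(f">{n}f", *x) + struct.pack(f">{n}f", *y)
    Path(path).write_bytes(bytes(header) + body + sub)


def read_roi(path) -> np.ndarray:
    """Read a polygon ``.roi`` file back into an (n, 2) (x, y) array."""
    raw = Path(path).read_bytes()
    if raw[0:4] != _MAGIC:
        raise InvalidPolygonError(f"{path}: not an ImageJ ROI file")
    roi_type = raw[6]
    if roi_type != _TYPE_POLYGON:
        raise InvalidPolygonError(
            f"{path}: unsupported ROI type {roi_type} (only polygon)"
        )
    version = struct.unpack_from(">h", raw, 4)[0]
    top, left, _bottom, _right = struct.unpack_from(">4h", raw, 8)
    n = struct.unpack_from(">h", raw, 16)[0]
    options = struct.unpack_from(">h", raw, 50)[0]
    if n < 3:
        raise InvalidPolygonError(f"{path}: polygon with {n} vertices")

    int_block = _HEADER_SIZE + 4 * n
    if version >= 222 and (options & _OPT_SUBPIXEL) and len(raw) >= int_block + 8 * n:
        x = np.array(struct.unpack_from(f">{n}f", raw, int_block))
        y = np.array(struct.unpack_from(f">{n}f", raw, int_block + 4 * n))
    else:
        xi = struct.unpack_from(f">{n}h", raw, _HEADER_SIZE)
        yi = struct.unpack_from(f">{n}h", raw, _HEADER_SIZE + 2 * n)
        x = np.array(xi, dtype=float) + left
        y = np.array(yi, dtype=float) + top
    return np.column_stack([x, y])
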