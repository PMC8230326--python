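"""Minimal reader/writer for ImageJ ROI outlines.

Supports the subset of the ImageJ ``.roi`` binary layout used for manual
nucleus annotation — polygon, freehand, traced, rectangle and oval ROIs —
plus ``.zip`` archives of many ROIs.  Coordinates are returned as closed
(y, x) pixel polygons in row-major image convention (origin top-left).

Layout (big-endian): bytes 0-3 magic ``Iout``; 4-5 version; 6 roi type;
8-15 top/left/bottom/right int16; 16-17 n_coordinates; 64+ the x offsets
(n int16, relative to left) followed by the y offsets (n int16, relative
to top).
"""

from __future__ import annotations

import struct
import zipfile
from pathlib import Path

import numpy as np

__all__ = ["read_roi", "read_roi_zip", "write_roi"]

_MAGIC = b"Iout"
# roi type byte
POLYGON, RECT, OVAL, FREEHAND, TRACED = 0, 1, 2, 7, 8
_SUPPORTED = {POLYGON, RECT, OVAL, FREEHAND, TRACED}


def read_roi(data: bytes | str | Path) -> np.ndarray:
    """Decode one ROI into a closed (n, 2) float array of (y, x) vertices.

    Rectangle and oval ROIs are converted to explicit polygons (ovals as a
    64-gon inscribed in the bounding box).
    """
    if not isinstance(data, (bytes, bytearray)):
        data = Path(data).read_bytes()
    if len(data) < 64 or data[:4] != _MAGIC:
        raise ValueError("not an ImageJ ROI record")
    roi_type = data[6]
    if roi_type not in _SUPPORTED:
        raise ValueError(f"unsupported ROI type {roi_type}")
    top, left, bottom, right = struct.unpack(">4h", data[8:16])
    if roi_type == RECT:
        return np.array(
            [[top, left], [top, right - 1], [bottom - 1, right - 1], [bottom - 1, left]],
            dtype=float,
        )
    if roi_type == OVAL:
        cy, cx = (top + bottom - 1) / 2.0, (left + right - 1) / 2.0
        ry, rx = (bottom - 1 - top) / 2.0, (right - 1 - left) / 2.0
        t = np.linspace(0, 2 * np.pi, 64, endpoint=False)
        return np.column_stack([cy + ry * np.sin(t), cx + rx * np.cos(t)])
    (n,) = struct.unpack(">h", data[16:18])
    if n <= 0 or len(data) < 64 + 4 * n:
        raise ValueError("malformed ROI record: bad coordinate count")
    xs = np.frombuffer(data, dtype=">i2", count=n, offset=64).astype(float) + left
    ys = np.frombuffer(data, dtype=">i2", count=n, offset=64 + 2 * n).astype(float) + top
    return np.column_stack([ys, xs])


def read_roi_zip(path: str | Path) -> list[np.ndarray]:
    """Decode every ``.roi`` member of an ImageJ ROI archive, sorted by name."""
    polygons = []
    with zipfile.ZipFile(path) as zf:
        for name in sorted(zf.namelist()):
            if name.lower().endswith(".roi"):
                polygons.append(read_roi(zf.read(name)))
    return polygons


def write_roi(polygon: np.ndarray, roi_type: int = POLYGON) -> bytes:
    """Encode a (y, x) vertex polygon as an ImageJ ``.roi`` record."""
    poly = np.asarray(polygon, dtype=int)
    if poly.ndim != 2 or poly.shape[1] != 2:
        raise ValueError("polygon must be an (n, 2) array of (y, x) vertices")
    ys, xs = poly[:, 0], poly[:, 1]
    top, left = int(ys.min()), int(xs.min())
    bottom, right = int(ys.max()) + 1, int(xs.max()) + 1
    header = bytearray(64)
    header[:4] = _MAGIC
    struct.pack_into(">h", header, 4, 228)  # version, as written by ImageJ 1.52
    header[6] = roi_type
    struct.pack_into(">4h", header, 8, top, left, bottom, right)
    struct.pack_into(">h", header, 16, len(poly))
    body = (xs - left).astype(">i2").tobytes() + (ys - top).astype(">i2").tobytes()
    return bytes(header) + body


def write_roi_zip(polygons: list[np.ndarray], path: str | Path) -> None:
    with zipfile.ZipFile(path, "w") as zf:
        for i, poly in enumerate(polygons):
            zf.writestr(f"{i:04d}.roi", write_roi(poly))
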