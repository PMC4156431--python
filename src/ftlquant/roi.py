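"""ROI polygon rasterization, channel transfer, and pixel metrics.

The region of interest is traced once per section on the Nissl counterstain
and applied unchanged to the label channels; the pixel metrics are the
number of above-threshold pixels inside the polygon and that number as a
percentage of the polygon's pixel total ("percent of nTS labeled").

Rasterization semantics (fixed, testable): a pixel belongs to the ROI iff
its center ``(j + 0.5, i + 0.5)`` is inside the polygon under the even-odd
rule, with boundary ties resolved half-open (a center exactly on a left /
top edge is inside, on a right / bottom edge outside).  The half-open rule
makes masks of edge-sharing polygons exactly additive.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Optional, Union

import numpy as np

from .errors import AlignmentError, EmptyRoiError, InvalidPolygonError
from .types import BinaryMask, FluorescenceSection, RoiPolygon

__all__ = ["rasterize_polygon", "transfer_roi", "quantify_pixels"]


def rasterize_polygon(poly: RoiPolygon, shape: tuple[int, int]) -> BinaryMask:
    """Rasterize a polygon to a boolean mask of the given ``(rows, cols)``.

    Scanline even-odd fill at pixel centers.  For each image row the
    crossings of the polygon edges with the horizontal line ``y = i + 0.5``
    are computed; consecutive crossing pairs ``[x_a, x_b)`` contain the
    pixels whose center x falls in that half-open interval.

    Raises
    ------
    InvalidPolygonError
        Fewer than 3 vertices, self-intersection, or vertices outside the
        image bounds.
    """
    poly.validate(shape)
    h, w = shape
    v = poly.vertices
    x1, y1 = v[:, 0], v[:, 1]
    x2, y2 = np.roll(x1, -1), np.roll(y1, -1)
    nonhoriz = y1 != y2
    x1, y1, x2, y2 = x1[nonhoriz], y1[nonhoriz], x2[nonhoriz], y2[nonhoriz]
    slope = (x2 - x1) / (y2 - y1)

    mask = np.zeros(shape, dtype=bool)
    ymin, ymax = v[:, 1].min(), v[:, 1].max()
    i_lo = max(int(np.floor(ymin - 0.5)), 0)
    i_hi = min(int(np.ceil(ymax)), h)
    for i in range(i_lo, i_hi):
        yc = i + 0.5
        crosses = ((y1 <= yc) & (yc < y2)) | ((y2 <= yc) & (yc < y1))
        if not crosses.any():
            continue
        xs = np.sort(x1[crosses] + (yc - y1[crosses]) * slope[crosses])
        for xa, xb in xs.reshape(-1, 2):
            j0 = max(int(np.ceil(xa - 0.5)), 0)
            j1 = min(int(np.ceil(xb - 0.5)), w)
            if j1 > j0:
                mask[i, j0:j1] = True
    return BinaryMask(mask=mask, channel=poly.source_channel, threshold=None)


def transfer_roi(
    poly: RoiPolygon,
    target_channel: str,
    section: Optional[Union[FluorescenceSection, dict]] = None,
) -> RoiPolygon:
    """Bind a traced polygon to another channel of the same section.

    Vertex coordinates are copied unchanged — the channels are co-registered
    by acquisition, so the Nissl trace applies directly to the label
    channels.  If ``section`` (a :class:`FluorescenceSection` or a plain
    ``{name: raster}`` dict) is given, the source and target channel
    dimensions are checked and a mismatch raises :class:`AlignmentError`.
    """
    if section is not None:
        channels = section.channels if hasattr(section, "channels") else section
        if target_channel not in channels:
            raise AlignmentError(f"no channel {target_channel!r} in section")
        src = channels.get(poly.source_channel)
        if src is not None and src.shape != channels[target_channel].shape:
            raise AlignmentError(
                f"channel {poly.source_channel!r} shape {src.shape} != "
                f"{target_channel!r} shape {channels[target_channel].shape}"
            )
    return replace(poly, vertices=poly.vertices.copy(),
                   source_channel=target_channel)


def _as_bool(mask) -> np.ndarray:
    return mask.mask if isinstance(mask, BinaryMask) else np.asarray(mask, bool)


def quantify_pixels(label_mask, roi_mask) -> tuple[int, int, float]:
    """Count above-threshold pixels inside the ROI.

    Returns ``(pixels_above, roi_pixels, pct_labeled)`` where
    ``pct_labeled = 100 * pixels_above / roi_pixels``.  Pixels outside the
    ROI never contribute.
    """
    lab = _as_bool(label_mask)
    roi = _as_bool(roi_mask)
    if lab.shape != roi.shape:
        raise AlignmentError(
            f"label mask shape {lab.shape} != roi mask shape {roi.shape}"
        )
    roi_pixels = int(roi.sum())
    if roi_pixels == 0:
        raise EmptyRoiError("ROI mask has no interior pixels")
    pixels_above = int(np.count_nonzero(lab & roi))
    return pixels_above, roi_pixels, 100.0 * pixels_above / roi_pixels
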