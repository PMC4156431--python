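"""Cell-body detection and double-label counting on binary masks.

Detection is deterministic connected-component labeling with an area band:
components of the thresholded channel (restricted to the ROI) whose pixel
area falls in ``[min_area, max_area]`` are counted as cell bodies.  The
lower bound excludes sub-nuclear punctate label, the upper bound excludes
merged clumps.  A cell is double-labeled when at least
``overlap_fraction_for_double`` of its pixels are also positive in the
other channel's mask — a deterministic replacement for judging overlap on a
two-color layer composite by eye.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
from scipy import ndimage

from .errors import AlignmentError
from .types import BinaryMask, CellRecord, DetectorParams

__all__ = ["detect_cells", "count_double_labeled"]

_STRUCTURES = {
    4: ndimage.generate_binary_structure(2, 1),
    8: ndimage.generate_binary_structure(2, 2),
}


def _as_bool(mask) -> np.ndarray:
    return mask.mask if isinstance(mask, BinaryMask) else np.asarray(mask, bool)


def _label_components(mask: np.ndarray, params: DetectorParams):
    """Label ``mask`` and keep components inside the area band.

    Returns ``(labels, kept_ids, areas, centroids_xy)`` where ``areas`` and
    ``centroids_xy`` align with ``kept_ids``.  Component order (and hence
    cell order) follows scipy's raster-scan labeling, so repeated calls on
    the same mask enumerate cells identically.
    """
    labels, n = ndimage.label(mask, structure=_STRUCTURES[params.connectivity])
    if n == 0:
        return labels, np.empty(0, int), np.empty(0, int), np.empty((0, 2))
    areas = np.bincount(labels.ravel())[1:]  # area of component id k at [k-1]
    keep = (areas >= params.min_area) & (areas <= params.max_area)
    kept_ids = np.nonzero(keep)[0] + 1
    if kept_ids.size == 0:
        return labels, kept_ids, np.empty(0, int), np.empty((0, 2))
    com = ndimage.center_of_mass(mask, labels, kept_ids)  # (row, col) pairs
    centroids_xy = np.array([(c, r) for r, c in com], dtype=float)
    return labels, kept_ids, areas[keep], centroids_xy


def detect_cells(
    mask, roi_mask, params: DetectorParams, channel: str = ""
) -> list[CellRecord]:
    """Detect labeled cell bodies inside the ROI.

    Components are taken from ``mask AND roi_mask``; a component clipped by
    the ROI boundary is kept if its *in-ROI* area falls within the band.
    Centroids are unweighted pixel centroids in ``(x, y)`` index
    coordinates.
    """
    m = _as_bool(mask)
    roi = _as_bool(roi_mask)
    if m.shape != roi.shape:
        raise AlignmentError(
            f"mask shape {m.shape} != roi shape {roi.shape}"
        )
    chan = channel or (mask.channel if isinstance(mask, BinaryMask) else "")
    _, _, areas, centroids = _label_components(m & roi, params)
    return [
        CellRecord(centroid_xy=(float(x), float(y)), area=int(a), channel=chan)
        for (x, y), a in zip(centroids, areas)
    ]


def count_double_labeled(
    cfos_cells: Optional[Sequence[CellRecord]],
    cfos_mask,
    bgal_mask,
    params: DetectorParams,
) -> tuple[int, list[CellRecord]]:
    """Count cells of one channel that are also labeled in the other.

    ``cfos_mask`` must be the same (ROI-restricted) mask the cells were
    detected on; its components are re-enumerated in the identical order,
    and each kept component's overlap fraction with ``bgal_mask`` is
    compared to ``params.overlap_fraction_for_double``.  Returns the double
    count and the cell list with ``is_double`` set.  Despite the argument
    names the operation is symmetric — pass the masks swapped to count
    beta-gal cells lacking c-Fos.
    """
    m1 = _as_bool(cfos_mask)
    m2 = _as_bool(bgal_mask)
    if m1.shape != m2.shape:
        raise AlignmentError(
            f"mask shapes differ: {m1.shape} vs {m2.shape}"
        )
    labels, kept_ids, areas, centroids = _label_components(m1, params)
    if kept_ids.size == 0:
        return 0, list(cfos_cells) if cfos_cells else []
    overlap = np.bincount(labels[m2].ravel(), minlength=labels.max() + 1)
    frac = overlap[kept_ids] / areas
    flags = frac >= params.overlap_fraction_for_double

    if cfos_cells is not None:
        cells = list(cfos_cells)
        if len(cells) != len(kept_ids):
            raise AlignmentError(
                f"{len(cells)} cells do not match {len(kept_ids)} components; "
                "pass the mask the cells were detected on"
            )
    else:
        chan = cfos_mask.channel if isinstance(cfos_mask, BinaryMask) else ""
        cells = [
            CellRecord(centroid_xy=(float(x), float(y)), area=int(a), channel=chan)
            for (x, y), a in zip(centroids, areas)
        ]
    for cell, fl in zip(cells, flags):
        cell.is_double = bool(fl)
    return int(flags.sum()), cells
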