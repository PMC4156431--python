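"""Intensity threshold derivation and channel binarization.

A single scalar cutoff per label channel is set at the mean plus a multiple
(default 2) of the standard deviation of a pixel-intensity sample.  The
default sample is the aggregate of all pixels inside every section's traced
ROI, pooled across the whole study — pooling normalizes staining and
preparation variability between animals, at the documented cost that adding
a section changes every mask.  A per-image background variant (sample =
non-label pixels of that section's ROI) is available behind the provenance
field for cell-count style thresholding.
"""

from __future__ import annotations

from typing import Iterable, Optional, Sequence

import numpy as np

from .errors import InsufficientSampleError, MissingRoiError
from .roi import rasterize_polygon
from .types import BinaryMask, FluorescenceSection, RoiPolygon, ThresholdEntry

__all__ = ["aggregate_roi_pixels", "estimate_threshold", "binarize"]


def aggregate_roi_pixels(
    sections: Sequence[FluorescenceSection],
    rois: Sequence[Optional[RoiPolygon]],
    channel: str,
    roi_masks: Optional[Sequence[BinaryMask]] = None,
) -> np.ndarray:
    """Pool the intensities of all in-ROI pixels of ``channel``.

    ``rois`` must align with ``sections`` one-to-one.  Pre-rasterized
    ``roi_masks`` may be supplied to avoid repeated rasterization; otherwise
    each polygon is rasterized here.  Returns a 1-D float array whose length
    is the sum of the per-section ROI pixel counts.

    Raises
    ------
    MissingRoiError
        ``rois[k]`` is None for some section.
    EmptyRoiError
        A rasterized ROI has zero interior pixels (raised by
        :func:`~ftlquant.roi.rasterize_polygon` consumers via the empty
        pool check below).
    """
    if len(rois) != len(sections):
        raise MissingRoiError(
            f"{len(sections)} sections but {len(rois)} ROIs"
        )
    pooled: list[np.ndarray] = []
    for k, (sec, poly) in enumerate(zip(sections, rois)):
        if poly is None:
            raise MissingRoiError(f"section {sec.section_id!r} has no ROI")
        if channel not in sec.channels:
            raise MissingRoiError(
                f"section {sec.section_id!r} has no channel {channel!r}"
            )
        if roi_masks is not None:
            m = roi_masks[k].mask
        else:
            m = rasterize_polygon(poly, sec.shape).mask
        if not m.any():
            from .errors import EmptyRoiError

            raise EmptyRoiError(f"ROI of section {sec.section_id!r} is empty")
        pooled.append(sec.channels[channel][m].astype(float).ravel())
    return np.concatenate(pooled) if pooled else np.empty(0)


def estimate_threshold(
    sample: Iterable[float],
    sd_multiplier: float = 2.0,
    channel: str = "",
    provenance: str = "global_aggregate",
) -> ThresholdEntry:
    """Cutoff = sample mean + ``sd_multiplier`` x sample SD (n-1 denominator).

    Zero variance is permitted (the cutoff is then the mean); fewer than two
    pixels raise :class:`InsufficientSampleError`.
    """
    arr = np.asarray(list(sample) if not isinstance(sample, np.ndarray) else sample,
                     dtype=float).ravel()
    n = arr.size
    if n < 2:
        raise InsufficientSampleError(
            f"threshold needs >= 2 pixels, got {n}"
        )
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1))
    return ThresholdEntry(
        channel=channel,
        cutoff=mean + sd_multiplier * sd,
        sample_size=int(n),
        sample_mean=mean,
        sample_sd=sd,
        sd_multiplier=float(sd_multiplier),
        provenance=provenance,
    )


def binarize(raster: np.ndarray, cutoff: float, channel: str = "") -> BinaryMask:
    """Mask true exactly where intensity is *strictly* greater than cutoff.

    The tie rule is negative: a pixel equal to the cutoff is background,
    matching the "greater than mean + 2 SD" criterion.
    """
    if not np.isfinite(cutoff) or cutoff < 0:
        raise ValueError(f"cutoff must be finite and >= 0, got {cutoff}")
    return BinaryMask(
        mask=np.asarray(raster) > cutoff, channel=channel, threshold=float(cutoff)
    )


def background_sample(
    section: FluorescenceSection,
    roi_mask: BinaryMask,
    label_mask: BinaryMask,
    channel: str,
) -> np.ndarray:
    """In-ROI pixels *not* covered by label: the per-image background pool.

    Used by the ``per_image_background`` threshold provenance; in synthetic
    mode the label mask comes from the planted ground truth.
    """
    m = roi_mask.mask & ~label_mask.mask
    return section.channels[channel][m].astype(float).ravel()
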