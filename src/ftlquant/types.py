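"""Core domain containers.

The pipeline passes a small set of plain dataclasses between stages:
sections (co-registered channel rasters plus study metadata), ROI polygons
traced on the Nissl counterstain, per-channel threshold entries, binary
masks, detected cells, and per-section quantification records.

Conventions used throughout the package:

* images are 2-D ``numpy`` arrays indexed ``[row, col]``;
* polygon vertices and cell centroids are ``(x, y)`` pairs with
  ``x = column``, ``y = row``, 0-based;
* pixel ``(i, j)`` has its geometric center at ``(x, y) = (j + 0.5, i + 0.5)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .errors import AlignmentError, DesignError, InvalidPolygonError

#: Channel names in storage order (multi-page TIFF page order).
CHANNELS = ("cfos", "bgal", "nissl")
#: Label channels that are thresholded and quantified.
LABEL_CHANNELS = ("cfos", "bgal")
#: Stimulation groups.
GROUPS = ("Unstim", "NoFoodWater", "MSG", "MSG5hPost")
#: Rostro-caudal levels of the nucleus of the solitary tract.
LEVELS = ("Rostral", "Intermediate", "Caudal")


@dataclass
class FluorescenceSection:
    """One tissue section: aligned channel rasters plus study metadata."""

    channels: dict[str, np.ndarray]
    animal_id: str
    group: str
    level: str
    pixel_depth: int = 16

    def __post_init__(self) -> None:
        shapes = {name: arr.shape for name, arr in self.channels.items()}
        if len(set(shapes.values())) > 1:
            raise AlignmentError(f"channel dimensions differ: {shapes}")
        hi = 2**self.pixel_depth - 1
        for name, arr in self.channels.items():
            if arr.ndim != 2:
                raise AlignmentError(f"channel {name!r} is not a 2-D raster")
            if np.any(arr < 0) or np.any(arr > hi):
                raise ValueError(
                    f"channel {name!r} intensities outside [0, {hi}]"
                )

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    @property
    def section_id(self) -> str:
        return f"{self.animal_id}_{self.level}"


@dataclass
class RoiPolygon:
    """Ordered vertex list (implicitly closed) delimiting the nTS.

    ``vertices`` is an ``(n, 2)`` float array of ``(x, y)`` pixel
    coordinates.  Polygons are traced on the Nissl channel and transferred
    unchanged to the label channels.
    """

    vertices: np.ndarray
    source_channel: str = "nissl"
    section_id: Optional[str] = None

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2:
            raise InvalidPolygonError("vertices must be an (n, 2) array")
        if len(self.vertices) < 3:
            raise InvalidPolygonError(
                f"polygon needs >= 3 vertices, got {len(self.vertices)}"
            )

    def validate(self, shape: Optional[tuple[int, int]] = None) -> None:
        """Raise :class:`InvalidPolygonError` on self-intersection or
        out-of-bounds vertices (bounds checked only when ``shape`` given)."""
        from shapely.geometry import Polygon as _ShapelyPolygon

        if not _ShapelyPolygon(self.vertices).is_valid:
            raise InvalidPolygonError("polygon is self-intersecting")
        if shape is not None:
            h, w = shape
            x, y = self.vertices[:, 0], self.vertices[:, 1]
            if x.min() < 0 or y.min() < 0 or x.max() > w or y.max() > h:
                raise InvalidPolygonError(
                    f"vertices leave the {h}x{w} image bounds"
                )


@dataclass
class ThresholdEntry:
    """A per-channel intensity cutoff with its provenance.

    The cutoff is ``sample_mean + sd_multiplier * sample_sd`` where the
    standard deviation uses the n-1 (sample) denominator; the identity is
    preserved exactly so it can be re-checked from the stored fields.
    """

    channel: str
    cutoff: float
    sample_size: int
    sample_mean: float
    sample_sd: float
    sd_multiplier: float = 2.0
    provenance: str = "global_aggregate"  # or "per_image_background"


#: A full threshold set is simply a mapping channel -> ThresholdEntry.
ThresholdSet = dict[str, ThresholdEntry]


@dataclass
class BinaryMask:
    """Boolean raster derived from one channel (or from a polygon)."""

    mask: np.ndarray
    channel: str = ""
    threshold: Optional[float] = None

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape

    def count(self) -> int:
        return int(self.mask.sum())


@dataclass
class CellRecord:
    """One detected (or planted) labeled cell body."""

    centroid_xy: tuple[float, float]
    area: int
    channel: str
    is_double: bool = False


@dataclass
class DetectorParams:
    """Connected-component cell detector settings.

    The area band ``[min_area, max_area]`` separates genuine cell bodies
    from sub-nuclear punctate label (too small) and merged clumps (too
    large).  ``overlap_fraction_for_double`` is the fraction of a cell's
    pixels that must also be positive in the other channel's mask for the
    cell to count as double-labeled.
    """

    min_area: int
    max_area: int
    connectivity: int = 8
    overlap_fraction_for_double: float = 0.5

    def __post_init__(self) -> None:
        if not (0 < self.min_area <= self.max_area):
            raise ValueError("need 0 < min_area <= max_area")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")
        if not (0 < self.overlap_fraction_for_double <= 1):
            raise ValueError("overlap_fraction_for_double must be in (0, 1]")


@dataclass
class QuantRecord:
    """Per section x channel quantification row."""

    animal_id: str
    group: str
    level: str
    channel: str
    cell_count: int
    double_count: int
    pixels_above: int
    roi_pixels: int

    def __post_init__(self) -> None:
        if not (0 <= self.pixels_above <= self.roi_pixels):
            raise ValueError("pixels_above must lie in [0, roi_pixels]")
        if self.double_count > self.cell_count:
            raise ValueError("double_count cannot exceed cell_count")

    @property
    def pct_labeled(self) -> float:
        return 100.0 * self.pixels_above / self.roi_pixels


@dataclass
class SceneParams:
    """Parameters of one synthetic section.

    Defaults encode the staining structure the analysis assumes: punctate
    nuclear c-Fos label, dense cytoplasmic somatic beta-gal label with short
    radiating processes, sub-nuclear-size non-specific puncta on the c-Fos
    channel, Gaussian background, and a traceable elevated-intensity region
    on the Nissl channel.  Intensities are in 16-bit camera counts.
    """

    image_height: int = 320
    image_width: int = 320
    background_mean: float = 100.0
    background_sd: float = 10.0
    n_cfos_cells: int = 20
    n_bgal_cells: int = 20
    double_label_fraction: float = 0.5
    nucleus_radius: int = 3
    soma_radius: int = 5
    cfos_cell_intensity: float = 600.0
    bgal_cell_intensity: float = 600.0
    n_puncta: int = 30
    punctum_radius: int = 1
    roi_margin: int = 16
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_height <= 0 or self.image_width <= 0:
            raise ValueError("image dimensions must be positive")
        for name in ("n_cfos_cells", "n_bgal_cells", "n_puncta"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("nucleus_radius", "soma_radius", "punctum_radius"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not (0.0 <= self.double_label_fraction <= 1.0):
            raise ValueError("double_label_fraction must be in [0, 1]")
        if self.cfos_cell_intensity <= self.background_mean:
            raise ValueError("cfos_cell_intensity must exceed background_mean")
        if self.bgal_cell_intensity <= self.background_mean:
            raise ValueError("bgal_cell_intensity must exceed background_mean")
        if self.punctum_radius >= self.nucleus_radius:
            raise ValueError("punctum_radius must be < nucleus_radius")

    def with_(self, **kwargs) -> "SceneParams":
        return replace(self, **kwargs)


@dataclass
class GroundTruth:
    """Planted truth for one synthetic section.

    ``cells`` holds the rendered-pixel centroid and in-ROI area of every
    planted cell body (consistent with the image actually written, so a
    perfect detector reproduces it exactly).  ``planted_area_fraction`` is
    the exact fraction of ROI pixels covered by planted label per channel,
    computed from the rendered label masks.
    """

    cells: list[CellRecord]
    planted_area_fraction: dict[str, float]
    roi_polygon: RoiPolygon
    label_masks: Optional[dict[str, np.ndarray]] = None
    puncta_xy: list[tuple[float, float]] = field(default_factory=list)

    def cells_in(self, channel: str) -> list[CellRecord]:
        return [c for c in self.cells if c.channel == channel]

    def n_double(self) -> int:
        """Number of double-labeled cell sites (counted once)."""
        return sum(1 for c in self.cells if c.channel == "cfos" and c.is_double)


@dataclass
class DesignRow:
    animal_id: str
    group: str
    level: str
    scene_overrides: dict = field(default_factory=dict)


@dataclass
class StudyDesign:
    """Balanced group x level study layout: one section per animal x level."""

    rows: list[DesignRow]

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        animal_group: dict[str, str] = {}
        seen_pairs = set()
        for r in self.rows:
            if animal_group.setdefault(r.animal_id, r.group) != r.group:
                raise DesignError(
                    f"animal {r.animal_id!r} assigned to more than one group"
                )
            pair = (r.animal_id, r.level)
            if pair in seen_pairs:
                raise DesignError(f"duplicate animal x level row: {pair}")
            seen_pairs.add(pair)
        per_group: dict[str, set] = {}
        for a, g in animal_group.items():
            per_group.setdefault(g, set()).add(a)
        sizes = {g: len(s) for g, s in per_group.items()}
        if len(set(sizes.values())) > 1:
            raise DesignError(f"unbalanced design: animals per group {sizes}")

    @classmethod
    def balanced(
        cls,
        groups: Sequence[str] = GROUPS,
        levels: Sequence[str] = LEVELS,
        n_per_group: int = 3,
        overrides=None,
    ) -> "StudyDesign":
        """Full-factorial design: ``n_per_group`` animals per group, one
        section per animal at each level.  ``overrides`` may be a callable
        ``(group, level) -> dict`` of SceneParams deltas."""
        rows = []
        idx = 0
        for g in groups:
            for _ in range(n_per_group):
                idx += 1
                aid = f"A{idx:02d}"
                for lv in levels:
                    ov = dict(overrides(g, lv)) if overrides else {}
                    rows.append(DesignRow(aid, g, lv, ov))
        return cls(rows)
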