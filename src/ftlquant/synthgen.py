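"""Synthetic multi-channel sections with planted, fully known ground truth.

Every downstream stage (thresholding, ROI metrics, cell and double-label
counting, ANOVA) is exercised against scenes whose truth is exact: the
generator records the rendered pixel set of every planted cell, so a
perfect detector reproduces the truth bit-for-bit.

A scene contains:

* **c-Fos channel** — disk-shaped nuclei (``nucleus_radius``) plus smaller
  non-specific puncta (``punctum_radius``), on Gaussian background;
* **beta-gal channel** — filled cytoplasmic somata (``soma_radius``) with
  one-pixel-wide radiating processes 2-4 soma radii long, emulating the
  dense tau-shuttled label of FTL tissue;
* **Nissl channel** — the nTS region at elevated intensity so the ROI is
  traceable without looking at the label channels.

Double-labeled cells share their centroid across the c-Fos and beta-gal
channels.  All intensities are 16-bit camera counts; noise is independent
per-pixel Gaussian truncated at zero.

Placement uses rejection sampling inside the ROI (eroded by one soma
radius) with a minimum centroid separation slightly above one soma
diameter, and processes stop before becoming 8-connected to another cell's
pixels or leaving the ROI — planted components therefore never merge and
the truth sidecar stays exact.
"""

from __future__ import annotations

import numpy as np
from numpy.random import SeedSequence, default_rng
from scipy import ndimage
from skimage.draw import disk as _draw_disk
from skimage.draw import line as _draw_line
from skimage.morphology import disk as _disk_struct

from .errors import PlacementError
from .roi import rasterize_polygon
from .types import (
    CellRecord,
    DesignRow,
    FluorescenceSection,
    GroundTruth,
    GROUPS,
    LEVELS,
    RoiPolygon,
    SceneParams,
    StudyDesign,
)

__all__ = [
    "generate_section",
    "generate_study",
    "scenario_design",
    "SCENARIOS",
]

_N_ROI_VERTICES = 24
#: Nissl intensity boost inside the nTS region, in background SD units.
_NISSL_BOOST_SD = 8.0
_U16_MAX = 65535


def _roi_polygon(rng: np.random.Generator, params: SceneParams) -> RoiPolygon:
    """Irregular star-shaped blob centred in the image.

    The radius is a smooth random harmonic perturbation of a base circle,
    which keeps the polygon simple (non-self-intersecting) by construction
    and at least ``roi_margin`` pixels away from the image border.
    """
    h, w = params.image_height, params.image_width
    r_base = min(h, w) / 2.0 - params.roi_margin
    if r_base < 4:
        raise PlacementError(
            "roi_margin leaves no room for the ROI in a "
            f"{h}x{w} image"
        )
    theta = np.linspace(0.0, 2.0 * np.pi, _N_ROI_VERTICES, endpoint=False)
    pert = np.zeros_like(theta)
    for k in (2, 3, 4):
        a, b = rng.uniform(-1.0, 1.0, 2) / k
        pert += a * np.cos(k * theta) + b * np.sin(k * theta)
    radius = r_base * (0.82 + 0.16 * np.tanh(pert))
    cx, cy = w / 2.0, h / 2.0
    verts = np.column_stack(
        [cx + radius * np.cos(theta), cy + radius * np.sin(theta)]
    )
    return RoiPolygon(vertices=verts, source_channel="nissl")


def _place_points(
    rng: np.random.Generator,
    allowed_rc: np.ndarray,
    n: int,
    min_sep: float,
    taken: np.ndarray,
    min_sep_taken: float,
    what: str,
) -> np.ndarray:
    """Rejection-sample ``n`` points (row, col) with separation constraints."""
    if n == 0:
        return np.empty((0, 2))
    if allowed_rc.shape[0] == 0:
        raise PlacementError(
            f"no interior room to place {what}: ROI too small for "
            "soma_radius / roi_margin"
        )
    accepted: list[np.ndarray] = []
    budget = 300 * n + 300
    while len(accepted) < n and budget > 0:
        budget -= 1
        cand = allowed_rc[rng.integers(allowed_rc.shape[0])].astype(float)
        if accepted:
            d2 = ((np.array(accepted) - cand) ** 2).sum(axis=1)
            if d2.min() < min_sep**2:
                continue
        if taken.size:
            d2 = ((taken - cand) ** 2).sum(axis=1)
            if d2.min() < min_sep_taken**2:
                continue
        accepted.append(cand)
    if len(accepted) < n:
        raise PlacementError(
            f"could not place {n} {what} (placed {len(accepted)}): "
            "reduce the count, shrink the radii, or enlarge the image"
        )
    return np.array(accepted)


def _neighbors_clear(owner: np.ndarray, r: int, c: int, cid: int) -> bool:
    """True when the 8-neighborhood of (r, c) holds only cid / background."""
    h, w = owner.shape
    win = owner[max(r - 1, 0):min(r + 2, h), max(c - 1, 0):min(c + 2, w)]
    return bool(np.all((win == 0) | (win == cid)))


def generate_section(
    params: SceneParams,
    animal_id: str = "S0",
    group: str = "Unstim",
    level: str = "Rostral",
) -> tuple[FluorescenceSection, GroundTruth]:
    """Render one synthetic section and its exact ground truth.

    Raises :class:`PlacementError` when the requested cell counts cannot be
    placed inside the ROI within the rejection-sampling budget.
    """
    rng = default_rng(params.seed)
    h, w = params.image_height, params.image_width
    shape = (h, w)

    poly = _roi_polygon(rng, params)
    roi_mask = rasterize_polygon(poly, shape).mask
    roi_count = int(roi_mask.sum())
    if roi_count == 0:
        raise PlacementError("ROI rasterized to zero pixels")

    # Interior where whole somata fit; +1 guard so disks stay off the edge.
    allowed = ndimage.binary_erosion(
        roi_mask, structure=_disk_struct(params.soma_radius + 2)
    )
    allowed_rc = np.argwhere(allowed)

    n_double = int(round(
        params.double_label_fraction
        * min(params.n_cfos_cells, params.n_bgal_cells)
    ))
    n_cfos_only = params.n_cfos_cells - n_double
    n_bgal_only = params.n_bgal_cells - n_double

    sep_cells = 2.0 * params.soma_radius + 3.0
    cells_rc = _place_points(
        rng, allowed_rc, n_double + n_cfos_only + n_bgal_only,
        sep_cells, np.empty((0, 2)), 0.0, "cell bodies",
    )
    double_rc = cells_rc[:n_double]
    cfos_rc = np.vstack([double_rc, cells_rc[n_double:n_double + n_cfos_only]])
    bgal_rc = np.vstack([double_rc, cells_rc[n_double + n_cfos_only:]])

    sep_puncta = 2.0 * params.punctum_radius + 3.0
    sep_puncta_cells = params.soma_radius + params.punctum_radius + 3.0
    puncta_rc = _place_points(
        rng, allowed_rc, params.n_puncta,
        sep_puncta, cells_rc, sep_puncta_cells, "puncta",
    )

    # --- render c-Fos channel truth ------------------------------------
    cfos_label = np.zeros(shape, dtype=bool)
    cfos_cell_pixels: list[tuple[np.ndarray, np.ndarray]] = []
    for r, c in cfos_rc:
        rr, cc = _draw_disk((r, c), params.nucleus_radius + 0.5, shape=shape)
        cfos_label[rr, cc] = True
        cfos_cell_pixels.append((rr, cc))
    for r, c in puncta_rc:
        rr, cc = _draw_disk((r, c), params.punctum_radius + 0.5, shape=shape)
        cfos_label[rr, cc] = True

    # --- render beta-gal channel truth ---------------------------------
    bgal_label = np.zeros(shape, dtype=bool)
    owner = np.zeros(shape, dtype=np.int32)
    pixel_lists: list[tuple[list, list]] = []
    # Pass 1: stamp every soma so processes know where their neighbors are.
    for cid, (r, c) in enumerate(bgal_rc, start=1):
        rr, cc = _draw_disk((r, c), params.soma_radius + 0.5, shape=shape)
        owner[rr, cc] = cid
        pixel_lists.append((list(rr), list(cc)))
    # Pass 2: radiating processes, stopping short of foreign pixels.
    bgal_cell_pixels: list[tuple[np.ndarray, np.ndarray]] = []
    for cid, (r, c) in enumerate(bgal_rc, start=1):
        px_r, px_c = pixel_lists[cid - 1]
        for _ in range(2):  # two radiating processes per soma
            ang = rng.uniform(0.0, 2.0 * np.pi)
            length = params.soma_radius * (1.0 + rng.uniform(2.0, 4.0))
            er = int(round(r + length * np.sin(ang)))
            ec = int(round(c + length * np.cos(ang)))
            er = min(max(er, 0), h - 1)
            ec = min(max(ec, 0), w - 1)
            lr, lc = _draw_line(int(round(r)), int(round(c)), er, ec)
            for pr, pc in zip(lr, lc):
                if owner[pr, pc] == cid:
                    continue  # still inside own soma
                if not roi_mask[pr, pc]:
                    break  # processes stay inside the traced region
                if not _neighbors_clear(owner, pr, pc, cid):
                    break  # would fuse with a neighboring cell
                owner[pr, pc] = cid
                px_r.append(pr)
                px_c.append(pc)
        rr_all = np.array(px_r)
        cc_all = np.array(px_c)
        bgal_label[rr_all, cc_all] = True
        bgal_cell_pixels.append((rr_all, cc_all))

    # --- intensities ----------------------------------------------------
    def _render(label: np.ndarray, intensity: float) -> np.ndarray:
        img = rng.normal(params.background_mean, params.background_sd, shape)
        n_lab = int(label.sum())
        if n_lab:
            img[label] = intensity + rng.normal(
                0.0, params.background_sd, n_lab
            )
        return np.clip(np.rint(img), 0, _U16_MAX).astype(np.uint16)

    cfos_img = _render(cfos_label, params.cfos_cell_intensity)
    bgal_img = _render(bgal_label, params.bgal_cell_intensity)
    nissl = rng.normal(params.background_mean, params.background_sd, shape)
    nissl[roi_mask] += _NISSL_BOOST_SD * params.background_sd
    nissl_img = np.clip(np.rint(nissl), 0, _U16_MAX).astype(np.uint16)

    section = FluorescenceSection(
        channels={"cfos": cfos_img, "bgal": bgal_img, "nissl": nissl_img},
        animal_id=animal_id,
        group=group,
        level=level,
    )
    poly.section_id = section.section_id

    # --- truth sidecar, consistent with the rendered pixels -------------
    cells: list[CellRecord] = []
    for idx, (rr, cc) in enumerate(cfos_cell_pixels):
        cells.append(CellRecord(
            centroid_xy=(float(cc.mean()), float(rr.mean())),
            area=int(len(rr)),
            channel="cfos",
            is_double=idx < n_double,
        ))
    for idx, (rr, cc) in enumerate(bgal_cell_pixels):
        cells.append(CellRecord(
            centroid_xy=(float(cc.mean()), float(rr.mean())),
            area=int(len(rr)),
            channel="bgal",
            is_double=idx < n_double,
        ))
    truth = GroundTruth(
        cells=cells,
        planted_area_fraction={
            "cfos": float((cfos_label & roi_mask).sum()) / roi_count,
            "bgal": float((bgal_label & roi_mask).sum()) / roi_count,
        },
        roi_polygon=poly,
        label_masks={"cfos": cfos_label, "bgal": bgal_label},
        puncta_xy=[(float(c), float(r)) for r, c in puncta_rc],
    )
    return section, truth


def generate_study(
    design: StudyDesign,
    base: SceneParams,
    poisson_counts: bool = False,
) -> list[tuple[FluorescenceSection, GroundTruth]]:
    """One section per design row, with per-row seeds derived from the base.

    Per-row seeds come from ``SeedSequence([base.seed, row_index])``, so the
    same design and base parameters reproduce the study bit-for-bit.  With
    ``poisson_counts`` the configured per-row cell counts are treated as
    expectations and the actual planted counts are Poisson draws — the
    between-animal biological variability the group comparison needs.
    """
    design.validate()
    out = []
    for idx, row in enumerate(design.rows):
        ss = SeedSequence([int(base.seed), idx])
        s_scene, s_counts = (int(x) for x in ss.generate_state(2))
        params = base.with_(**row.scene_overrides)
        if poisson_counts:
            crng = default_rng(s_counts)
            params = params.with_(
                n_cfos_cells=int(crng.poisson(params.n_cfos_cells)),
                n_bgal_cells=int(crng.poisson(params.n_bgal_cells)),
            )
        params = params.with_(seed=s_scene % (2**31))
        out.append(generate_section(
            params, animal_id=row.animal_id, group=row.group, level=row.level
        ))
    return out


# ---------------------------------------------------------------------------
# Study scenarios
# ---------------------------------------------------------------------------

#: Mean planted beta-gal cell counts per nTS level in the "paper-pattern"
#: scenario: a rostral > intermediate > caudal gradient, identical across
#: stimulation groups (the stable beta-gal population).
_BGAL_GRADIENT = {"Rostral": 55, "Intermediate": 40, "Caudal": 25}
#: Mean planted c-Fos cell count outside / inside the MSG group.
_CFOS_BASE = 10
_CFOS_MSG_MULTIPLIER = 3.0
#: Flat count used by the "null" scenario.
_BGAL_FLAT = 40


def _paper_pattern(group: str, level: str) -> dict:
    n_cfos = _CFOS_BASE * (_CFOS_MSG_MULTIPLIER if group == "MSG" else 1.0)
    return {
        "n_cfos_cells": int(round(n_cfos)),
        "n_bgal_cells": _BGAL_GRADIENT[level],
    }


def _null(group: str, level: str) -> dict:
    return {"n_cfos_cells": _CFOS_BASE, "n_bgal_cells": _BGAL_FLAT}


def _custom(group: str, level: str) -> dict:
    return {}  # every row uses the base SceneParams unchanged


SCENARIOS = {"paper-pattern": _paper_pattern, "null": _null, "custom": _custom}


def scenario_design(
    name: str,
    n_per_group: int = 3,
    groups=GROUPS,
    levels=LEVELS,
) -> StudyDesign:
    """Balanced 4-group x 3-level design with per-row scenario overrides.

    ``paper-pattern`` plants the study's central contrast: c-Fos cell
    number multiplied by 3 in the MSG group only, beta-gal counts identical
    across groups but graded rostral > intermediate > caudal.  ``null``
    plants no effect anywhere.
    """
    if name not in SCENARIOS:
        raise ValueError(
            f"unknown scenario {name!r}; choose from {sorted(SCENARIOS)}"
        )
    return StudyDesign.balanced(
        groups=groups, levels=levels, n_per_group=n_per_group,
        overrides=SCENARIOS[name],
    )
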