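"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately re-derive results pixel-by-pixel (point-in-
polygon scans, BFS connected components, explicit sums-of-squares loops) so
they share no code path with the implementation they check.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest


# ---------------------------------------------------------------------------
# brute-force oracles
# ---------------------------------------------------------------------------

def point_in_polygon(px: float, py: float, verts: np.ndarray) -> bool:
    """Crossing-number even-odd test with half-open boundary handling:
    an edge counts when it crosses the horizontal ray strictly to the
    right of the point."""
    inside = False
    n = len(verts)
    for i in range(n):
        x1, y1 = verts[i]
        x2, y2 = verts[(i + 1) % n]
        if (y1 <= py < y2) or (y2 <= py < y1):
            xint = x1 + (py - y1) * (x2 - x1) / (y2 - y1)
            if px < xint:
                inside = not inside
    return inside


def brute_force_raster(verts: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    h, w = shape
    out = np.zeros(shape, dtype=bool)
    for i in range(h):
        for j in range(w):
            out[i, j] = point_in_polygon(j + 0.5, i + 0.5, verts)
    return out


def brute_force_components(
    mask: np.ndarray, connectivity: int = 8
) -> list[dict]:
    """BFS flood fill; returns per-component pixel lists, areas, centroids."""
    if connectivity == 4:
        offs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    else:
        offs = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1)
                if (dr, dc) != (0, 0)]
    h, w = mask.shape
    seen = np.zeros_like(mask, dtype=bool)
    comps = []
    for r in range(h):
        for c in range(w):
            if not mask[r, c] or seen[r, c]:
                continue
            stack = [(r, c)]
            seen[r, c] = True
            pixels = []
            while stack:
                pr, pc = stack.pop()
                pixels.append((pr, pc))
                for dr, dc in offs:
                    nr, nc = pr + dr, pc + dc
                    if 0 <= nr < h and 0 <= nc < w and mask[nr, nc] \
                            and not seen[nr, nc]:
                        seen[nr, nc] = True
                        stack.append((nr, nc))
            arr = np.array(pixels, dtype=float)
            comps.append({
                "area": len(pixels),
                "centroid_xy": (arr[:, 1].mean(), arr[:, 0].mean()),
                "pixels": pixels,
            })
    return comps


def brute_force_anova_ss(frame: pd.DataFrame, response: str):
    """Explicit-loop sums of squares for the balanced two-way layout."""
    groups = list(pd.unique(frame["group"]))
    levels = list(pd.unique(frame["level"]))
    y = frame[response].to_numpy(dtype=float)
    gm = y.mean()
    cell = {}
    for g in groups:
        for l in levels:
            cell[(g, l)] = frame[(frame["group"] == g) & (frame["level"] == l)][
                response].to_numpy(dtype=float)
    n = len(cell[(groups[0], levels[0])])
    a, b = len(groups), len(levels)
    amean = {g: np.concatenate([cell[(g, l)] for l in levels]).mean()
             for g in groups}
    bmean = {l: np.concatenate([cell[(g, l)] for g in groups]).mean()
             for l in levels}
    ss_a = b * n * sum((amean[g] - gm) ** 2 for g in groups)
    ss_b = a * n * sum((bmean[l] - gm) ** 2 for l in levels)
    ss_ab = n * sum(
        (cell[(g, l)].mean() - amean[g] - bmean[l] + gm) ** 2
        for g in groups for l in levels
    )
    ss_res = sum(
        float(((cell[(g, l)] - cell[(g, l)].mean()) ** 2).sum())
        for g in groups for l in levels
    )
    return ss_a, ss_b, ss_ab, ss_res, a, b, n


def random_simple_polygon(
    rng: np.random.Generator, w: int, h: int, n_vertices: int = 8
) -> np.ndarray:
    """Star-shaped (hence simple) polygon with float vertices inside the
    image; vertices are continuous so pixel-center boundary ties have
    probability zero."""
    cx = rng.uniform(0.35, 0.65) * w
    cy = rng.uniform(0.35, 0.65) * h
    while True:
        ang = np.sort(rng.uniform(0, 2 * np.pi, n_vertices))
        gaps = np.diff(np.concatenate([ang, [ang[0] + 2 * np.pi]]))
        # no near-duplicate directions (zero-area spikes) and every wedge
        # below pi: angle-sorted vertices are then provably simple
        if gaps.min() > 0.05 and gaps.max() < 2.8:
            break
    verts = []
    for t in ang:
        # farthest admissible radius toward the border along this direction
        dx, dy = np.cos(t), np.sin(t)
        rmax = min(
            ((w - 1e-6 - cx) / dx) if dx > 0 else ((0 + 1e-6 - cx) / dx) if dx < 0 else np.inf,
            ((h - 1e-6 - cy) / dy) if dy > 0 else ((0 + 1e-6 - cy) / dy) if dy < 0 else np.inf,
        )
        r = rng.uniform(0.25, 0.95) * rmax
        verts.append((cx + r * dx, cy + r * dy))
    return np.array(verts)


def random_blob_mask(
    rng: np.random.Generator, shape: tuple[int, int], n_blobs: int = 6
) -> np.ndarray:
    """Sprinkle random rectangles and single pixels for CC oracle tests."""
    mask = np.zeros(shape, dtype=bool)
    h, w = shape
    for _ in range(n_blobs):
        r = rng.integers(0, h)
        c = rng.integers(0, w)
        dr = int(rng.integers(1, 6))
        dc = int(rng.integers(1, 6))
        mask[r:min(r + dr, h), c:min(c + dc, w)] = True
    mask |= rng.random(shape) < 0.02
    return mask


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20140905)


@pytest.fixture
def small_scene():
    """Fast small scene used by generator unit tests."""
    from ftlquant import SceneParams

    return SceneParams(
        image_height=160, image_width=160, n_cfos_cells=8, n_bgal_cells=8,
        n_puncta=10, roi_margin=10, seed=11,
    )
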