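"""File formats: multi-page TIFF sections, ROI polygons (GeoJSON and
ImageJ ``.roi``), ground-truth sidecars, and the fixed-header CSV tables.

All tabular outputs carry a comment-free fixed header so downstream tools
can rely on the column order; run-level metadata (seed, thresholds, stage
counts) lives in the JSON run report instead of CSV comments.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import tifffile

from . import ijroi
from .errors import ConfigError
from .types import (
    CHANNELS,
    CellRecord,
    FluorescenceSection,
    GroundTruth,
    QuantRecord,
    RoiPolygon,
    ThresholdEntry,
)

RECORD_COLUMNS = [
    "animal", "group", "level", "channel",
    "cell_count", "double_count", "pixels_above", "roi_pixels", "pct_labeled",
]
THRESHOLD_COLUMNS = ["channel", "provenance", "n", "mean", "sd", "cutoff"]


# --- sections --------------------------------------------------------------

def write_section_tiff(path, section: FluorescenceSection) -> None:
    """Multi-page TIFF, page order c-Fos, beta-gal, Nissl; metadata in the
    image description as JSON."""
    stack = np.stack([section.channels[c] for c in CHANNELS])
    meta = {
        "channels": list(CHANNELS),
        "animal_id": section.animal_id,
        "group": section.group,
        "level": section.level,
        "pixel_depth": section.pixel_depth,
    }
    tifffile.imwrite(path, stack, photometric="minisblack",
                     description=json.dumps(meta))


def read_section_tiff(path, animal_id: Optional[str] = None,
                      group: Optional[str] = None,
                      level: Optional[str] = None) -> FluorescenceSection:
    with tifffile.TiffFile(path) as tf:
        stack = tf.asarray()
        desc = tf.pages[0].description
    meta = {}
    if desc:
        try:
            meta = json.loads(desc)
        except (json.JSONDecodeError, TypeError):
            meta = {}
    names = meta.get("channels", list(CHANNELS))
    if stack.ndim != 3 or stack.shape[0] != len(names):
        raise ConfigError(
            f"{path}: expected {len(names)} pages, got shape {stack.shape}"
        )
    return FluorescenceSection(
        channels={n: stack[i] for i, n in enumerate(names)},
        animal_id=animal_id or meta.get("animal_id", "NA"),
        group=group or meta.get("group", "NA"),
        level=level or meta.get("level", "NA"),
        pixel_depth=int(meta.get("pixel_depth", 16)),
    )


# --- ROI polygons ----------------------------------------------------------

def write_roi_geojson(path, poly: RoiPolygon) -> None:
    ring = poly.vertices.tolist()
    ring.append(ring[0])  # GeoJSON rings are explicitly closed
    obj = {
        "type": "Feature",
        "geometry": {"type": "Polygon", "coordinates": [ring]},
        "properties": {
            "source_channel": poly.source_channel,
            "section_id": poly.section_id,
        },
    }
    Path(path).write_text(json.dumps(obj))


def read_roi_geojson(path) -> RoiPolygon:
    obj = json.loads(Path(path).read_text())
    geom = obj.get("geometry", obj)
    if geom.get("type") != "Polygon":
        raise ConfigError(f"{path}: expected a GeoJSON Polygon")
    ring = np.asarray(geom["coordinates"][0], dtype=float)
    if len(ring) > 1 and np.allclose(ring[0], ring[-1]):
        ring = ring[:-1]  # drop the closing duplicate
    props = obj.get("properties", {}) or {}
    return RoiPolygon(
        vertices=ring,
        source_channel=props.get("source_channel", "nissl"),
        section_id=props.get("section_id"),
    )


def write_roi_imagej(path, poly: RoiPolygon) -> None:
    ijroi.write_roi(path, poly.vertices)


def read_roi_imagej(path) -> RoiPolygon:
    return RoiPolygon(vertices=ijroi.read_roi(path))


def read_roi_any(path) -> RoiPolygon:
    path = Path(path)
    if path.suffix.lower() == ".roi":
        return read_roi_imagej(path)
    return read_roi_geojson(path)


# --- ground truth ----------------------------------------------------------

def write_truth_json(path, truth: GroundTruth) -> None:
    obj = {
        "cells": [
            {"x": c.centroid_xy[0], "y": c.centroid_xy[1], "area": c.area,
             "channel": c.channel, "is_double": c.is_double}
            for c in truth.cells
        ],
        "planted_area_fraction": truth.planted_area_fraction,
        "puncta_xy": truth.puncta_xy,
        "roi_vertices": truth.roi_polygon.vertices.tolist(),
    }
    Path(path).write_text(json.dumps(obj))


def read_truth_json(path) -> GroundTruth:
    obj = json.loads(Path(path).read_text())
    return GroundTruth(
        cells=[
            CellRecord(centroid_xy=(c["x"], c["y"]), area=c["area"],
                       channel=c["channel"], is_double=c["is_double"])
            for c in obj["cells"]
        ],
        planted_area_fraction=obj["planted_area_fraction"],
        roi_polygon=RoiPolygon(vertices=np.asarray(obj["roi_vertices"])),
        puncta_xy=[tuple(p) for p in obj.get("puncta_xy", [])],
    )


# --- masks -----------------------------------------------------------------

def write_mask_tiff(path, mask) -> None:
    arr = mask.mask if hasattr(mask, "mask") else np.asarray(mask, bool)
    tifffile.imwrite(path, arr.astype(np.uint8) * 255)


# --- tables ----------------------------------------------------------------

def records_to_frame(records: Sequence[QuantRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [{
            "animal": r.animal_id, "group": r.group, "level": r.level,
            "channel": r.channel, "cell_count": r.cell_count,
            "double_count": r.double_count, "pixels_above": r.pixels_above,
            "roi_pixels": r.roi_pixels, "pct_labeled": r.pct_labeled,
        } for r in records],
        columns=RECORD_COLUMNS,
    )


def write_records_csv(path, frame: pd.DataFrame) -> None:
    frame.to_csv(path, index=False, columns=RECORD_COLUMNS)


def read_records_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def thresholds_to_frame(thresholds: dict[str, ThresholdEntry]) -> pd.DataFrame:
    return pd.DataFrame(
        [{
            "channel": t.channel, "provenance": t.provenance,
            "n": t.sample_size, "mean": t.sample_mean, "sd": t.sample_sd,
            "cutoff": t.cutoff,
        } for t in thresholds.values()],
        columns=THRESHOLD_COLUMNS,
    )
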