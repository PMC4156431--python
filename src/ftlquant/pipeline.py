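"""End-to-end orchestration: generate or ingest sections, derive pooled
thresholds, quantify ROI pixels, detect and double-count cells, and run the
group x level ANOVAs with Tukey post-hocs — one configured, seeded run.

The one deliberately non-local step is threshold pooling: by default the
cutoff for each label channel is estimated from the aggregate of in-ROI
pixels of *every* section in the run (all groups, all levels), which
normalizes staining variability between animals but means adding a section
changes every mask.  The ``per_image_background`` provenance estimates a
per-section cutoff from that section's non-label ROI pixels instead
(synthetic mode only, where the truth defines "non-label").
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import io as fio
from .cells import count_double_labeled, detect_cells
from .errors import ConfigError, PipelineStageError
from .imgproc import (
    aggregate_roi_pixels,
    background_sample,
    binarize,
    estimate_threshold,
)
from .roi import quantify_pixels, rasterize_polygon, transfer_roi
from .stats import AnovaResult, TukeyResult, tukey_hsd, two_way_anova
from .synthgen import generate_study, scenario_design
from .types import (
    BinaryMask,
    DetectorParams,
    LABEL_CHANNELS,
    QuantRecord,
    SceneParams,
    StudyDesign,
)

log = logging.getLogger("ftlquant")

RESPONSES = ("cell_count", "double_count", "pixels_above", "pct_labeled")


def nominal_disk_area(radius: float) -> int:
    """Pixel area of the rendered prototype disk of the given radius."""
    from skimage.draw import disk as _draw_disk

    n = int(np.ceil(2 * radius + 3))
    rr, _cc = _draw_disk((n, n), radius + 0.5, shape=(2 * n + 1, 2 * n + 1))
    return int(len(rr))


def default_detectors(scene: SceneParams) -> dict[str, DetectorParams]:
    """Per-channel area bands at [0.5x, 2x] the nominal planted body area.

    The c-Fos band brackets the nucleus disk, the beta-gal band the soma
    disk (its upper bound also absorbs the radiating processes); both lower
    bounds sit well above the punctum area, which is how sub-nuclear
    non-specific label is excluded from cell counts.

    The double-label overlap criterion is asymmetric by geometry: a c-Fos
    nucleus sitting inside a beta-gal soma is fully covered by the soma
    (fraction 1 of the nucleus), while the soma is only fractionally
    covered by the nucleus (roughly the nucleus/soma area ratio).  The
    beta-gal detector therefore uses half that area ratio as its overlap
    threshold so both one-sided populations are counted correctly.
    """
    a_nuc = nominal_disk_area(scene.nucleus_radius)
    a_soma = nominal_disk_area(scene.soma_radius)
    return {
        "cfos": DetectorParams(min_area=int(np.ceil(0.5 * a_nuc)),
                               max_area=int(np.floor(2.0 * a_nuc))),
        "bgal": DetectorParams(min_area=int(np.ceil(0.5 * a_soma)),
                               max_area=int(np.floor(2.0 * a_soma)),
                               overlap_fraction_for_double=0.5 * a_nuc / a_soma),
    }


@dataclass
class RunConfig:
    """Everything one reproducible run needs."""

    mode: str = "synthetic"  # or "files"
    scenario: str = "paper-pattern"  # synthetic mode: paper-pattern | null
    scene: SceneParams = field(default_factory=SceneParams)
    n_per_group: int = 3
    poisson_counts: bool = True
    threshold_provenance: str = "global_aggregate"
    sd_multiplier: float = 2.0
    detectors: Optional[dict[str, DetectorParams]] = None
    alpha: float = 0.05
    seed: int = 0
    outdir: Optional[str] = None
    write_images: bool = False
    include_truth: bool = True
    manifest: Optional[str] = None  # files mode: CSV of image/roi/design rows

    def __post_init__(self) -> None:
        if self.mode not in ("synthetic", "files"):
            raise ConfigError(f"unknown mode {self.mode!r}")
        if self.threshold_provenance not in (
            "global_aggregate", "per_image_background"
        ):
            raise ConfigError(
                f"unknown threshold provenance {self.threshold_provenance!r}"
            )
        if self.mode == "files" and self.manifest is None:
            raise ConfigError("files mode requires a manifest CSV")
        if self.mode == "files" and self.threshold_provenance != "global_aggregate":
            raise ConfigError(
                "per_image_background needs a background mask source and is "
                "available in synthetic mode only"
            )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        scene = SceneParams(**raw.pop("scene", {}))
        detectors = raw.pop("detectors", None)
        if detectors is not None:
            detectors = {ch: DetectorParams(**d) for ch, d in detectors.items()}
        return cls(scene=scene, detectors=detectors, **raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class RunResult:
    records: pd.DataFrame
    thresholds: dict
    anovas: dict[tuple[str, str], AnovaResult]
    tukeys: dict[tuple[str, str, str], TukeyResult]
    report: dict
    truths: Optional[list] = None


def _load_file_sections(config: RunConfig):
    manifest = pd.read_csv(config.manifest)
    needed = {"animal", "group", "level", "image", "roi"}
    if not needed.issubset(manifest.columns):
        raise ConfigError(
            f"manifest must have columns {sorted(needed)}"
        )
    base = Path(config.manifest).parent
    sections, rois = [], []
    for _, row in manifest.iterrows():
        sec = fio.read_section_tiff(
            base / row["image"], animal_id=str(row["animal"]),
            group=str(row["group"]), level=str(row["level"]),
        )
        poly = fio.read_roi_any(base / row["roi"])
        poly.section_id = sec.section_id
        sections.append(sec)
        rois.append(poly)
    return sections, rois, None


def run_study(config: RunConfig) -> RunResult:
    """Execute the full pipeline and return records, ANOVAs and Tukey sets.

    Re-running with the same config (and seed) reproduces identical output
    tables.  Any per-section stage failure is re-raised as
    :class:`PipelineStageError` carrying the section id and stage name;
    rows quantified before the failure are written to
    ``<outdir>/quarantine/`` when an output directory is configured.
    """
    # --- acquire -------------------------------------------------------
    if config.mode == "synthetic":
        base = config.scene.with_(seed=config.seed)
        design = scenario_design(config.scenario, n_per_group=config.n_per_group)
        pairs = generate_study(design, base, poisson_counts=config.poisson_counts)
        sections = [s for s, _ in pairs]
        truths = [t for _, t in pairs]
        rois = [t.roi_polygon for t in truths]
    else:
        sections, rois, truths = _load_file_sections(config)
    log.info("acquired %d sections", len(sections))

    detectors = config.detectors or default_detectors(config.scene)

    # --- rasterize ROIs once, transfer to label channels ---------------
    roi_masks: list[BinaryMask] = []
    for sec, poly in zip(sections, rois):
        roi_masks.append(rasterize_polygon(poly, sec.shape))
        log.info("section %s: ROI %d px", sec.section_id, roi_masks[-1].count())

    # --- thresholds ----------------------------------------------------
    thresholds: dict = {}
    cutoffs: dict[str, list[float]] = {}
    if config.threshold_provenance == "global_aggregate":
        for ch in LABEL_CHANNELS:
            sample = aggregate_roi_pixels(sections, rois, ch, roi_masks=roi_masks)
            entry = estimate_threshold(
                sample, sd_multiplier=config.sd_multiplier, channel=ch,
                provenance="global_aggregate",
            )
            thresholds[ch] = entry
            cutoffs[ch] = [entry.cutoff] * len(sections)
    else:  # per_image_background, synthetic mode only
        for ch in LABEL_CHANNELS:
            per = []
            for sec, rm, truth in zip(sections, roi_masks, truths):
                bg = background_sample(
                    sec, rm, BinaryMask(truth.label_masks[ch]), ch
                )
                entry = estimate_threshold(
                    bg, sd_multiplier=config.sd_multiplier, channel=ch,
                    provenance="per_image_background",
                )
                per.append(entry)
            thresholds[ch] = per
            cutoffs[ch] = [e.cutoff for e in per]

    # --- per-section quantification ------------------------------------
    records: list[QuantRecord] = []
    rows: list[dict] = []
    for k, (sec, poly, rm) in enumerate(zip(sections, rois, roi_masks)):
        try:
            label_masks = {}
            for ch in LABEL_CHANNELS:
                # Transfer validates co-registration; the Nissl-traced mask
                # itself applies unchanged, so it is rasterized only once.
                transfer_roi(poly, ch, sec)
                label_masks[ch] = binarize(
                    sec.channels[ch], cutoffs[ch][k], channel=ch
                )
            in_roi = {
                ch: BinaryMask(label_masks[ch].mask & rm.mask, channel=ch)
                for ch in LABEL_CHANNELS
            }
            for ch in LABEL_CHANNELS:
                other = "bgal" if ch == "cfos" else "cfos"
                above, roi_px, _pct = quantify_pixels(label_masks[ch], rm)
                cells_ch = detect_cells(in_roi[ch], rm, detectors[ch], channel=ch)
                dbl, cells_ch = count_double_labeled(
                    cells_ch, in_roi[ch], in_roi[other], detectors[ch]
                )
                rec = QuantRecord(
                    animal_id=sec.animal_id, group=sec.group, level=sec.level,
                    channel=ch, cell_count=len(cells_ch), double_count=dbl,
                    pixels_above=above, roi_pixels=roi_px,
                )
                records.append(rec)
                row = {
                    "animal": rec.animal_id, "group": rec.group,
                    "level": rec.level, "channel": ch,
                    "cell_count": rec.cell_count, "double_count": rec.double_count,
                    "pixels_above": rec.pixels_above, "roi_pixels": rec.roi_pixels,
                    "pct_labeled": rec.pct_labeled,
                }
                if config.include_truth and truths is not None:
                    t = truths[k]
                    row["planted_cell_count"] = len(t.cells_in(ch))
                    row["planted_double_count"] = t.n_double()
                    row["planted_pct"] = 100.0 * t.planted_area_fraction[ch]
                rows.append(row)
                log.info(
                    "section %s channel %s: %d cells, %d double, %d/%d px",
                    sec.section_id, ch, rec.cell_count, dbl, above, roi_px,
                )
        except Exception as exc:  # surface with section id and stage
            if config.outdir:
                qdir = Path(config.outdir) / "quarantine"
                qdir.mkdir(parents=True, exist_ok=True)
                pd.DataFrame(rows).to_csv(qdir / "records_partial.csv", index=False)
            raise PipelineStageError(
                sec.section_id, "quantify", str(exc)
            ) from exc

    frame = pd.DataFrame(rows)

    # --- statistics ----------------------------------------------------
    anovas: dict[tuple[str, str], AnovaResult] = {}
    tukeys: dict[tuple[str, str, str], TukeyResult] = {}
    for ch in LABEL_CHANNELS:
        sub = frame[frame["channel"] == ch]
        for resp in RESPONSES:
            res = two_way_anova(sub, resp)
            anovas[(ch, resp)] = res
            for factor in ("group", "level"):
                try:
                    tukeys[(ch, resp, factor)] = tukey_hsd(
                        res, sub, factor, alpha=config.alpha
                    )
                except Exception:
                    continue  # degenerate residual: no post-hoc

    # --- report and outputs --------------------------------------------
    thr_report = {
        ch: ([{"cutoff": e.cutoff, "n": e.sample_size} for e in v]
             if isinstance(v, list)
             else {"cutoff": v.cutoff, "n": v.sample_size,
                   "mean": v.sample_mean, "sd": v.sample_sd})
        for ch, v in thresholds.items()
    }
    report = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "mode": config.mode,
        "scenario": config.scenario if config.mode == "synthetic" else None,
        "n_sections": len(sections),
        "n_records": len(records),
        "thresholds": thr_report,
        "alpha": config.alpha,
    }

    result = RunResult(
        records=frame, thresholds=thresholds, anovas=anovas,
        tukeys=tukeys, report=report, truths=truths,
    )
    if config.outdir:
        _write_outputs(config, result, sections, rois)
    return result


def _write_outputs(config: RunConfig, result: RunResult, sections, rois) -> None:
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    fio.write_records_csv(out / "records.csv", result.records)
    if config.threshold_provenance == "global_aggregate":
        fio.thresholds_to_frame(result.thresholds).to_csv(
            out / "thresholds.csv", index=False
        )
    anova_rows = []
    for (ch, resp), res in result.anovas.items():
        t = res.to_frame()
        t.insert(0, "channel", ch)
        t.insert(1, "response", resp)
        anova_rows.append(t)
    pd.concat(anova_rows, ignore_index=True).to_csv(
        out / "anova.csv", index=False
    )
    tukey_rows = []
    for (ch, resp, factor), tk in result.tukeys.items():
        t = tk.to_frame()
        t.insert(0, "channel", ch)
        t.insert(1, "response", resp)
        t.insert(2, "factor", factor)
        tukey_rows.append(t)
    if tukey_rows:
        pd.concat(tukey_rows, ignore_index=True).to_csv(
            out / "tukey.csv", index=False
        )
    (out / "report.json").write_text(json.dumps(result.report, indent=2))
    if config.write_images:
        img_dir = out / "sections"
        img_dir.mkdir(exist_ok=True)
        for sec, poly in zip(sections, rois):
            stem = sec.section_id
            fio.write_section_tiff(img_dir / f"{stem}.tif", sec)
            fio.write_roi_geojson(img_dir / f"{stem}.geojson", poly)
            fio.write_roi_imagej(img_dir / f"{stem}.roi", poly)
        if result.truths is not None:
            for sec, truth in zip(sections, result.truths):
                fio.write_truth_json(
                    img_dir / f"{sec.section_id}_truth.json", truth
                )
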