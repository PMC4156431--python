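"""Synthetic-section generator: truth consistency, determinism, scenarios."""

import numpy as np
import pytest
from scipy import ndimage

from ftlquant import SceneParams, StudyDesign, generate_section, generate_study
from ftlquant import io as fio
from ftlquant.errors import DesignError, PlacementError
from ftlquant.roi import rasterize_polygon
from ftlquant.synthgen import scenario_design
from ftlquant.types import DesignRow


class TestScene:
    def test_empty_scene(self):
        params = SceneParams(n_cfos_cells=0, n_bgal_cells=0, n_puncta=0, seed=1)
        _, truth = generate_section(params)
        assert truth.cells == []
        assert truth.planted_area_fraction == {"cfos": 0.0, "bgal": 0.0}

    def test_full_overlap_doubles(self):
        params = SceneParams(n_cfos_cells=10, n_bgal_cells=10,
                             double_label_fraction=1.0, n_puncta=0, seed=2)
        _, truth = generate_section(params)
        cfos = truth.cells_in("cfos")
        bgal = truth.cells_in("bgal")
        assert len(cfos) == len(bgal) == 10
        assert all(c.is_double for c in cfos + bgal)
        assert truth.n_double() == 10
        # shared sites: every c-Fos nucleus centroid has a beta-gal soma
        # centroid within a pixel (soma pixels are a superset around it)
        # the soma's rendered centroid can shift a few pixels because of
        # its radiating processes, but stays within one soma radius of the
        # shared planting site
        bc = np.array([c.centroid_xy for c in bgal])
        for c in cfos:
            d = np.hypot(*(bc - np.array(c.centroid_xy)).T)
            assert d.min() <= params.soma_radius

    def test_background_mean_monte_carlo(self):
        """No planted label: mean in-ROI intensity tracks background_mean."""
        means = []
        for seed in range(10):
            params = SceneParams(
                image_height=160, image_width=160, background_mean=100,
                background_sd=5, n_cfos_cells=0, n_bgal_cells=0, n_puncta=0,
                seed=seed,
            )
            sec, truth = generate_section(params)
            rm = rasterize_polygon(truth.roi_polygon, sec.shape).mask
            means.append(sec.channels["cfos"][rm].mean())
        assert np.mean(means) == pytest.approx(100.0, abs=1.0)

    def test_rendered_truth_consistency(self):
        """Every planted centroid is brighter than mean + 2 SD when the
        cell intensity sits well above background."""
        params = SceneParams(
            background_mean=100, background_sd=10,
            cfos_cell_intensity=100 + 6 * 10, bgal_cell_intensity=100 + 6 * 10,
            seed=5,
        )
        sec, truth = generate_section(params)
        for cell in truth.cells:
            x, y = cell.centroid_xy
            val = sec.channels[cell.channel][int(round(y)), int(round(x))]
            assert val > 100 + 2 * 10

    def test_planted_fraction_matches_mask_exactly(self, small_scene):
        sec, truth = generate_section(small_scene)
        rm = rasterize_polygon(truth.roi_polygon, sec.shape).mask
        for ch in ("cfos", "bgal"):
            frac = (truth.label_masks[ch] & rm).sum() / rm.sum()
            assert truth.planted_area_fraction[ch] == frac

    def test_planted_components_never_merge(self):
        """The truth mask decomposes into exactly one component per planted
        body (cells stay separable despite radiating processes)."""
        for seed in range(6):
            params = SceneParams(n_bgal_cells=30, n_cfos_cells=15, seed=seed)
            _, truth = generate_section(params)
            lab, n = ndimage.label(truth.label_masks["bgal"],
                                   structure=np.ones((3, 3)))
            assert n == 30
            lab, n = ndimage.label(truth.label_masks["cfos"],
                                   structure=np.ones((3, 3)))
            assert n == 15 + params.n_puncta

    def test_centroids_inside_polygon(self, small_scene):
        from shapely.geometry import Point, Polygon

        _, truth = generate_section(small_scene)
        poly = Polygon(truth.roi_polygon.vertices)
        for cell in truth.cells:
            assert poly.contains(Point(cell.centroid_xy))

    def test_double_count_rounding(self):
        params = SceneParams(n_cfos_cells=7, n_bgal_cells=9,
                             double_label_fraction=0.5, n_puncta=0, seed=3)
        _, truth = generate_section(params)
        assert truth.n_double() == round(0.5 * 7)

    def test_placement_error_names_cause(self):
        params = SceneParams(image_height=64, image_width=64,
                             n_bgal_cells=500, roi_margin=4, seed=1)
        with pytest.raises(PlacementError):
            generate_section(params)

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            SceneParams(double_label_fraction=1.5)
        with pytest.raises(ValueError):
            SceneParams(punctum_radius=4, nucleus_radius=3)
        with pytest.raises(ValueError):
            SceneParams(cfos_cell_intensity=50, background_mean=100)


class TestStudy:
    def test_cardinality_4x3x3(self, small_scene):
        design = scenario_design("custom")
        pairs = generate_study(design, small_scene)
        assert len(pairs) == 36
        ids = {(s.animal_id, s.level) for s, _ in pairs}
        assert len(ids) == 36

    def test_determinism_bit_for_bit(self, small_scene):
        design = scenario_design("custom", n_per_group=1)
        a = generate_study(design, small_scene, poisson_counts=True)
        b = generate_study(design, small_scene, poisson_counts=True)
        for (sa, ta), (sb, tb) in zip(a, b):
            for ch in ("cfos", "bgal", "nissl"):
                assert np.array_equal(sa.channels[ch], sb.channels[ch])
            assert ta.planted_area_fraction == tb.planted_area_fraction

    def test_different_rows_get_different_scenes(self, small_scene):
        design = scenario_design("custom", n_per_group=1)
        pairs = generate_study(design, small_scene)
        imgs = [p[0].channels["cfos"] for p in pairs]
        assert not np.array_equal(imgs[0], imgs[1])

    def test_msg_multiplier_in_expectation(self):
        """Planted c-Fos counts in MSG rows average ~3x the other groups."""
        base = SceneParams(image_height=192, image_width=192, n_puncta=5,
                           roi_margin=10)

        def overrides(group, level):
            return {"n_cfos_cells": 18 if group == "MSG" else 6,
                    "n_bgal_cells": 8}

        msg, rest = [], []
        for rep in range(20):
            design = StudyDesign.balanced(
                groups=("Unstim", "MSG"), levels=("Rostral",),
                n_per_group=2, overrides=overrides,
            )
            pairs = generate_study(design, base.with_(seed=rep),
                                   poisson_counts=True)
            for sec, truth in pairs:
                n = len(truth.cells_in("cfos"))
                (msg if sec.group == "MSG" else rest).append(n)
        ratio = np.mean(msg) / np.mean(rest)
        assert ratio == pytest.approx(3.0, rel=0.15)

    def test_unbalanced_design_rejected(self):
        rows = [
            DesignRow("A1", "Unstim", "Rostral"),
            DesignRow("A2", "Unstim", "Rostral"),
            DesignRow("A3", "MSG", "Rostral"),
        ]
        with pytest.raises(DesignError):
            StudyDesign(rows)

    def test_animal_in_two_groups_rejected(self):
        rows = [
            DesignRow("A1", "Unstim", "Rostral"),
            DesignRow("A1", "MSG", "Intermediate"),
        ]
        with pytest.raises(DesignError):
            StudyDesign(rows)


class TestSectionIO:
    def test_tiff_truth_roi_roundtrip(self, small_scene, tmp_path):
        sec, truth = generate_section(small_scene, animal_id="A07",
                                      group="MSG", level="Caudal")
        fio.write_section_tiff(tmp_path / "s.tif", sec)
        back = fio.read_section_tiff(tmp_path / "s.tif")
        assert back.animal_id == "A07" and back.group == "MSG"
        for ch in ("cfos", "bgal", "nissl"):
            assert np.array_equal(back.channels[ch], sec.channels[ch])

        fio.write_truth_json(tmp_path / "t.json", truth)
        tback = fio.read_truth_json(tmp_path / "t.json")
        assert tback.planted_area_fraction == truth.planted_area_fraction
        assert len(tback.cells) == len(truth.cells)

        fio.write_roi_geojson(tmp_path / "r.geojson", truth.roi_polygon)
        rback = fio.read_roi_geojson(tmp_path / "r.geojson")
        assert np.array_equal(rback.vertices, truth.roi_polygon.vertices)
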